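import numpy as np
import pandas as pd
import pytest
from scipy import stats

from advpercept import behavior_analysis as ba
from advpercept.coarse_classes import CoarseMapping
from advpercept.stimuli import StimulusPair
from advpercept.synthetic_data import ObserverConfig, simulate_observer


def _table(participants):
    """Build a response table from {pid: (consistent_flags, catch_correct_flags)}."""
    rows = []
    for pid, (flags, catches) in participants.items():
        for i, f in enumerate(flags):
            rows.append(
                {
                    "participant_id": pid,
                    "pair_id": f"p{i}",
                    "question_class": "round",
                    "epsilon": 4.0,
                    "chosen_side": "left",
                    "chose_adversarial_consistent": f,
                    "is_catch": 0,
                    "catch_correct": np.nan,
                }
            )
        for i, ok in enumerate(catches):
            rows.append(
                {
                    "participant_id": pid,
                    "pair_id": f"c{i}",
                    "question_class": "round",
                    "epsilon": 0.0,
                    "chosen_side": "left",
                    "chose_adversarial_consistent": np.nan,
                    "is_catch": 1,
                    "catch_correct": ok,
                }
            )
    return pd.DataFrame(rows)


class TestApplyExclusions:
    def test_e2_one_failed_catch_excluded(self):
        table = _table({"a": ([1, 0, 1], [1, 0]), "b": ([1, 1, 0], [1, 1])})
        out = ba.apply_exclusions(table, "E2")
        assert set(out["participant_id"]) == {"b"}

    def test_e4_one_failed_catch_retained(self):
        table = _table({"a": ([1, 0], [1, 0]), "b": ([1, 1], [0, 0])})
        out = ba.apply_exclusions(table, "E4")
        assert set(out["participant_id"]) == {"a"}

    def test_clean_participant_untouched(self):
        table = _table({"a": ([1, 0, 1], [1, 1])})
        out = ba.apply_exclusions(table, "E3")
        pd.testing.assert_frame_equal(out, table)

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            ba.apply_exclusions(_table({"a": ([1], [1])}), "E9")


class TestPerceptualBias:
    def test_simple_proportion(self):
        flags = [1] * 60 + [0] * 40
        table = _table({"a": (flags, [1])})
        summary = ba.perceptual_bias(table)
        assert summary.bias_for(question_class="round", epsilon=4.0) == pytest.approx(0.6)

    def test_all_consistent_boundary(self):
        table = _table({"a": ([1] * 10, [1])})
        summary = ba.perceptual_bias(table)
        assert summary.bias_for(question_class="round", epsilon=4.0) == 1.0

    def test_uniform_observer_near_chance(self):
        trials = [
            {
                "pair_id": f"p{i}",
                "question_class": "round",
                "epsilon": 4.0,
                "is_catch": False,
                "consistent_side": "left",
            }
            for i in range(10_000)
        ]
        table = simulate_observer(trials, ObserverConfig(bias=0.5, seed=0))
        summary = ba.perceptual_bias(table)
        assert summary.bias_for(question_class="round", epsilon=4.0) == pytest.approx(0.5, abs=0.015)

    def test_catch_rows_excluded_from_proportion(self):
        table = _table({"a": ([1, 1], [0, 0, 0])})
        summary = ba.perceptual_bias(table)
        assert summary.bias_for(question_class="round", epsilon=4.0) == 1.0

    def test_no_rows_rejected(self):
        table = _table({"a": ([], [1])})
        with pytest.raises(ValueError):
            ba.perceptual_bias(table)


class FixedScorer:
    """Scores images by their mean pixel value on logit 0."""

    n_classes = 3

    def __init__(self, scorer_id="bb"):
        self.scorer_id = scorer_id

    def logits(self, image):
        return np.array([float(np.mean(image)) / 10.0, 0.0, 0.0])

    def logits_vjp(self, image, g):
        return np.zeros_like(np.asarray(image, dtype=float))


def _pair(left_val, right_val, consistent="left", member_ids=()):
    return StimulusPair(
        experiment="E4",
        pair_id=f"pair-{left_val}-{right_val}",
        left=np.full((8, 8, 3), float(left_val)),
        right=np.full((8, 8, 3), float(right_val)),
        source=np.full((8, 8, 3), float(min(left_val, right_val))),
        source_id="s",
        question_class="q",
        consistent_side=consistent,
        epsilon=64.0,
        provenance={"member_ids": list(member_ids)},
    )


class TestAnnObserverBias:
    MAPPING = CoarseMapping({"q": {0}}, n_fine=3)

    def test_argmax_choice(self):
        out = ba.ann_observer_bias([_pair(100, 50)], FixedScorer(), self.MAPPING)
        assert out["chosen_side"].iloc[0] == "left"
        assert out["chose_adversarial_consistent"].iloc[0] == 1

    def test_tie_is_seeded_coin_flip_and_recorded(self):
        class ConstScorer(FixedScorer):
            def logits(self, image):
                return np.zeros(3)

        pairs = [_pair(80, 81)]
        out1 = ba.ann_observer_bias(pairs, ConstScorer(), self.MAPPING, seed=1)
        out2 = ba.ann_observer_bias(pairs, ConstScorer(), self.MAPPING, seed=1)
        assert out1["tie"].iloc[0]
        assert out1["chosen_side"].iloc[0] == out2["chosen_side"].iloc[0]

    def test_blackbox_violation_rejected(self):
        pairs = [_pair(100, 50, member_ids=["bb"])]
        with pytest.raises(ValueError, match="generating ensemble"):
            ba.ann_observer_bias(pairs, FixedScorer("bb"), self.MAPPING)

    def test_score_diff_column(self):
        out = ba.ann_observer_bias([_pair(100, 50)], FixedScorer(), self.MAPPING, score_diff=True)
        assert out["score_diff"].iloc[0] > 0

    def test_e4_mean_consistency_above_chance(self, testbed):
        """Qualitative analogue of the black-box preference result: a
        held-out scorer prefers the A-up image on E4 pairs."""
        from advpercept.stimuli import build_pair

        pairs = []
        for i in range(30):
            pairs.append(
                build_pair(
                    "E4",
                    testbed.dataset.images[i * 7 % 300],
                    source_id=f"s{i}",
                    mapping=testbed.mapping,
                    ensemble=testbed.ensemble,
                    epsilon=16.0,
                    target="round",
                    target_prime="boxy",
                    question_class="round",
                    seed=i,
                )
            )
        out = ba.ann_observer_bias(pairs, testbed.blackbox, testbed.mapping)
        assert out["chose_adversarial_consistent"].mean() > 0.5


class TestBiasTtest:
    def test_symmetric_around_null_zero_t(self):
        res = ba.bias_ttest([0.4, 0.5, 0.6])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_oracle_two_sqrt_three(self):
        # mean .7, sd .1, n 3: t = (0.7-0.5)/(0.1/sqrt(3)) = 2*sqrt(3)
        res = ba.bias_ttest([0.6, 0.7, 0.8])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res.df == 2
        assert res.effect_size == pytest.approx(0.2 / 0.1)

    def test_location_equivariance(self):
        base = np.array([0.52, 0.61, 0.55, 0.49])
        r1 = ba.bias_ttest(base)
        r2 = ba.bias_ttest(base + 0.1)
        assert r2.ci[0] == pytest.approx(r1.ci[0] + 0.1)
        assert r2.ci[1] == pytest.approx(r1.ci[1] + 0.1)
        # d's denominator (SD) unchanged
        sd = base.std(ddof=1)
        assert r2.effect_size - r1.effect_size == pytest.approx(0.1 / sd)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ba.bias_ttest([0.6, 0.6, 0.6])

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ba.bias_ttest([0.6])

    def test_bonferroni(self):
        assert ba.bonferroni([0.01, 0.3, 0.9]) == pytest.approx([0.03, 0.9, 1.0])


def _bias_table(rng, n_per_class=30, eps_effect=0.0, class_effect=0.0, noise=0.05):
    rows = []
    classes = ["c1", "c2"]
    eps_levels = [2.0, 4.0, 8.0, 16.0]
    for ci, cls in enumerate(classes):
        for p in range(n_per_class):
            pid = f"{cls}-p{p}"
            base = 0.5 + class_effect * ci + rng.normal(0, noise)
            for ei, eps in enumerate(eps_levels):
                rows.append(
                    {
                        "participant_id": pid,
                        "question_class": cls,
                        "epsilon": eps,
                        "bias": base + eps_effect * ei + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


class TestTwoFactorAnova:
    def test_all_equal_zero_f(self):
        df = _bias_table(np.random.default_rng(0), noise=0.0)
        df["bias"] = 0.5
        res = ba.two_factor_anova(df)
        for key in ("between", "within", "interaction"):
            assert res[key].statistic == 0.0
            assert res[key].effect_size == 0.0

    def test_partial_eta_squared_in_range(self):
        df = _bias_table(np.random.default_rng(1), eps_effect=0.02, class_effect=0.03)
        res = ba.two_factor_anova(df)
        for r in res.values():
            assert 0.0 <= r.effect_size <= 1.0

    def test_pure_epsilon_effect_detected(self):
        """Simulated observers with beta rising in epsilon and no class
        effect: the within factor is significant at alpha = .01, the
        between factor is not."""
        rng = np.random.default_rng(2)
        eps_levels = [2.0, 4.0, 8.0, 16.0]
        rows = []
        for cls in ("c1", "c2"):
            for p in range(100):
                pid = f"{cls}-{p}"
                for ei, eps in enumerate(eps_levels):
                    beta = 0.5 + 0.03 * ei
                    trials = [
                        {
                            "pair_id": f"t{t}",
                            "question_class": cls,
                            "epsilon": eps,
                            "is_catch": False,
                            "consistent_side": "left",
                        }
                        for t in range(24)
                    ]
                    cfg = ObserverConfig(
                        bias=beta, seed=int(rng.integers(2**31)), lapse_rate=0.0
                    )
                    table = simulate_observer(trials, cfg, participant_id=pid)
                    rows.append(
                        {
                            "participant_id": pid,
                            "question_class": cls,
                            "epsilon": eps,
                            "bias": table["chose_adversarial_consistent"].mean(),
                        }
                    )
        res = ba.two_factor_anova(pd.DataFrame(rows))
        assert res["within"].p < 0.01
        assert res["between"].p > 0.01

    def test_incomplete_participant_dropped(self):
        df = _bias_table(np.random.default_rng(3))
        df = df[~((df["participant_id"] == "c1-p0") & (df["epsilon"] == 2.0))]
        with pytest.warns(UserWarning, match="missing cells"):
            res = ba.two_factor_anova(df)
        assert res["within"].extra["n_dropped"] == 1


class TestSpearman:
    def test_monotone_pairs(self):
        res = ba.spearman_bias_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_pairs(self):
        res = ba.spearman_bias_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.statistic == pytest.approx(-1.0)

    def test_midrank_ties_against_brute_force(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 2.0, 3.0, 3.0]

        def midranks(v):
            v = np.asarray(v, dtype=float)
            out = np.empty(len(v))
            for i, val in enumerate(v):
                less = np.sum(v < val)
                equal = np.sum(v == val)
                out[i] = less + (equal + 1) / 2.0
            return out

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        res = ba.spearman_bias_correlation(x, y)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.df == 2

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ba.spearman_bias_correlation([1, 1, 1], [1, 2, 3])

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            ba.spearman_bias_correlation([1, 2, 3], [1, 2])


def _mean_bias(table):
    rows = table[table["is_catch"].astype(int) == 0]
    return rows["chose_adversarial_consistent"].mean()


def _sim_table(beta, n_participants, n_trials, seed):
    trials = [
        {
            "pair_id": f"p{i}",
            "question_class": "round",
            "epsilon": 4.0,
            "is_catch": False,
            "consistent_side": "left",
        }
        for i in range(n_trials)
    ]
    frames = []
    for p in range(n_participants):
        cfg = ObserverConfig(bias=beta, seed=seed * 10_000 + p)
        frames.append(simulate_observer(trials, cfg, participant_id=f"p{p}"))
    return pd.concat(frames, ignore_index=True)


class TestPermutationNull:
    def test_observed_rank_well_defined(self):
        table = _sim_table(0.7, 5, 20, seed=1)
        null, p = ba.permutation_null(table, _mean_bias, n_perm=199, seed=0)
        assert len(null) == 199
        assert 0.0 < p <= 1.0

    def test_null_p_roughly_uniform_under_chance(self):
        # calibration: under beta = 0.5 the permutation p is uniform
        ps = []
        for rep in range(60):
            table = _sim_table(0.5, 4, 24, seed=rep)
            _, p = ba.permutation_null(table, _mean_bias, n_perm=119, seed=rep)
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_under_strong_bias(self):
        rejections = 0
        for rep in range(10):
            table = _sim_table(0.7, 50, 96, seed=100 + rep)
            _, p = ba.permutation_null(table, _mean_bias, n_perm=299, seed=rep)
            rejections += p < 0.01
        assert rejections == 10

    def test_small_n_perm_warns(self):
        table = _sim_table(0.6, 2, 10, seed=0)
        with pytest.warns(UserWarning):
            ba.permutation_null(table, _mean_bias, n_perm=50, seed=0)

    def test_within_participant_preserves_participant_means(self):
        table = _sim_table(0.6, 3, 30, seed=2)
        before = table.groupby("participant_id")["chose_adversarial_consistent"].mean()

        def stat(t):
            after = t.groupby("participant_id")["chose_adversarial_consistent"].mean()
            return float(np.max(np.abs(after - before)))

        null, _ = ba.permutation_null(table, stat, n_perm=100, seed=0, method="within_participant")
        assert np.max(null) == pytest.approx(0.0, abs=1e-12)


class TestWrappers:
    def test_shapiro_on_normal_data(self, rng):
        res = ba.shapiro_wilk(rng.normal(size=100))
        assert res.p > 0.001

    def test_wilcoxon_detects_shift(self, rng):
        res = ba.wilcoxon_signed_rank(0.6 + 0.05 * rng.normal(size=40))
        assert res.p < 0.001


class TestEndToEndRecovery:
    def test_known_beta_recovered_with_exclusions(self):
        """Full chain: simulate observers with known per-condition beta,
        run exclusions then bias estimation, recover beta within the 95%
        binomial CI of the pooled estimate."""
        rng = np.random.default_rng(0)
        betas = {("round", 2.0): 0.52, ("round", 8.0): 0.60}
        trials = []
        for i in range(48):
            eps = 2.0 if i % 2 == 0 else 8.0
            trials.append(
                {
                    "pair_id": f"p{i}",
                    "question_class": "round",
                    "epsilon": eps,
                    "is_catch": False,
                    "consistent_side": "left" if i % 3 else "right",
                }
            )
        trials += [
            {
                "pair_id": f"c{i}",
                "question_class": "round",
                "epsilon": 0.0,
                "is_catch": True,
                "correct_side": "left",
            }
            for i in range(4)
        ]
        frames = []
        for p in range(80):
            cfg = ObserverConfig(
                bias=0.5, bias_by_condition=betas, catch_accuracy=0.95, seed=p
            )
            frames.append(simulate_observer(trials, cfg, participant_id=f"p{p}"))
        table = pd.concat(frames, ignore_index=True)
        kept = ba.apply_exclusions(table, "E2")
        assert kept["participant_id"].nunique() < 80  # some exclusions happen
        summary = ba.perceptual_bias(kept)
        for (cls, eps), beta in betas.items():
            est = summary.bias_for(question_class=cls, epsilon=eps)
            n = summary.table.query("epsilon == @eps")["n"].iloc[0]
            half_width = 1.96 * np.sqrt(beta * (1 - beta) / n)
            assert abs(est - beta) < half_width + 0.01
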