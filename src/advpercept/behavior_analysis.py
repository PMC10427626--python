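"""Behavioral statistics for 2AFC response tables.

Implements the analysis chain applied to forced-choice data: catch-trial
exclusions, perceptual-bias estimation, ANN forced-choice observers,
one-sample t tests against chance, a mixed two-factor ANOVA with partial
eta squared, tie-aware Spearman correlation, permutation nulls, and thin
wrappers for the auxiliary normality / signed-rank checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .coarse_classes import CoarseMapping, coarse_score
from .model_interface import DifferentiableScorer
from .stimuli import StimulusPair

__all__ = [
    "BiasSummary",
    "StatResult",
    "CATCH_FAIL_THRESHOLD",
    "apply_exclusions",
    "perceptual_bias",
    "ann_observer_bias",
    "bias_ttest",
    "bonferroni",
    "two_factor_anova",
    "spearman_bias_correlation",
    "permutation_null",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
]

#: Failed-catch count at which a participant's data is discarded.
CATCH_FAIL_THRESHOLD = {"E1": 1, "E2": 1, "E3": 1, "E4": 2, "E5": 1}


@dataclass(frozen=True)
class StatResult:
    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BiasSummary:
    """Per-group proportion of adversarial-consistent choices."""

    table: pd.DataFrame  # group keys + bias, n, se

    def bias_for(self, **keys) -> float:
        sel = self.table
        for k, v in keys.items():
            sel = sel[sel[k] == v]
        if len(sel) != 1:
            raise KeyError(f"keys {keys} select {len(sel)} rows")
        return float(sel["bias"].iloc[0])


def apply_exclusions(responses: pd.DataFrame, experiment: str) -> pd.DataFrame:
    """Drop every row of participants at or above the failed-catch threshold.

    The threshold is 1 failed catch for E1/E2/E3/E5 and 2 for E4. Rows of
    retained participants pass through untouched.
    """
    try:
        threshold = CATCH_FAIL_THRESHOLD[experiment]
    except KeyError:
        raise ValueError(f"unknown experiment tag {experiment!r}") from None
    catch = responses[responses["is_catch"].astype(int) == 1]
    fails = (
        catch.assign(failed=lambda d: 1 - d["catch_correct"].astype(float))
        .groupby("participant_id")["failed"]
        .sum()
    )
    excluded = set(fails[fails >= threshold].index)
    return responses[~responses["participant_id"].isin(excluded)].copy()


def perceptual_bias(
    responses: pd.DataFrame, group_by: Sequence[str] = ("question_class", "epsilon")
) -> BiasSummary:
    """Proportion of adversarial-consistent choices per group (catch excluded)."""
    df = responses[responses["is_catch"].astype(int) == 0]
    if df.empty:
        raise ValueError("no non-catch rows to summarize")
    rows = []
    grouped = df.groupby(list(group_by)) if group_by else [((), df)]
    for keys, grp in grouped:
        if grp.empty:
            warnings.warn(f"empty group {keys}; omitted")
            continue
        x = grp["chose_adversarial_consistent"].astype(float)
        n = len(x)
        bias = float(x.mean())
        # SE of participant-level biases when several participants present
        per_part = grp.groupby("participant_id")["chose_adversarial_consistent"].mean()
        if len(per_part) > 1:
            se = float(per_part.std(ddof=1) / np.sqrt(len(per_part)))
        else:
            se = float(np.sqrt(bias * (1 - bias) / n))
        row = dict(zip(group_by, keys if isinstance(keys, tuple) else (keys,)))
        row.update(bias=bias, n=n, se=se)
        rows.append(row)
    return BiasSummary(table=pd.DataFrame(rows))


def ann_observer_bias(
    pairs: Sequence[StimulusPair],
    scorer: DifferentiableScorer,
    mapping: CoarseMapping,
    score_diff: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Forced choices of a black-box scorer over stimulus pairs.

    Picks the side with the higher coarse score for the question class;
    exact ties are broken by a seeded coin flip and flagged. Raises if
    the scorer was part of any generating ensemble (black-box
    violation). ``score_diff=True`` additionally reports a continuous
    consistent-minus-other score difference.
    """
    rng = np.random.default_rng(seed)
    scorer_id = getattr(scorer, "scorer_id", None)
    rows = []
    for p in pairs:
        if p.is_catch:
            continue
        if scorer_id is not None and scorer_id in p.provenance.get("member_ids", []):
            raise ValueError(
                f"scorer {scorer_id!r} was in the generating ensemble of pair {p.pair_id}"
            )
        s_left = coarse_score(scorer.logits(p.left), mapping, p.question_class)
        s_right = coarse_score(scorer.logits(p.right), mapping, p.question_class)
        tie = s_left == s_right
        if tie:
            chosen = "left" if rng.random() < 0.5 else "right"
        else:
            chosen = "left" if s_left > s_right else "right"
        consistent = int(chosen == p.consistent_side)
        row = {
            "pair_id": p.pair_id,
            "source_id": p.source_id,
            "question_class": p.question_class,
            "epsilon": p.epsilon,
            "chosen_side": chosen,
            "chose_adversarial_consistent": consistent,
            "tie": bool(tie),
        }
        if score_diff:
            s_cons = s_left if p.consistent_side == "left" else s_right
            s_other = s_right if p.consistent_side == "left" else s_left
            row["score_diff"] = s_cons - s_other
        rows.append(row)
    return pd.DataFrame(rows)


def bias_ttest(
    per_participant_biases: Sequence[float],
    null: float = 0.5,
    tails: str = "two-sided",
) -> StatResult:
    """One-sample t test of participant biases against chance.

    Reports df = n - 1, Cohen's d = (mean - null) / SD, and the
    t-interval CI of the mean.
    """
    x = np.asarray(per_participant_biases, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two participants")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance in biases (all equal to {x[0]})")
    res = stats.ttest_1samp(x, null, alternative=tails if tails != "two-sided" else "two-sided")
    n = len(x)
    d = (x.mean() - null) / sd
    ci = res.confidence_interval(0.95)
    return StatResult(
        name="one-sample t",
        statistic=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        effect_size=float(d),
        effect_size_name="cohen_d",
        ci=(float(ci.low), float(ci.high)),
        extra={"mean": float(x.mean()), "null": null},
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]


def two_factor_anova(
    bias_table: pd.DataFrame,
    dv: str = "bias",
    between: str = "question_class",
    within: str = "epsilon",
    subject: str = "participant_id",
) -> dict[str, StatResult]:
    """Mixed-design ANOVA (between = class, within = epsilon) with partial
    eta squared; participants with incomplete within-factor cells are
    dropped listwise (and counted in the result extras)."""
    df = bias_table.copy()
    n_levels = df[within].nunique()
    cells = df.groupby(subject)[within].nunique()
    complete = set(cells[cells == n_levels].index)
    dropped = sorted(set(df[subject]) - complete)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} participants with missing cells")
        df = df[df[subject].isin(complete)]
    if df[dv].nunique() == 1:
        # degenerate design: no variance anywhere, so no effect explains any
        return {
            key: StatResult(
                name=f"mixed ANOVA {key}",
                statistic=0.0,
                df=(0.0, 0.0),
                p=1.0,
                effect_size=0.0,
                effect_size_name="partial_eta_sq",
                extra={"n_dropped": len(dropped), "degenerate": True},
            )
            for key in ("between", "within", "interaction")
        }
    aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between, subject=subject)
    out: dict[str, StatResult] = {}
    for _, row in aov.iterrows():
        key = {between: "between", within: "within", "Interaction": "interaction"}.get(
            row["Source"], row["Source"]
        )
        out[key] = StatResult(
            name=f"mixed ANOVA {row['Source']}",
            statistic=float(row["F"]),
            df=(float(row["DF1"]), float(row["DF2"])),
            p=float(row["p_unc"]),
            effect_size=float(row["np2"]),
            effect_size_name="partial_eta_sq",
            extra={"n_dropped": len(dropped)},
        )
    return out


def spearman_bias_correlation(
    human_bias: Sequence[float], ann_bias: Sequence[float]
) -> StatResult:
    """Tie-aware Spearman correlation between paired per-image biases."""
    x = np.asarray(human_bias, dtype=float)
    y = np.asarray(ann_bias, dtype=float)
    if x.shape != y.shape:
        raise ValueError("bias vectors must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    # Fisher-z CI on the rank correlation
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(n - 3) if n > 3 else np.nan
    ci = (float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se)))
    return StatResult(
        name="spearman",
        statistic=float(rho),
        df=n - 2,
        p=float(p),
        effect_size=float(rho),
        effect_size_name="rho",
        ci=ci,
    )


def permutation_null(
    responses: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "flip",
) -> tuple[np.ndarray, float]:
    """Seeded shuffle null for a response-table statistic.

    ``method='flip'`` (default) re-randomizes the adversarial-consistency
    labeling: each non-catch row's consistency indicator is replaced by
    its value XOR a fair coin, which is the exact null of "choice is
    independent of which side the attack favored".
    ``method='within_participant'`` instead permutes the indicator values
    among each participant's rows (preserves participant means; only
    meaningful for condition-structure statistics). Returns the null
    distribution and the rank-based two-sided-agnostic p of the observed
    statistic, ``(1 + #{null >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p value")
    rng = np.random.default_rng(seed)
    observed = float(statistic(responses))
    non_catch = responses["is_catch"].astype(int) == 0
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = responses.copy()
        vals = shuffled.loc[non_catch, "chose_adversarial_consistent"].to_numpy(dtype=float)
        if method == "flip":
            coins = rng.integers(0, 2, size=len(vals))
            shuffled.loc[non_catch, "chose_adversarial_consistent"] = np.abs(vals - coins)
        elif method == "within_participant":
            pid = shuffled.loc[non_catch, "participant_id"].to_numpy()
            out = vals.copy()
            for part in np.unique(pid):
                idx = np.flatnonzero(pid == part)
                out[idx] = vals[rng.permutation(idx)]
            shuffled.loc[non_catch, "chose_adversarial_consistent"] = out
        else:
            raise ValueError(f"unknown permutation method {method!r}")
        null[b] = statistic(shuffled)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return null, float(p)


def shapiro_wilk(values: Sequence[float]) -> StatResult:
    """Shapiro-Wilk normality check (thin wrapper)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return StatResult(name="shapiro-wilk", statistic=float(w), df=len(values), p=float(p))


def wilcoxon_signed_rank(values: Sequence[float], null: float = 0.5) -> StatResult:
    """Wilcoxon signed-rank test of symmetric location against ``null``."""
    x = np.asarray(values, dtype=float) - null
    res = stats.wilcoxon(x)
    return StatResult(
        name="wilcoxon", statistic=float(res.statistic), df=len(x), p=float(res.pvalue)
    )
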