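"""Experiment stimulus pairs, session assembly, and stimulus I/O.

Five paired-presentation designs are supported:

* E1 — adversarial image vs. the top-down flipped-perturbation control.
* E2 — same source pushed toward (targeted) vs. away from (untargeted)
  its own class T.
* E3 — adversarial image vs. the right-left flipped-perturbation control.
* E4 — the same source pushed toward two different classes A and A',
  with per-image class subsampling to equalize fine-class support.
* E5 — the same targeted attack generated by two different ensembles.

Sessions interleave seeded catch trials (an unperturbed exemplar of the
queried class paired with a wrong-class exemplar) among the experiment
trials at random positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .adversarial_attack import AttackConfig, Perturbation, flip_control, generate_adversarial
from .coarse_classes import CoarseMapping, subsample_mapping
from .model_interface import Ensemble
from .synthetic_data import RESPONSE_COLUMNS, Dataset, derive_seed

__all__ = [
    "StimulusPair",
    "SessionPlan",
    "build_pair",
    "make_catch_pairs",
    "build_session",
    "write_stimuli",
    "read_responses",
]

MANIFEST_SCHEMA_VERSION = 1

EXPERIMENTS = ("E1", "E2", "E3", "E4", "E5")

#: Default protocol for the extended-viewing experiments: 104 trials per
#: participant session of which 8 are randomly placed catch trials.
DEFAULT_N_TRIALS = 104
DEFAULT_N_CATCH = 8


@dataclass
class StimulusPair:
    experiment: str
    pair_id: str
    left: np.ndarray
    right: np.ndarray
    source: np.ndarray | None
    source_id: str
    question_class: str
    consistent_side: str | None  # 'left' | 'right'; None for catch pairs
    epsilon: float
    provenance: dict = field(default_factory=dict)
    is_catch: bool = False
    correct_side: str | None = None
    delta_left: np.ndarray | None = None
    delta_right: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS and not self.is_catch:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if not self.is_catch and self.consistent_side not in ("left", "right"):
            raise ValueError("non-catch pair needs a consistency side")
        if np.array_equal(self.left, self.right):
            raise ValueError("left and right stimuli are identical")


def _place(primary: np.ndarray, other: np.ndarray, rng: np.random.Generator):
    """Randomize which image goes on which side; returns (left, right, side_of_primary)."""
    if rng.random() < 0.5:
        return primary, other, "left"
    return other, primary, "right"


def build_pair(
    experiment: str,
    source: np.ndarray,
    source_id: str,
    mapping: CoarseMapping,
    ensemble: Ensemble,
    *,
    epsilon: float,
    target: str,
    target_prime: str | None = None,
    question_class: str | None = None,
    ensemble_b: Ensemble | None = None,
    seed: int = 0,
    attack_kwargs: Mapping | None = None,
) -> StimulusPair:
    """Assemble one experiment-specific stimulus pair from a source image.

    ``target`` is T for E2 and the adversarial class A otherwise; E4
    additionally needs ``target_prime`` (A') and E5 a second ensemble.
    Side assignment is randomized by ``seed``.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = np.random.default_rng(derive_seed(seed, "pair", experiment, source_id))
    kwargs = dict(attack_kwargs or {})
    attack_seed = derive_seed(seed, "attack", experiment, source_id)

    def attack(mode: str, y: str, ens: Ensemble, amap: CoarseMapping, salt: str):
        cfg = AttackConfig(
            epsilon=epsilon,
            mode=mode,
            target=y,
            seed=derive_seed(attack_seed, salt),
            **kwargs,
        )
        return generate_adversarial(source, ens, amap, cfg)

    question = question_class or target
    prov: dict = {
        "experiment": experiment,
        "source_id": source_id,
        "epsilon": epsilon,
        "seed": seed,
        "ensemble_ids": [ensemble.ensemble_id],
        "member_ids": list(ensemble.member_ids),
    }

    if experiment in ("E1", "E3"):
        adv, pert, _ = attack("targeted", target, ensemble, mapping, "A-up")
        axis = "vertical" if experiment == "E1" else "horizontal"
        control_delta = flip_control(pert, axis)
        control = np.clip(source + control_delta.delta, 0, 255)
        left, right, side = _place(adv, control, rng)
        d_adv, d_ctl = pert.delta, control_delta.delta
    elif experiment == "E2":
        up, pert_up, _ = attack("targeted", target, ensemble, mapping, "T-up")
        down, pert_down, _ = attack("untargeted", target, ensemble, mapping, "T-down")
        left, right, side = _place(up, down, rng)
        d_adv, d_ctl = pert_up.delta, pert_down.delta
    elif experiment == "E4":
        if target_prime is None:
            raise ValueError("experiment E4 needs a second target class")
        if target_prime == target:
            raise ValueError("E4 target classes must be distinct")
        sub = subsample_mapping(
            mapping, target, target_prime, derive_seed(seed, "subsample", source_id)
        )
        a_up, pert_a, _ = attack("targeted", target, ensemble, sub, "A-up")
        ap_up, pert_ap, _ = attack("targeted", target_prime, ensemble, sub, "Aprime-up")
        if question not in (target, target_prime):
            raise ValueError("E4 question class must be one of the two targets")
        primary, other = (a_up, ap_up) if question == target else (ap_up, a_up)
        left, right, side = _place(primary, other, rng)
        d_adv = pert_a.delta if question == target else pert_ap.delta
        d_ctl = pert_ap.delta if question == target else pert_a.delta
        prov["target_prime"] = target_prime
    elif experiment == "E5":
        if ensemble_b is None:
            raise ValueError("experiment E5 needs a second ensemble")
        adv_a, pert_a, _ = attack("targeted", target, ensemble, mapping, "ens-a")
        adv_b, pert_b, _ = attack("targeted", target, ensemble_b, mapping, "ens-b")
        # consistency convention: the second ensemble's image is the
        # 'consistent' choice (analogue of the attention-family preference)
        left, right, side = _place(adv_b, adv_a, rng)
        d_adv, d_ctl = pert_b.delta, pert_a.delta
        prov["ensemble_ids"] = [ensemble.ensemble_id, ensemble_b.ensemble_id]
        prov["member_ids"] = list(ensemble.member_ids) + list(ensemble_b.member_ids)
    else:  # pragma: no cover
        raise AssertionError

    prov["target"] = target
    delta_left = d_adv if side == "left" else d_ctl
    delta_right = d_ctl if side == "left" else d_adv
    return StimulusPair(
        experiment=experiment,
        pair_id=f"{experiment}-{source_id}-eps{epsilon:g}-q{question}",
        left=left,
        right=right,
        source=np.asarray(source, dtype=float),
        source_id=source_id,
        question_class=question,
        consistent_side=side,
        epsilon=float(epsilon),
        provenance=prov,
        delta_left=delta_left,
        delta_right=delta_right,
    )


def make_catch_pairs(
    dataset: Dataset,
    mapping: CoarseMapping,
    n: int,
    seed: int = 0,
) -> list[StimulusPair]:
    """Unambiguous catch pairs: a clean exemplar of the queried coarse
    class against a clean image from outside it."""
    rng = np.random.default_rng(derive_seed(seed, "catch"))
    names = list(mapping.names)
    pairs = []
    for i in range(n):
        question = names[rng.integers(len(names))]
        members = mapping.members(question)
        in_idx = np.flatnonzero(np.isin(dataset.labels, list(members)))
        out_idx = np.flatnonzero(~np.isin(dataset.labels, list(members)))
        a = dataset.images[rng.choice(in_idx)]
        b = dataset.images[rng.choice(out_idx)]
        left, right, side = _place(a, b, rng)
        pairs.append(
            StimulusPair(
                experiment="catch",
                pair_id=f"catch-{i}",
                left=left,
                right=right,
                source=None,
                source_id=f"catch-{i}",
                question_class=question,
                consistent_side=None,
                epsilon=0.0,
                is_catch=True,
                correct_side=side,
            )
        )
    return pairs


@dataclass
class SessionPlan:
    """Seeded ordered trial list with catch trials at random positions."""

    trials: pd.DataFrame
    pairs: dict[str, StimulusPair]
    n_trials: int
    n_catch: int
    seed: int

    def trial_records(self) -> list[dict]:
        return self.trials.to_dict("records")


def build_session(
    pairs: Sequence[StimulusPair],
    n_trials: int = DEFAULT_N_TRIALS,
    n_catch: int = DEFAULT_N_CATCH,
    seed: int = 0,
    catch_pairs: Sequence[StimulusPair] | None = None,
) -> SessionPlan:
    """Assemble a participant session of exactly ``n_trials`` trials.

    ``n_catch`` of them are catch trials at seeded random positions; the
    rest cycle through ``pairs`` in seeded random order.
    """
    if n_catch > n_trials:
        raise ValueError("n_catch cannot exceed n_trials")
    n_exp = n_trials - n_catch
    pool = [p for p in pairs if not p.is_catch]
    if n_exp > 0 and len(pool) < 1:
        raise ValueError("no experiment pairs supplied")
    if len(pool) < n_exp:
        raise ValueError(
            f"need at least {n_exp} experiment pairs, got {len(pool)}"
        )
    catch_pool = list(catch_pairs or [])
    if n_catch > 0 and len(catch_pool) < n_catch:
        raise ValueError(f"need at least {n_catch} catch pairs, got {len(catch_pool)}")

    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_exp, replace=False)]
    chosen_catch = [catch_pool[i] for i in rng.choice(len(catch_pool), size=n_catch, replace=False)]
    catch_positions = set(rng.choice(n_trials, size=n_catch, replace=False).tolist())

    rows = []
    it_exp = iter(chosen)
    it_catch = iter(chosen_catch)
    used: dict[str, StimulusPair] = {}
    for t in range(n_trials):
        p = next(it_catch) if t in catch_positions else next(it_exp)
        used[p.pair_id] = p
        rows.append(
            {
                "trial_index": t,
                "pair_id": p.pair_id,
                "question_class": p.question_class,
                "epsilon": p.epsilon,
                "is_catch": int(p.is_catch),
                "consistent_side": p.consistent_side,
                "correct_side": p.correct_side,
            }
        )
    return SessionPlan(
        trials=pd.DataFrame(rows),
        pairs=used,
        n_trials=n_trials,
        n_catch=n_catch,
        seed=seed,
    )


def _save_png(image: np.ndarray, path: Path) -> None:
    arr = np.clip(np.round(np.asarray(image)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_stimuli(
    pairs: Sequence[StimulusPair],
    session: SessionPlan | None,
    out_dir,
) -> Path:
    """Write 8-bit PNG stimuli plus a JSON manifest; returns manifest path.

    The epsilon constraint of each pair's provenance is re-checked at
    write time against the stored source (with one intensity level of
    slack for 8-bit rounding).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for p in pairs:
        files = {}
        for side in ("left", "right"):
            img = getattr(p, side)
            if p.source is not None and not p.is_catch:
                dev = float(np.max(np.abs(img - p.source)))
                if dev > p.epsilon + 1.0:
                    raise ValueError(
                        f"pair {p.pair_id}: {side} stimulus deviates {dev:.2f} "
                        f"from source, beyond epsilon {p.epsilon}"
                    )
            fname = f"{p.pair_id}_{side}.png"
            _save_png(img, out / fname)
            files[side] = fname
        if p.source is not None:
            fname = f"{p.pair_id}_source.png"
            _save_png(p.source, out / fname)
            files["source"] = fname
        entries[p.pair_id] = {
            "files": files,
            "experiment": p.experiment,
            "source_id": p.source_id,
            "question_class": p.question_class,
            "consistent_side": p.consistent_side,
            "correct_side": p.correct_side,
            "epsilon": p.epsilon,
            "is_catch": int(p.is_catch),
            "provenance": p.provenance,
        }
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "pairs": entries,
    }
    if session is not None:
        manifest["session"] = {
            "n_trials": session.n_trials,
            "n_catch": session.n_catch,
            "seed": session.seed,
            "trials": session.trials.to_dict("records"),
        }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_responses(path, manifest: Path | Mapping | None = None) -> pd.DataFrame:
    """Read and validate a 2AFC response CSV.

    Requires the documented response-table header; if a manifest (path
    or parsed dict) is given, every ``pair_id`` must exist in it.
    """
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table is missing columns: {missing}")
    bad_side = set(df["chosen_side"].unique()) - {"left", "right"}
    if bad_side:
        raise ValueError(f"invalid chosen_side values: {sorted(bad_side)}")
    is_catch = df["is_catch"].astype(int)
    catch_na = df["catch_correct"].isna()
    if ((is_catch == 0) & ~catch_na).any() or ((is_catch == 1) & catch_na).any():
        raise ValueError("catch_correct must be present exactly on catch rows")
    if manifest is not None:
        if not isinstance(manifest, Mapping):
            manifest = json.loads(Path(manifest).read_text())
        known = set(manifest["pairs"])
        unknown = set(df["pair_id"].astype(str)) - known
        if unknown:
            raise ValueError(f"responses reference unknown pair ids: {sorted(unknown)}")
    return df
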