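"""Synthetic testbed: shape/texture images, toy scorers, simulated observers.

Everything here is scaffolding that stands in for photographic datasets,
large pretrained classifiers, and human participants, so that the attack
and analysis machinery can be exercised and verified offline. Nothing in
this module models real observers; the Bernoulli observer is a test
instrument with known ground-truth bias.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coarse_classes import CoarseMapping, default_mapping_for
from .model_interface import Ensemble, EnsembleSpec, MLPScorer

__all__ = [
    "SHAPE_CLASSES",
    "SyntheticDatasetSpec",
    "Dataset",
    "generate_dataset",
    "ToyTrainConfig",
    "ToyScorerAccuracyError",
    "fit_toy_scorer",
    "ObserverConfig",
    "simulate_observer",
    "Testbed",
    "make_default_testbed",
]

SHAPE_CLASSES = ("ellipse", "rectangle", "triangle", "annulus", "cross", "bar")

RESPONSE_COLUMNS = [
    "participant_id",
    "pair_id",
    "question_class",
    "epsilon",
    "chosen_side",
    "chose_adversarial_consistent",
    "is_catch",
    "catch_correct",
]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for a labelled synthetic image population.

    Each fine class is a parametric 2D shape carrying a class-specific
    sinusoidal texture; per-image variation comes from sampled shape
    parameters (position jitter, size scale, texture phase/orientation
    jitter) plus i.i.d. pixel noise.
    """

    n_fine_classes: int = 6
    images_per_class: int = 50
    L: int = 64
    noise_sd: float = 8.0
    jitter_px: float = 3.0
    size_range: tuple[float, float] = (0.8, 1.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fine_classes < 1:
            raise ValueError("need at least one fine class")
        if self.n_fine_classes > len(SHAPE_CLASSES):
            raise ValueError(
                f"at most {len(SHAPE_CLASSES)} fine classes are supported"
            )
        if self.images_per_class < 1:
            raise ValueError("need at least one image per class")
        if self.L < 16:
            raise ValueError("image side must be >= 16 pixels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("degenerate size range")

    @property
    def class_names(self) -> tuple[str, ...]:
        return SHAPE_CLASSES[: self.n_fine_classes]


@dataclass
class Dataset:
    images: np.ndarray  # (N, L, L, 3) float in [0, 255]
    labels: np.ndarray  # (N,) int fine-class labels
    class_names: tuple[str, ...]
    spec: SyntheticDatasetSpec

    def __len__(self) -> int:
        return len(self.labels)


def _shape_mask(kind: str, L: int, cx: float, cy: float, size: float) -> np.ndarray:
    yy, xx = np.mgrid[0:L, 0:L].astype(float)
    dx, dy = xx - cx, yy - cy
    r = size * L / 4
    if kind == "ellipse":
        return (dx / (1.3 * r)) ** 2 + (dy / (0.8 * r)) ** 2 <= 1.0
    if kind == "rectangle":
        return (np.abs(dx) <= 1.2 * r) & (np.abs(dy) <= 0.8 * r)
    if kind == "triangle":
        return (dy >= -r) & (dy + 2 * np.abs(dx) <= r)
    if kind == "annulus":
        rho = np.hypot(dx, dy)
        return (rho <= 1.2 * r) & (rho >= 0.6 * r)
    if kind == "cross":
        arm = 0.45 * r
        return ((np.abs(dx) <= arm) & (np.abs(dy) <= 1.4 * r)) | (
            (np.abs(dy) <= arm) & (np.abs(dx) <= 1.4 * r)
        )
    if kind == "bar":
        return (np.abs(dx) <= 1.6 * r) & (np.abs(dy) <= 0.35 * r)
    raise ValueError(f"unknown shape kind {kind!r}")


# class-specific texture: (cycles per image side, orientation radians).
# orientations are deliberately oblique (never 0 or pi/2) so that no
# class signal is mirror-symmetric: spatially flipping a perturbation
# must destroy its alignment with the class features
_TEXTURE = {
    "ellipse": (2.0, 0.35),
    "rectangle": (3.5, 1.2),
    "triangle": (2.5, 0.8),
    "annulus": (4.0, 0.5),
    "cross": (1.5, 1.05),
    "bar": (3.0, 0.2),
}


def _render(kind: str, L: int, cx: float, cy: float, size: float, phase: float) -> np.ndarray:
    """Deterministic render of one class exemplar (no pixel noise)."""
    mask = _shape_mask(kind, L, cx, cy, size)
    freq, orient = _TEXTURE[kind]
    yy, xx = np.mgrid[0:L, 0:L].astype(float)
    carrier = np.sin(
        2 * np.pi * freq / L * (xx * np.cos(orient) + yy * np.sin(orient)) + phase
    )
    img = np.full((L, L, 3), 110.0)
    fg = 150.0 + 70.0 * carrier
    for ch, gain in enumerate((1.0, 0.9, 0.8)):
        img[..., ch] = np.where(mask, gain * fg, img[..., ch])
    return img


def generate_dataset(spec: SyntheticDatasetSpec) -> Dataset:
    """Sample a balanced labelled image population; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    n = spec.n_fine_classes * spec.images_per_class
    images = np.empty((n, spec.L, spec.L, 3))
    labels = np.empty(n, dtype=int)
    i = 0
    for label, kind in enumerate(spec.class_names):
        for _ in range(spec.images_per_class):
            cx = spec.L / 2 + rng.uniform(-spec.jitter_px, spec.jitter_px)
            cy = spec.L / 2 + rng.uniform(-spec.jitter_px, spec.jitter_px)
            size = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            img = _render(kind, spec.L, cx, cy, size, phase)
            if spec.noise_sd > 0:
                img = img + rng.normal(0, spec.noise_sd, img.shape)
            images[i] = np.clip(img, 0, 255)
            labels[i] = label
            i += 1
    return Dataset(images=images, labels=labels, class_names=spec.class_names, spec=spec)


# ---------------------------------------------------------------------------
# toy scorer training
# ---------------------------------------------------------------------------


class ToyScorerAccuracyError(RuntimeError):
    """Raised when training fails to reach the configured accuracy floor."""

    def __init__(self, achieved: float, required: float):
        super().__init__(
            f"toy scorer reached held-out accuracy {achieved:.3f}, "
            f"below the required {required:.3f}"
        )
        self.achieved = achieved
        self.required = required


@dataclass(frozen=True)
class ToyTrainConfig:
    hidden: int = 96
    epochs: int = 140
    batch_size: int = 64
    lr: float = 2e-3
    weight_decay: float = 1e-4
    holdout_frac: float = 0.2
    min_accuracy: float = 0.9
    pool: int = 2
    family: str = "a"
    #: transformed copies added per training image; the augmentation law
    #: matches the viewing-condition transforms the attacks must survive
    #: (rotation U(0, pi/6), per-axis scale U(0.5 L, L), translation
    #: U(-L/4, L/4)), giving the scorers approximate invariance to them
    augment_copies: int = 2
    seed: int = 0


def fit_toy_scorer(
    dataset: Dataset, cfg: ToyTrainConfig = ToyTrainConfig(), _retries: int = 2
) -> MLPScorer:
    """Train a small MLP scorer on a synthetic dataset (Adam, cross-entropy).

    Raises :class:`ToyScorerAccuracyError` if held-out top-1 accuracy
    falls below ``cfg.min_accuracy``. Different seeds give different
    initializations (and therefore distinct members for ensembling).
    """
    k = len(dataset.class_names)
    if k < 2:
        raise ValueError("need at least two fine classes to fit a scorer")
    rng = np.random.default_rng(cfg.seed)
    L = dataset.spec.L
    # self-attention-ish family gets a wider net and coarser pooling: the
    # flag only has to yield systematically different members, not
    # architectural fidelity
    hidden = cfg.hidden if cfg.family == "a" else int(cfg.hidden * 1.5)
    pool = cfg.pool if cfg.family == "a" else max(1, cfg.pool * 2)

    scorer = MLPScorer(
        w1=rng.normal(0, 1, (hidden, 3 * (L // pool) ** 2)) / np.sqrt(3 * (L // pool) ** 2),
        b1=np.zeros(hidden),
        w2=rng.normal(0, 1, (k, hidden)) / np.sqrt(hidden),
        b2=np.zeros(k),
        image_side=L,
        pool=pool,
        family=cfg.family,
        scorer_id=f"toy-{cfg.family}-seed{cfg.seed}",
    )

    n = len(dataset)
    perm = rng.permutation(n)
    n_holdout = max(1, int(round(cfg.holdout_frac * n)))
    test_idx, train_idx = perm[:n_holdout], perm[n_holdout:]
    z_all = scorer._features(dataset.images)
    y = dataset.labels

    if cfg.augment_copies > 0:
        from .adversarial_attack import TransformOp, TransformSample

        aug_feats, aug_labels = [], []
        for _ in range(cfg.augment_copies):
            for i in train_idx:
                t = TransformSample(
                    theta=rng.uniform(0, np.pi / 6),
                    s_x=rng.uniform(0.5 * L, L),
                    s_y=rng.uniform(0.5 * L, L),
                    t_x=rng.uniform(-L / 4, L / 4),
                    t_y=rng.uniform(-L / 4, L / 4),
                )
                aug_feats.append(
                    scorer._features(TransformOp(t, L).apply(dataset.images[i]))[0]
                )
                aug_labels.append(y[i])
        z_all = np.vstack([z_all, np.array(aug_feats)])
        y = np.concatenate([y, np.array(aug_labels)])
        train_idx = np.concatenate([train_idx, np.arange(n, len(y))])

    params = [scorer.w1, scorer.b1, scorer.w2, scorer.b2]
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = z_all[idx]
            h = np.tanh(z @ scorer.w1.T + scorer.b1)
            logits = h @ scorer.w2.T + scorer.b2
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            g_logits = p
            g_logits[np.arange(len(idx)), y[idx]] -= 1.0
            g_logits /= len(idx)
            g_w2 = g_logits.T @ h + cfg.weight_decay * scorer.w2
            g_b2 = g_logits.sum(axis=0)
            g_h = (g_logits @ scorer.w2) * (1 - h**2)
            g_w1 = g_h.T @ z + cfg.weight_decay * scorer.w1
            g_b1 = g_h.sum(axis=0)
            step += 1
            for p_, g_, m_, v_ in zip(params, (g_w1, g_b1, g_w2, g_b2), m_t, v_t):
                m_ *= beta1
                m_ += (1 - beta1) * g_
                v_ *= beta2
                v_ += (1 - beta2) * g_**2
                mhat = m_ / (1 - beta1**step)
                vhat = v_ / (1 - beta2**step)
                p_ -= cfg.lr * mhat / (np.sqrt(vhat) + eps_adam)

    pred = scorer.logits_batch(dataset.images[test_idx]).argmax(axis=1)
    acc = float(np.mean(pred == y[test_idx]))
    if acc < cfg.min_accuracy:
        if _retries > 0:
            # rare optimization collapse: deterministic reseeded restart
            reseeded = dataclasses.replace(cfg, seed=derive_seed(cfg.seed, "retry", _retries))
            return fit_toy_scorer(dataset, reseeded, _retries=_retries - 1)
        raise ToyScorerAccuracyError(acc, cfg.min_accuracy)
    return scorer


# ---------------------------------------------------------------------------
# simulated 2AFC observers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverConfig:
    """Bernoulli 2AFC observer with lapses and catch-trial competence.

    On non-catch trials the adversarial-consistent side is chosen with
    probability ``(1 - lapse_rate) * beta + lapse_rate * 0.5`` where
    ``beta`` is looked up per (question class, epsilon) condition with a
    scalar fallback. Catch trials are answered correctly with probability
    ``catch_accuracy``.
    """

    bias: float = 0.5
    bias_by_condition: Mapping[tuple[str, float], float] | None = None
    lapse_rate: float = 0.0
    catch_accuracy: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.bias, self.lapse_rate, self.catch_accuracy]
        if self.bias_by_condition:
            probs += list(self.bias_by_condition.values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all observer probabilities must lie in [0, 1]")

    def beta_for(self, question_class: str, epsilon: float) -> float:
        if self.bias_by_condition:
            key = (question_class, float(epsilon))
            if key in self.bias_by_condition:
                return float(self.bias_by_condition[key])
        return self.bias


def simulate_observer(
    pairs: Sequence[Mapping],
    config: ObserverConfig,
    participant_id: str = "sim-0",
) -> pd.DataFrame:
    """Simulate one participant's responses over a trial sequence.

    ``pairs`` rows need ``pair_id``, ``question_class``, ``epsilon``,
    ``is_catch`` and, for non-catch trials, ``consistent_side``
    ('left'/'right'); catch trials need ``correct_side``. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for trial in pairs:
        is_catch = bool(trial.get("is_catch", False))
        if is_catch:
            correct = str(trial["correct_side"])
            if rng.random() < config.catch_accuracy:
                chosen = correct
            else:
                chosen = "left" if correct == "right" else "right"
            rows.append(
                {
                    "participant_id": participant_id,
                    "pair_id": trial["pair_id"],
                    "question_class": trial["question_class"],
                    "epsilon": float(trial["epsilon"]),
                    "chosen_side": chosen,
                    "chose_adversarial_consistent": np.nan,
                    "is_catch": 1,
                    "catch_correct": int(chosen == correct),
                }
            )
            continue
        side = trial.get("consistent_side")
        if side not in ("left", "right"):
            raise ValueError(
                f"pair {trial.get('pair_id')!r} lacks an adversarial-consistency label"
            )
        beta = config.beta_for(str(trial["question_class"]), float(trial["epsilon"]))
        p_consistent = (1.0 - config.lapse_rate) * beta + config.lapse_rate * 0.5
        consistent = rng.random() < p_consistent
        chosen = side if consistent else ("left" if side == "right" else "right")
        rows.append(
            {
                "participant_id": participant_id,
                "pair_id": trial["pair_id"],
                "question_class": trial["question_class"],
                "epsilon": float(trial["epsilon"]),
                "chosen_side": chosen,
                "chose_adversarial_consistent": int(consistent),
                "is_catch": 0,
                "catch_correct": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def derive_seed(global_seed: int, *parts) -> int:
    """Stable per-item seed from a global seed and arbitrary labels."""
    key = ":".join([str(global_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


# ---------------------------------------------------------------------------
# the frozen default testbed
# ---------------------------------------------------------------------------


@dataclass
class Testbed:
    """Dataset + attack ensemble + held-out black-box scorer + mapping."""

    dataset: Dataset
    ensemble: Ensemble
    ensemble_b: Ensemble
    blackbox: MLPScorer
    mapping: CoarseMapping


def make_default_testbed(seed: int = 0, images_per_class: int = 50) -> Testbed:
    """Build the default frozen testbed used throughout the test suite.

    Three family-'a' members form the attack ensemble, two family-'b'
    members form the alternative-architecture ensemble, and one extra
    family-'a' scorer (never placed in either ensemble) serves as the
    black-box observer.
    """
    spec = SyntheticDatasetSpec(seed=seed, images_per_class=images_per_class)
    dataset = generate_dataset(spec)
    members = [
        fit_toy_scorer(dataset, ToyTrainConfig(seed=derive_seed(seed, "member", i)))
        for i in range(3)
    ]
    members_b = [
        fit_toy_scorer(
            dataset, ToyTrainConfig(family="b", seed=derive_seed(seed, "member-b", i))
        )
        for i in range(2)
    ]
    blackbox = fit_toy_scorer(
        dataset, ToyTrainConfig(seed=derive_seed(seed, "blackbox"))
    )
    mapping = default_mapping_for(dataset.class_names)
    return Testbed(
        dataset=dataset,
        ensemble=Ensemble(EnsembleSpec(members), ensemble_id="toy-conv"),
        ensemble_b=Ensemble(EnsembleSpec(members_b), ensemble_id="toy-attn"),
        blackbox=blackbox,
        mapping=mapping,
    )
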