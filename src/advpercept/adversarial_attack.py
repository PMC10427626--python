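"""Iterative sign-gradient attacks with an L-infinity budget and EOT.

The attack maximizes (targeted) or minimizes (untargeted) the coarse
category probability of an ensemble by repeatedly stepping along the
sign of the input gradient:

    X_i = clip(X_{i-1} + alpha * sgn(grad(-J)), X - eps, X + eps)

with a final clip to the displayable [0, 255] range each iteration.
Optionally the gradient is averaged over random identity-preserving
geometric transforms (rotation / anisotropic rescale / translation) so
the perturbation survives changes in viewing geometry (EOT). Both the
transform and the optional retinal blur are linear in the image, so all
gradients are exact adjoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .coarse_classes import CoarseMapping, coarse_prob, coarse_score, coarse_score_grad
from .model_interface import Ensemble, RetinalBlurConfig, retinal_blur, retinal_blur_vjp

__all__ = [
    "AttackConfig",
    "Perturbation",
    "TransformSample",
    "TransformOp",
    "attack_objective",
    "attack_objective_grad",
    "ifgsm_step",
    "sample_transform",
    "apply_transform",
    "generate_adversarial",
    "flip_control",
]

_PROB_FLOOR = 1e-12  # probabilities clamped to [floor, 1-floor] before log


@dataclass(frozen=True)
class AttackConfig:
    """Attack hyperparameters and EOT transform ranges.

    ``alpha`` and ``n_iters`` default to 1 intensity level and
    ``2 * epsilon`` steps. Transform ranges follow the stated sampling
    laws: rotation U(0, pi/6) (one-sided as printed; set
    ``symmetric_rotation`` for +/-), scale U(0.5 L, L) pixels per axis,
    translation U(-L/4, L/4) pixels.
    """

    epsilon: float
    alpha: float = 1.0
    n_iters: int | None = None
    mode: str = "targeted"
    target: str = ""
    eot: bool = True
    transforms_per_step: int = 1
    theta_max: float = np.pi / 6
    symmetric_rotation: bool = False
    scale_frac_range: tuple[float, float] = (0.5, 1.0)
    translate_frac: float = 0.25
    blur: RetinalBlurConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_iters is not None and self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")
        if self.mode not in ("targeted", "untargeted"):
            raise ValueError(f"unknown attack mode {self.mode!r}")
        if self.transforms_per_step < 1:
            raise ValueError("transforms_per_step must be >= 1")

    @property
    def iters(self) -> int:
        return self.n_iters if self.n_iters is not None else max(1, int(round(2 * self.epsilon)))


@dataclass(frozen=True)
class Perturbation:
    """A per-pixel delta bounded by the generating epsilon."""

    delta: np.ndarray
    epsilon: float
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if np.max(np.abs(self.delta)) > self.epsilon + 1e-9:
            raise ValueError("perturbation exceeds its epsilon bound")

    @property
    def linf(self) -> float:
        return float(np.max(np.abs(self.delta)))


@dataclass(frozen=True)
class TransformSample:
    theta: float  # radians
    s_x: float  # pixels
    s_y: float  # pixels
    t_x: float  # pixels
    t_y: float  # pixels


def sample_transform(cfg: AttackConfig, L: int, rng: int | np.random.Generator) -> TransformSample:
    """Uniform seeded draw of a geometric transform within cfg ranges."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo = -cfg.theta_max if cfg.symmetric_rotation else 0.0
    theta = rng.uniform(lo, cfg.theta_max)
    s_lo, s_hi = cfg.scale_frac_range
    s_x = rng.uniform(s_lo * L, s_hi * L)
    s_y = rng.uniform(s_lo * L, s_hi * L)
    t_max = cfg.translate_frac * L
    t_x = rng.uniform(-t_max, t_max)
    t_y = rng.uniform(-t_max, t_max)
    return TransformSample(theta, s_x, s_y, t_x, t_y)


def _reflect(coord: np.ndarray, n: int) -> np.ndarray:
    """Mirror continuous coordinates into [0, n-1] (reflect padding)."""
    if n == 1:
        return np.zeros_like(coord)
    period = 2.0 * (n - 1)
    c = np.mod(coord, period)
    return np.where(c > n - 1, period - c, c)


class TransformOp:
    """Bilinear warp (rotate, rescale, translate) as an explicit linear op.

    The source coordinate for each output pixel is precomputed together
    with its four bilinear weights; ``apply`` is a weighted gather and
    ``vjp`` the exact scatter adjoint. Out-of-frame coordinates reflect
    into the image, so no artificial borders enter the objective.
    """

    def __init__(self, t: TransformSample, L: int) -> None:
        self.L = L
        c = (L - 1) / 2.0
        cols, rows = np.meshgrid(np.arange(L, dtype=float), np.arange(L, dtype=float))
        # inverse map: undo translation, undo scale, undo rotation
        x = cols - c - t.t_x
        y = rows - c - t.t_y
        x *= L / t.s_x
        y *= L / t.s_y
        cos_t, sin_t = np.cos(t.theta), np.sin(t.theta)
        src_x = _reflect(cos_t * x + sin_t * y + c, L)
        src_y = _reflect(-sin_t * x + cos_t * y + c, L)

        x0 = np.clip(np.floor(src_x).astype(np.intp), 0, L - 2)
        y0 = np.clip(np.floor(src_y).astype(np.intp), 0, L - 2)
        fx = src_x - x0
        fy = src_y - y0
        self._corners = (
            (y0, x0, (1 - fy) * (1 - fx)),
            (y0, x0 + 1, (1 - fy) * fx),
            (y0 + 1, x0, fy * (1 - fx)),
            (y0 + 1, x0 + 1, fy * fx),
        )

    def apply(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        out = np.zeros_like(x)
        for yy, xx, w in self._corners:
            out += w[..., None] * x[yy, xx]
        return out

    def vjp(self, grad_out: np.ndarray) -> np.ndarray:
        g = np.asarray(grad_out, dtype=float)
        grad = np.zeros((self.L, self.L, g.shape[2]))
        for yy, xx, w in self._corners:
            np.add.at(grad, (yy, xx), w[..., None] * g)
        return grad


def apply_transform(image: np.ndarray, t: TransformSample) -> np.ndarray:
    """Rotate about center, rescale to (s_x, s_y), translate; bilinear."""
    return TransformOp(t, np.asarray(image).shape[0]).apply(image)


def attack_objective(
    image: np.ndarray,
    y: str,
    mode: str,
    ensemble: Ensemble,
    mapping: CoarseMapping,
) -> float:
    """Binary cross-entropy against the coarse target class.

    targeted: -log P(y|X); untargeted: -log(1 - P(y|X)), where P is the
    logistic of the ensemble coarse score. Probabilities are clamped to
    [1e-12, 1 - 1e-12] before the log.
    """
    score = coarse_score(ensemble.logits(image), mapping, y)
    p = np.clip(coarse_prob(score), _PROB_FLOOR, 1 - _PROB_FLOOR)
    if mode == "targeted":
        return float(-np.log(p))
    if mode == "untargeted":
        return float(-np.log(1 - p))
    raise ValueError(f"unknown attack mode {mode!r}")


def attack_objective_grad(
    image: np.ndarray,
    y: str,
    mode: str,
    ensemble: Ensemble,
    mapping: CoarseMapping,
) -> tuple[float, np.ndarray]:
    """Objective value and its exact gradient with respect to the pixels."""
    logits = ensemble.logits(image)
    score = coarse_score(logits, mapping, y)
    p = coarse_prob(score)
    p_safe = np.clip(p, _PROB_FLOOR, 1 - _PROB_FLOOR)
    if mode == "targeted":
        loss = float(-np.log(p_safe))
        dscore = p - 1.0  # d(-log sigmoid(s))/ds
    elif mode == "untargeted":
        loss = float(-np.log(1 - p_safe))
        dscore = p  # d(-log(1 - sigmoid(s)))/ds
    else:
        raise ValueError(f"unknown attack mode {mode!r}")
    dlogits = dscore * coarse_score_grad(logits, mapping, y)
    return loss, ensemble.logits_vjp(image, dlogits)


def ifgsm_step(
    current: np.ndarray,
    source: np.ndarray,
    gradient_of_negJ: np.ndarray,
    alpha: float,
    epsilon: float,
) -> np.ndarray:
    """One signed-gradient ascent step with the two clips.

    ``sgn(0) = 0`` (no movement without gradient evidence). The epsilon
    clip is applied first, then the [0, 255] range clip.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    current = np.asarray(current, dtype=float)
    source = np.asarray(source, dtype=float)
    if current.shape != source.shape or current.shape != np.asarray(gradient_of_negJ).shape:
        raise ValueError("shape mismatch between image and gradient")
    stepped = current + alpha * np.sign(gradient_of_negJ)
    clipped = np.clip(stepped, source - epsilon, source + epsilon)
    return np.clip(clipped, 0.0, 255.0)


def generate_adversarial(
    source: np.ndarray,
    ensemble: Ensemble,
    mapping: CoarseMapping,
    cfg: AttackConfig,
) -> tuple[np.ndarray, Perturbation, list[float]]:
    """Run the full iterative attack; returns (adversarial, delta, loss trace).

    Each iteration averages the gradient of -J over
    ``cfg.transforms_per_step`` fresh EOT samples (a stochastic estimate
    of the expectation over transforms); with EOT off, the objective is
    evaluated on the (optionally blurred) image directly. The loss trace
    records the mean per-iteration objective; it need not be monotone.
    """
    if not cfg.target:
        raise ValueError("attack config must name a target coarse class")
    if cfg.target not in mapping.names:
        raise KeyError(f"unknown coarse category {cfg.target!r}")
    source = np.asarray(source, dtype=float)
    L = source.shape[0]
    rng = np.random.default_rng(cfg.seed)
    current = source.copy()
    trace: list[float] = []
    for _ in range(cfg.iters):
        grad = np.zeros_like(source)
        losses = []
        for _ in range(cfg.transforms_per_step if cfg.eot else 1):
            x = current
            if cfg.blur is not None:
                x = retinal_blur(x, cfg.blur)
            op = None
            if cfg.eot:
                op = TransformOp(sample_transform(cfg, L, rng), L)
                x = op.apply(x)
            loss, g = attack_objective_grad(x, cfg.target, cfg.mode, ensemble, mapping)
            if op is not None:
                g = op.vjp(g)
            if cfg.blur is not None:
                g = retinal_blur_vjp(g, cfg.blur)
            losses.append(loss)
            grad -= g  # gradient of -J
        n_samples = len(losses)
        current = ifgsm_step(current, source, grad / n_samples, cfg.alpha, cfg.epsilon)
        trace.append(float(np.mean(losses)))
    # float-exact constraint: re-adding a clipped delta to the source can
    # overshoot epsilon by one ulp, so nudge offenders back toward source
    current = np.clip(source + np.clip(current - source, -cfg.epsilon, cfg.epsilon), 0.0, 255.0)
    over = np.abs(current - source) > cfg.epsilon
    while np.any(over):
        current[over] = np.nextafter(current[over], source[over])
        over = np.abs(current - source) > cfg.epsilon
    delta = current - source
    perturbation = Perturbation(
        delta=delta,
        epsilon=cfg.epsilon,
        provenance={
            "ensemble_id": ensemble.ensemble_id,
            "member_ids": list(ensemble.member_ids),
            "mode": cfg.mode,
            "target": cfg.target,
            "seed": cfg.seed,
            "eot": cfg.eot,
        },
    )
    return current, perturbation, trace


def flip_control(delta: Perturbation | np.ndarray, axis: str) -> Perturbation | np.ndarray:
    """Spatially mirror a perturbation (the statistics-preserving control).

    ``axis='vertical'`` mirrors top-down, ``axis='horizontal'`` mirrors
    left-right. Per-pixel magnitudes are preserved as a multiset, hence
    all norms are unchanged.
    """
    if axis not in ("vertical", "horizontal"):
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
    if isinstance(delta, Perturbation):
        flipped = flip_control(delta.delta, axis)
        prov = dict(delta.provenance or {})
        prov["control"] = f"{axis}-flip"
        return Perturbation(delta=flipped, epsilon=delta.epsilon, provenance=prov)
    arr = np.asarray(delta)
    return np.flipud(arr) if axis == "vertical" else np.fliplr(arr)
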