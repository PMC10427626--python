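"""Differentiable-scorer contract, calibration, ensembling, and retinal blur.

All scorers map an H x W x 3 image on the 0-255 intensity scale to a
length-K vector of unnormalized class scores (logits) and expose the
exact vector-Jacobian product (VJP) of the logits with respect to the
input pixels. Gradients are hand-derived and verified against central
finite differences in the test suite; no autodiff framework is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "DifferentiableScorer",
    "MLPScorer",
    "EnsembleSpec",
    "Ensemble",
    "RetinalBlurConfig",
    "calibrate",
    "ensemble_logits",
    "retinal_blur",
    "retinal_blur_vjp",
]

CHECKPOINT_SCHEMA_VERSION = 1


@runtime_checkable
class DifferentiableScorer(Protocol):
    """Contract: image -> fine logits, with an input-pixel VJP."""

    n_classes: int

    def logits(self, image: np.ndarray) -> np.ndarray:
        """Length-K unnormalized scores for one H x W x 3 image."""
        ...

    def logits_vjp(self, image: np.ndarray, grad_logits: np.ndarray) -> np.ndarray:
        """d(grad_logits . logits)/d(image), shaped like ``image``."""
        ...


def calibrate(logits: np.ndarray, T: float) -> np.ndarray:
    """Temperature-scale a logit vector: elementwise division by ``T`` > 0."""
    if T <= 0:
        raise ValueError(f"calibration temperature must be positive, got {T}")
    return np.asarray(logits, dtype=float) / T


class MLPScorer:
    """One-hidden-layer tanh network over average-pooled pixels.

    The toy stand-in for a large pretrained classifier. Input pixels on
    [0, 255] are average-pooled by ``pool`` in each spatial dimension,
    rescaled to [-1, 1], flattened, and passed through
    ``tanh(W1 z + b1)`` then an affine readout. Every stage is linear or
    has a closed-form derivative, so the input-pixel VJP is exact.
    """

    def __init__(
        self,
        w1: np.ndarray,
        b1: np.ndarray,
        w2: np.ndarray,
        b2: np.ndarray,
        image_side: int,
        pool: int = 2,
        family: str = "a",
        scorer_id: str = "mlp",
    ) -> None:
        self.w1 = np.asarray(w1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float)
        self.w2 = np.asarray(w2, dtype=float)
        self.b2 = np.asarray(b2, dtype=float)
        self.image_side = int(image_side)
        self.pool = int(pool)
        self.family = family
        self.scorer_id = scorer_id
        if self.image_side % self.pool:
            raise ValueError("pool must divide the image side")

    @property
    def n_classes(self) -> int:
        return self.w2.shape[0]

    # -- feature map ---------------------------------------------------
    def _features(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) or (H, W, 3) uint/float pixels -> (N, D) in [-1, 1]."""
        x = np.asarray(images, dtype=float)
        single = x.ndim == 3
        if single:
            x = x[None]
        n, h, w, c = x.shape
        p = self.pool
        x = x.reshape(n, h // p, p, w // p, p, c).mean(axis=(2, 4))
        z = x.reshape(n, -1) / 127.5 - 1.0
        return z

    def _unpool(self, grad_z: np.ndarray) -> np.ndarray:
        """Adjoint of ``_features`` for a single image."""
        p = self.pool
        hp = self.image_side // p
        g = grad_z.reshape(hp, 1, hp, 1, 3) / 127.5
        g = np.broadcast_to(g / (p * p), (hp, p, hp, p, 3))
        return g.reshape(self.image_side, self.image_side, 3)

    # -- contract ------------------------------------------------------
    def logits(self, image: np.ndarray) -> np.ndarray:
        return self.logits_batch(image[None])[0]

    def logits_batch(self, images: np.ndarray) -> np.ndarray:
        z = self._features(images)
        h = np.tanh(z @ self.w1.T + self.b1)
        return h @ self.w2.T + self.b2

    def logits_vjp(self, image: np.ndarray, grad_logits: np.ndarray) -> np.ndarray:
        z = self._features(image)
        h = np.tanh(z @ self.w1.T + self.b1)
        gh = (np.asarray(grad_logits, dtype=float) @ self.w2) * (1.0 - h[0] ** 2)
        gz = gh @ self.w1
        return self._unpool(gz)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            schema_version=CHECKPOINT_SCHEMA_VERSION,
            w1=self.w1,
            b1=self.b1,
            w2=self.w2,
            b2=self.b2,
            image_side=self.image_side,
            pool=self.pool,
            family=np.str_(self.family),
            scorer_id=np.str_(self.scorer_id),
        )

    @classmethod
    def load(cls, path) -> "MLPScorer":
        with np.load(path, allow_pickle=False) as ckpt:
            version = int(ckpt["schema_version"])
            if version != CHECKPOINT_SCHEMA_VERSION:
                raise ValueError(f"unsupported checkpoint schema version {version}")
            return cls(
                ckpt["w1"],
                ckpt["b1"],
                ckpt["w2"],
                ckpt["b2"],
                image_side=int(ckpt["image_side"]),
                pool=int(ckpt["pool"]),
                family=str(ckpt["family"]),
                scorer_id=str(ckpt["scorer_id"]),
            )


@dataclass(frozen=True)
class EnsembleSpec:
    """Member scorers plus a per-member calibration temperature."""

    members: Sequence[DifferentiableScorer]
    temperatures: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("ensemble must have at least one member")
        temps = self.temperatures
        if temps is None:
            temps = (1.0,) * len(self.members)
        temps = tuple(float(t) for t in temps)
        if len(temps) != len(self.members):
            raise ValueError("one temperature per member required")
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        k = {m.n_classes for m in self.members}
        if len(k) != 1:
            raise ValueError(f"members disagree on fine-class count: {sorted(k)}")
        object.__setattr__(self, "temperatures", temps)


class Ensemble:
    """Unweighted mean of per-member temperature-calibrated logits.

    Calibration is applied per member before averaging; the VJP
    distributes the incoming cotangent as ``g / (M * T_m)`` to member
    ``m``, so gradients flow through every member.
    """

    def __init__(self, spec: EnsembleSpec, ensemble_id: str = "ensemble") -> None:
        self.spec = spec
        self.ensemble_id = ensemble_id

    @property
    def n_classes(self) -> int:
        return self.spec.members[0].n_classes

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(
            getattr(m, "scorer_id", f"member{i}")
            for i, m in enumerate(self.spec.members)
        )

    def logits(self, image: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_classes)
        for member, temp in zip(self.spec.members, self.spec.temperatures):
            out += calibrate(member.logits(image), temp)
        return out / len(self.spec.members)

    def logits_vjp(self, image: np.ndarray, grad_logits: np.ndarray) -> np.ndarray:
        m = len(self.spec.members)
        grad = np.zeros_like(np.asarray(image, dtype=float))
        for member, temp in zip(self.spec.members, self.spec.temperatures):
            grad += member.logits_vjp(image, np.asarray(grad_logits) / (m * temp))
        return grad


def ensemble_logits(spec: EnsembleSpec, image: np.ndarray) -> np.ndarray:
    """Functional form of :class:`Ensemble` logit averaging."""
    return Ensemble(spec).logits(image)


@dataclass(frozen=True)
class RetinalBlurConfig:
    """Foveated blur: sigma grows linearly with eccentricity from fixation.

    ``sigma(e) = sigma_min + (sigma_max - sigma_min) * e / e_max`` with
    ``e`` the Euclidean pixel distance from the fixation point and
    ``e_max`` the largest such distance in the frame. The default
    (``sigma_min = sigma_max = 0``) is a no-op; the profile here is one
    admissible monotone choice, not a reconstruction of any particular
    retina model.
    """

    fixation: tuple[float, float] = (0.0, 0.0)  # (row, col); set per image
    sigma_min: float = 0.0
    sigma_max: float = 0.0
    n_levels: int = 5

    def __post_init__(self) -> None:
        if self.sigma_min < 0:
            raise ValueError("sigma_min must be >= 0")
        if self.sigma_max < self.sigma_min:
            raise ValueError("sigma_max must be >= sigma_min")
        if self.n_levels < 2:
            raise ValueError("need at least two blur levels")


def _blur_bank(cfg: RetinalBlurConfig, shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Per-level sigmas and per-pixel interpolation weights (H, W, n_levels)."""
    h, w = shape[:2]
    fr, fc = cfg.fixation
    if not (0 <= fr <= h - 1 and 0 <= fc <= w - 1):
        raise ValueError("fixation point outside image bounds")
    rows, cols = np.mgrid[0:h, 0:w]
    ecc = np.hypot(rows - fr, cols - fc)
    e_max = ecc.max()
    frac = ecc / e_max if e_max > 0 else np.zeros_like(ecc)
    sigma = cfg.sigma_min + (cfg.sigma_max - cfg.sigma_min) * frac

    sigmas = np.linspace(cfg.sigma_min, cfg.sigma_max, cfg.n_levels)
    weights = np.zeros((h, w, cfg.n_levels))
    if cfg.sigma_max == cfg.sigma_min:
        weights[..., 0] = 1.0
        return sigmas[:1], weights[..., :1]
    # linear interpolation between the two bracketing levels
    pos = (sigma - cfg.sigma_min) / (cfg.sigma_max - cfg.sigma_min) * (cfg.n_levels - 1)
    lo = np.clip(np.floor(pos).astype(int), 0, cfg.n_levels - 2)
    t = pos - lo
    ij = np.ogrid[0:h, 0:w]
    weights[ij[0], ij[1], lo] = 1.0 - t
    weights[ij[0], ij[1], lo + 1] = t
    return sigmas, weights


def _gauss(x: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return x
    # wrap mode: the blur matrix is symmetric, so the operator is its own
    # adjoint and the VJP below is exact
    return gaussian_filter(x, sigma=(sigma, sigma, 0), mode="wrap")


def retinal_blur(image: np.ndarray, cfg: RetinalBlurConfig) -> np.ndarray:
    """Spatially varying Gaussian smoothing, heavier far from fixation.

    Implemented as per-pixel interpolation across a bank of uniformly
    blurred copies; the map is linear in the input, preserves [0, 255],
    and is exactly differentiable via :func:`retinal_blur_vjp`.
    """
    x = np.asarray(image, dtype=float)
    sigmas, weights = _blur_bank(cfg, x.shape)
    out = np.zeros_like(x)
    for k, s in enumerate(sigmas):
        out += weights[..., k : k + 1] * _gauss(x, s)
    return out


def retinal_blur_vjp(grad_out: np.ndarray, cfg: RetinalBlurConfig) -> np.ndarray:
    """Adjoint of :func:`retinal_blur` (the operator is input-independent)."""
    g = np.asarray(grad_out, dtype=float)
    sigmas, weights = _blur_bank(cfg, g.shape)
    grad = np.zeros_like(g)
    for k, s in enumerate(sigmas):
        grad += _gauss(weights[..., k : k + 1] * g, s)
    return grad
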