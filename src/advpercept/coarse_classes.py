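"""Fine-to-coarse logit aggregation and paired-target class subsampling.

A *coarse category* is a named, nonempty set of fine-class indices. Its
unnormalized score contrasts the member logits against all non-member
logits:

    score(c) = logsumexp(S_i, i in c) - logsumexp(S_j, j not in c)

which is the logit of a binary member/non-member classifier; the logistic
transform of this score is the coarse-category probability.

Fine classes assigned to no category are allowed and always contribute to
the complement (non-member) sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit, logsumexp, softmax

__all__ = [
    "CoarseMapping",
    "coarse_score",
    "coarse_score_grad",
    "coarse_prob",
    "subsample_mapping",
    "load_mapping",
    "save_mapping",
    "IMAGENET_COARSE_NAMES",
]

#: The nine coarse object categories used with ImageNet-scale models,
#: shipped for documentation parity. Fine-class index supports belong to
#: a 1000-class indexing and are not reconstructed here.
IMAGENET_COARSE_NAMES = (
    "sheep",
    "dog",
    "cat",
    "elephant",
    "bird",
    "chair",
    "bottle",
    "truck",
    "clock",
)


@dataclass(frozen=True)
class CoarseMapping:
    """Named coarse categories over ``n_fine`` fine classes.

    Parameters
    ----------
    groups
        Mapping from category name to the set of 0-based fine-class
        indices it contains.
    n_fine
        Total number of fine classes (length of the logit vector).

    Each group must be a nonempty strict subset of ``range(n_fine)`` (the
    complement must be nonempty for the member/non-member contrast to be
    defined), and groups must be pairwise disjoint.
    """

    groups: Mapping[str, frozenset[int]]
    n_fine: int

    def __post_init__(self) -> None:
        groups = {name: frozenset(idx) for name, idx in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        if self.n_fine < 2:
            raise ValueError("need at least two fine classes")
        seen: set[int] = set()
        for name, idx in groups.items():
            if not idx:
                raise ValueError(f"coarse category {name!r} is empty")
            if not all(0 <= i < self.n_fine for i in idx):
                raise ValueError(f"coarse category {name!r} has out-of-range indices")
            if len(idx) == self.n_fine:
                raise ValueError(
                    f"coarse category {name!r} covers every fine class; "
                    "the complement must be nonempty"
                )
            if seen & idx:
                raise ValueError(f"coarse category {name!r} overlaps another category")
            seen |= idx
        if len(groups) < 1:
            raise ValueError("mapping has no coarse categories")

    def members(self, name: str) -> frozenset[int]:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"unknown coarse category {name!r}") from None

    def member_array(self, name: str) -> np.ndarray:
        return np.fromiter(sorted(self.members(name)), dtype=np.intp)

    def complement_array(self, name: str) -> np.ndarray:
        c = self.members(name)
        return np.fromiter(
            (i for i in range(self.n_fine) if i not in c), dtype=np.intp
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.groups)


def coarse_score(logits: np.ndarray, mapping: CoarseMapping, c: str) -> float:
    """Member-vs-complement log-sum-exp contrast for category ``c``.

    Computed with overflow-safe log-sum-exp; exact to floating precision
    for bounded logits.
    """
    s = np.asarray(logits, dtype=float)
    if s.shape != (mapping.n_fine,):
        raise ValueError(
            f"logit vector has shape {s.shape}, expected ({mapping.n_fine},)"
        )
    inside = mapping.member_array(c)
    outside = mapping.complement_array(c)
    return float(logsumexp(s[inside]) - logsumexp(s[outside]))


def coarse_score_grad(
    logits: np.ndarray, mapping: CoarseMapping, c: str
) -> np.ndarray:
    """Gradient of :func:`coarse_score` with respect to the fine logits.

    Equals the within-member softmax on member coordinates and the
    negated within-complement softmax on complement coordinates.
    """
    s = np.asarray(logits, dtype=float)
    inside = mapping.member_array(c)
    outside = mapping.complement_array(c)
    g = np.zeros_like(s)
    g[inside] = softmax(s[inside])
    g[outside] = -softmax(s[outside])
    return g


def coarse_prob(score: float) -> float:
    """Logistic transform of a coarse score; strictly increasing."""
    if not np.isfinite(score):
        raise ValueError("coarse score must be finite")
    return float(expit(score))


def subsample_mapping(
    mapping: CoarseMapping,
    a: str,
    a_prime: str,
    seed: int | np.random.Generator,
) -> CoarseMapping:
    """Equalize the fine-class support of two paired target categories.

    Both categories are reduced to ``min(n_a, n_a')`` fine classes; the
    smaller category is left unchanged and the larger one is reduced by a
    uniform seeded draw without replacement. All other categories pass
    through untouched. Drawn once per image in pipeline use, with the
    seed derived from (global seed, image id).
    """
    if a == a_prime:
        raise ValueError("paired target categories must be distinct")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_keep = min(len(mapping.members(a)), len(mapping.members(a_prime)))
    groups = dict(mapping.groups)
    # iteration order fixed (a then a_prime) so the draw is reproducible
    for name in (a, a_prime):
        idx = np.sort(mapping.member_array(name))
        if len(idx) > n_keep:
            keep = rng.choice(idx, size=n_keep, replace=False)
            groups[name] = frozenset(int(i) for i in keep)
    return CoarseMapping(groups=groups, n_fine=mapping.n_fine)


def save_mapping(mapping: CoarseMapping, path) -> None:
    """Write a mapping as ``name: idx,idx,...`` lines (0-based indices)."""
    with open(path, "w") as fh:
        fh.write(f"# n_fine = {mapping.n_fine}\n")
        for name, idx in mapping.groups.items():
            fh.write(f"{name}: {','.join(str(i) for i in sorted(idx))}\n")


def load_mapping(path, n_fine: int | None = None, one_based: bool = False) -> CoarseMapping:
    """Read a mapping file written by :func:`save_mapping`.

    ``one_based=True`` converts 1-based index lists on ingest.
    """
    groups: dict[str, frozenset[int]] = {}
    file_n_fine = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_fine" in line and "=" in line:
                    file_n_fine = int(line.split("=")[1])
                continue
            name, _, rest = line.partition(":")
            idx = [int(tok) for tok in rest.split(",") if tok.strip()]
            if one_based:
                idx = [i - 1 for i in idx]
            groups[name.strip()] = frozenset(idx)
    n = n_fine if n_fine is not None else file_n_fine
    if n is None:
        raise ValueError("n_fine not given and not recorded in the mapping file")
    return CoarseMapping(groups=groups, n_fine=n)


def default_mapping_for(class_names: Iterable[str]) -> CoarseMapping:
    """Deliberately unequal default grouping for the synthetic testbed.

    Groups the six built-in shape classes into three coarse categories of
    unequal support (2/3/1). All fine classes are covered here so that an
    untargeted attack cannot sink every coarse score at once by inflating
    an uncovered class; uncovered fine classes remain supported (they
    always count in the complement sum) and are exercised with custom
    mappings in the tests.
    """
    names = list(class_names)
    k = len(names)
    pools = {
        "round": ("ellipse", "annulus"),
        "boxy": ("rectangle", "bar", "cross"),
        "pointy": ("triangle",),
    }
    groups = {}
    for coarse, fine_names in pools.items():
        idx = frozenset(names.index(n) for n in fine_names if n in names)
        if idx and len(idx) < k:
            groups[coarse] = idx
    if not groups:
        raise ValueError("class names do not overlap the built-in shape classes")
    return CoarseMapping(groups=groups, n_fine=k)
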