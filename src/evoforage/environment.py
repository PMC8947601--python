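"""Random resource environments on a periodic 2-d lattice.

The environment is an ``L x L`` lattice with periodic boundaries.  Each site
carries a fixed, non-depleting resource level ``S_k``, ``k = 1..K`` (K = 5 by
default), drawn i.i.d. from a categorical distribution with weights

    w_k = A * exp(-c*k),    A = 1 / sum_j exp(-c*j),

so ``c = 0`` gives the discrete uniform distribution and ``c > 0`` makes
high-resource levels exponentially rarer.  The level of a site determines the
per-capita birth rate ``b_k`` of any agent sitting on it; birth rates are
ordered with resource level (``b`` non-decreasing).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResourceWeights",
    "ResourceLattice",
    "BirthRates",
    "exponential_weights",
    "generate_lattice",
    "neighbors",
]

#: Number of resource levels used throughout the study.
DEFAULT_K = 5

# displacement vectors of the 2d = 4 orthogonal neighbours
_NEIGHBOR_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class ResourceWeights:
    """Level-frequency distribution ``w_k``, k = 1..K.

    Parameters
    ----------
    K
        Number of resource levels.
    c
        Exponential rarity coefficient (dimensionless, >= 0).
    w
        Length-K probability vector, ``w_k = exp(-c*k) / sum_j exp(-c*j)``.
    """

    K: int
    c: float
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (self.K,):
            raise ValueError(f"weights must have shape ({self.K},), got {w.shape}")
        if np.any(w <= 0):
            raise ValueError("all weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        object.__setattr__(self, "w", w)


def exponential_weights(c: float, K: int = DEFAULT_K) -> ResourceWeights:
    """Exponential level frequencies ``w_k = exp(-c*k) / sum_j exp(-c*j)``.

    ``c = 0`` yields the discrete uniform distribution ``w_k = 1/K``; large
    ``c`` concentrates all mass on the lowest level ``k = 1``.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if c < 0:
        raise ValueError(f"c must be >= 0, got {c}")
    k = np.arange(1, K + 1, dtype=float)
    # subtract the max exponent before exponentiating so huge c cannot underflow
    # every term at once
    logw = -c * k
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return ResourceWeights(K=K, c=float(c), w=w)


@dataclass(frozen=True)
class BirthRates:
    """Per-capita birth rates ``b_k`` (events per unit time), one per level.

    Rates must be non-negative and non-decreasing in the level index: richer
    sites confer faster reproduction.
    """

    b: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("birth rates must be a non-empty 1-d vector")
        if np.any(b < 0):
            raise ValueError("birth rates must be non-negative")
        if np.any(np.diff(b) < 0):
            raise ValueError("birth rates must be non-decreasing in resource level")
        object.__setattr__(self, "b", b)

    @property
    def K(self) -> int:
        return self.b.size


@dataclass
class ResourceLattice:
    """Fixed resource environment on an ``L x L`` periodic lattice.

    ``levels`` holds the 1-based level label of every site (values in
    ``1..K``).  The lattice stays fixed across catastrophes within a run.
    """

    L: int
    K: int
    levels: np.ndarray
    c: float = 0.0
    seed: int | None = None
    d: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if levels.shape != (self.L, self.L):
            raise ValueError(f"levels must have shape ({self.L}, {self.L})")
        if levels.min() < 1 or levels.max() > self.K:
            raise ValueError(f"levels must lie in 1..{self.K}")
        self.levels = levels.astype(np.int64)

    @property
    def M(self) -> int:
        """Total number of sites, ``M = L**d``."""
        return self.L**self.d

    def level_counts(self) -> np.ndarray:
        """Number of sites of each level, length K."""
        return np.bincount(self.levels.ravel(), minlength=self.K + 1)[1:]

    def neighbors(self, x: tuple[int, int]) -> list[tuple[int, int]]:
        """The 2d = 4 orthogonal neighbours of site ``x`` with periodic wrap."""
        return neighbors(self, x)

    # -- plain-text serialization -------------------------------------------

    def to_text(self) -> str:
        """Serialize as a commented header plus one space-delimited row per
        lattice row."""
        buf = io.StringIO()
        buf.write(f"# L={self.L} K={self.K} c={self.c!r} seed={self.seed!r}\n")
        np.savetxt(buf, self.levels, fmt="%d")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ResourceLattice":
        lines = text.strip().splitlines()
        header = dict(
            item.split("=", 1) for item in lines[0].lstrip("# ").split()
        )
        levels = np.loadtxt(io.StringIO("\n".join(lines[1:])), dtype=np.int64, ndmin=2)
        seed = None if header["seed"] == "None" else int(header["seed"])
        return cls(
            L=int(header["L"]),
            K=int(header["K"]),
            levels=levels,
            c=float(header["c"]),
            seed=seed,
        )


def generate_lattice(
    L: int,
    weights: ResourceWeights,
    seed: int | np.random.Generator | None = None,
) -> ResourceLattice:
    """Draw each site's level i.i.d. from the categorical distribution ``w``.

    Reproducible: the same seed yields a bit-identical lattice.
    """
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    rng = np.random.default_rng(seed)
    levels = rng.choice(np.arange(1, weights.K + 1), size=(L, L), p=weights.w)
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return ResourceLattice(
        L=L, K=weights.K, levels=levels, c=weights.c, seed=stored_seed
    )


def neighbors(lattice: ResourceLattice, x: tuple[int, int]) -> list[tuple[int, int]]:
    """Orthogonal neighbours of ``x`` under periodic wrap, excluding ``x``."""
    i, j = x
    L = lattice.L
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"site {x} outside the {L}x{L} lattice")
    return [((i + di) % L, (j + dj) % L) for di, dj in _NEIGHBOR_STEPS]
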