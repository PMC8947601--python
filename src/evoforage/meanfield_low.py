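"""Low-density linear 5-state model and the eigenvalue effective fitness.

When the occupied fraction is small, blocking is negligible, phenotypes
decouple, and the expected per-level counts ``n_k`` of one phenotype obey the
linear system

    dn_k/dt = w_k * sum_i (b_i + gamma_i) n_i  -  gamma_k n_k,

i.e. ``dn/dt = M_gamma n`` with ``M_gamma[k, i] = w_k (b_i + gamma_i) -
delta_ki gamma_k``.  Its largest eigenvalue ``Lambda_gamma`` is the
phenotype's asymptotic growth rate; under iterated growth-and-reset dynamics
the phenotype with the largest ``Lambda`` is the sole long-run survivor, so
``Lambda`` acts as an emergent fitness function.  The spectrum is empirically
purely real with exactly one positive eigenvalue for rates in the study range.

The module also locates the exploration-exploitation transition: the critical
birth rate ``b5`` at which the ``Lambda``-maximizing hopping rate out of the
second-richest level crosses the midpoint of its range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq, minimize_scalar

from .environment import BirthRates, ResourceWeights, exponential_weights

__all__ = [
    "EigenResult",
    "BoundaryPoint",
    "build_transition_matrix",
    "effective_fitness",
    "batched_max_eigenvalues",
    "propagate_lowdensity",
    "optimal_phenotype",
    "continuous_argmax_gamma4",
    "transition_boundary",
    "fixed_point_check",
]

#: eigenvalues are asserted real to this imaginary-part tolerance
_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class EigenResult:
    """Spectrum of one phenotype's growth matrix.

    ``Lambda`` is the largest (real) eigenvalue — the effective fitness;
    ``eigvec`` its eigenvector normalized to a non-negative unit-sum level
    profile; ``all_eigs`` the full sorted spectrum.
    """

    Lambda: float
    eigvec: np.ndarray
    all_eigs: np.ndarray


@dataclass(frozen=True)
class BoundaryPoint:
    """A point (c, b5_critical) on the exploration-exploitation transition
    line: at this b5 the continuous Lambda-maximizer over gamma_4 equals the
    phenotype-range midpoint."""

    c: float
    b5_critical: float


def build_transition_matrix(
    phenotype: np.ndarray, weights: ResourceWeights, births: BirthRates
) -> np.ndarray:
    """``M[k, i] = w_k (b_i + gamma_i) - delta_ki gamma_k`` (K x K)."""
    g = np.asarray(phenotype, dtype=float)
    if g.shape != (weights.K,) or births.K != weights.K:
        raise ValueError(
            f"dimension mismatch: phenotype {g.shape}, K = {weights.K}, "
            f"births K = {births.K}"
        )
    return weights.w[:, None] * (births.b + g)[None, :] - np.diag(g)


def effective_fitness(
    phenotype: np.ndarray, weights: ResourceWeights, births: BirthRates
) -> EigenResult:
    """Largest eigenvalue ``Lambda`` of ``M_gamma`` with its eigenvector and
    the full spectrum.

    Eigenvalues are computed with a dense general solver and asserted real to
    ``|Im| < 1e-9`` rather than assumed.  An all-zero birth-rate vector gives
    ``Lambda = 0`` (no growth) and triggers a warning.
    """
    mat = build_transition_matrix(phenotype, weights, births)
    vals, vecs = np.linalg.eig(mat)
    if np.abs(vals.imag).max(initial=0.0) >= _IMAG_TOL:
        raise ArithmeticError(
            "growth matrix has a non-real eigenvalue; |Im| = "
            f"{np.abs(vals.imag).max():.3e}"
        )
    vals = vals.real
    order = np.argsort(vals)
    i_max = order[-1]
    vec = vecs[:, i_max].real
    # dominant eigenvector has single-signed components; report it non-negative
    if vec.sum() < 0:
        vec = -vec
    total = vec.sum()
    if total > 0:
        vec = vec / total
    if np.all(births.b == 0):
        warnings.warn(
            "all birth rates are zero: Lambda = 0, no growth; the reset map "
            "is degenerate",
            stacklevel=2,
        )
    return EigenResult(
        Lambda=float(vals[i_max]), eigvec=vec, all_eigs=vals[order]
    )


def batched_max_eigenvalues(
    phenotypes: np.ndarray, weights: ResourceWeights, births: BirthRates
) -> np.ndarray:
    """``Lambda`` for every row of a (G, K) phenotype array, vectorized."""
    G = np.asarray(phenotypes, dtype=float)
    mats = weights.w[None, :, None] * (births.b[None, None, :] + G[:, None, :])
    idx = np.arange(weights.K)
    mats[:, idx, idx] -= G
    vals = np.linalg.eigvals(mats)
    if np.abs(vals.imag).max(initial=0.0) >= _IMAG_TOL:
        raise ArithmeticError("growth matrix has a non-real eigenvalue")
    return vals.real.max(axis=1)


def propagate_lowdensity(
    n0: np.ndarray,
    phenotype: np.ndarray,
    weights: ResourceWeights,
    births: BirthRates,
    t: float,
) -> np.ndarray:
    """Matrix-exponential propagation ``n(t) = expm(t M_gamma) n(0)``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    n0 = np.asarray(n0, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("initial counts must be non-negative")
    mat = build_transition_matrix(phenotype, weights, births)
    return expm(t * mat) @ n0


def integrate_lowdensity_ode(
    n0: np.ndarray,
    phenotype: np.ndarray,
    weights: ResourceWeights,
    births: BirthRates,
    t: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Same propagation via a generic adaptive ODE integrator (cross-check
    for :func:`propagate_lowdensity`)."""
    mat = build_transition_matrix(phenotype, weights, births)
    sol = solve_ivp(
        lambda _, y: mat @ y, (0.0, t), np.asarray(n0, float),
        method="RK45", rtol=rtol, atol=atol,
    )
    return sol.y[:, -1]


def optimal_phenotype(
    weights: ResourceWeights,
    births: BirthRates,
    grid,
    rel_tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Grid phenotype(s) maximizing ``Lambda``.

    ``grid`` is a (G, K) array of phenotypes or any object with a
    ``phenotypes`` attribute holding one.  Returns ``(maximizers, Lambda)``
    where ``maximizers`` contains every phenotype whose ``Lambda`` is within
    relative tolerance ``rel_tol`` of the maximum (ties are reported, never
    silently broken).
    """
    phen = getattr(grid, "phenotypes", grid)
    phen = np.asarray(phen, dtype=float)
    if phen.ndim != 2 or phen.shape[0] == 0:
        raise ValueError("grid must be a non-empty (G, K) phenotype array")
    lams = batched_max_eigenvalues(phen, weights, births)
    best = lams.max()
    tie = lams >= best - rel_tol * max(1.0, abs(best))
    return phen[tie], float(best)


def continuous_argmax_gamma4(
    b5: float,
    c: float,
    *,
    K: int = 5,
    births_base: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0),
    gamma_min: float = 0.0,
    gamma_max: float = 10.0,
    xatol: float = 1e-6,
) -> float:
    """Continuous maximizer of ``Lambda`` over ``gamma_4`` in
    ``[gamma_min, gamma_max]``, with the other components held at their
    optima (``gamma_{1,2,3} = gamma_max``, ``gamma_5 = gamma_min``)."""
    weights = exponential_weights(c, K)
    births = BirthRates(np.array([*births_base, b5]))

    def neg_lambda(g4: float) -> float:
        g = np.array([gamma_max] * 3 + [g4, gamma_min])
        return -batched_max_eigenvalues(g[None, :], weights, births)[0]

    res = minimize_scalar(
        neg_lambda, bounds=(gamma_min, gamma_max), method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x)


def transition_boundary(
    c: float,
    bracket: tuple[float, float] = (3.01, 30.0),
    *,
    K: int = 5,
    births_base: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0),
    gamma_min: float = 0.0,
    gamma_max: float = 10.0,
    tol: float = 1e-3,
) -> BoundaryPoint:
    """Root-find the critical ``b5`` at which the continuous
    ``Lambda``-maximizer over ``gamma_4`` equals ``(gamma_min+gamma_max)/2``.

    The bracket must straddle the transition (maximizer on the ``gamma_min``
    side at ``bracket[0]`` and the ``gamma_max`` side at ``bracket[1]``).
    """
    mid = 0.5 * (gamma_min + gamma_max)
    kwargs = dict(
        K=K, births_base=births_base, gamma_min=gamma_min, gamma_max=gamma_max
    )

    def excess(b5: float) -> float:
        return continuous_argmax_gamma4(b5, c, **kwargs) - mid

    lo, hi = bracket
    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"bracket {bracket} does not straddle the transition at c = {c}: "
            f"argmax excess {f_lo:+.3f} and {f_hi:+.3f}"
        )
    b5c = brentq(excess, lo, hi, xtol=tol)
    return BoundaryPoint(c=float(c), b5_critical=float(b5c))


def fixed_point_check(
    phenotypes: np.ndarray,
    weights: ResourceWeights,
    births: BirthRates,
    T: float,
    N0: float,
    *,
    max_iterations: int = 100_000,
    survivor_tol: float = 1e-9,
    converge_tol: float = 1e-13,
    record_history: bool = False,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate the growth-and-reset map on a finite phenotype set.

    Every phenotype starts with equal total mass distributed over levels by
    ``w``.  Each period the per-phenotype vectors advance by
    ``expm(T M_gamma)`` and the whole population is rescaled to ``N0``.
    Returns ``(fractions, survivor_indices)`` where ``fractions`` is the
    converged share of each phenotype and survivors are those above
    ``survivor_tol``.  The survivor set equals the argmax of ``Lambda``
    (coexistence only on exact ``Lambda`` ties).  With ``record_history``
    the per-iteration fraction trajectory is returned as a third element.
    """
    phen = np.asarray(phenotypes, dtype=float)
    G = phen.shape[0]
    props = np.stack(
        [expm(T * build_transition_matrix(g, weights, births)) for g in phen]
    )
    n = np.tile(weights.w * (N0 / G), (G, 1))  # (G, K)
    frac_prev = np.full(G, 1.0 / G)
    history = [frac_prev] if record_history else None
    for _ in range(max_iterations):
        n = np.einsum("gki,gi->gk", props, n)
        n *= N0 / n.sum()
        frac = n.sum(axis=1) / N0
        if history is not None:
            history.append(frac)
        if np.abs(frac - frac_prev).max() < converge_tol:
            break
        frac_prev = frac
    survivors = np.flatnonzero(frac > survivor_tol)
    if record_history:
        return frac, survivors, np.array(history)
    return frac, survivors
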