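"""Occupancy-coupled nonlinear 5-state mean-field model.

Expected counts ``n_{k,gamma}`` of agents at resource level ``k`` with grid
phenotype ``gamma`` evolve as

    dn_kg/dt = w_k (1 - rho_k) * sum_i (b_i + gamma_i) n_ig
               - [sum_i w_i (1 - rho_i)] * gamma_k n_kg,

with ``rho_k = sum_g n_kg / (w_k M)`` the occupied fraction of level ``k``.
The occupancy factors couple every phenotype to every other; at vanishing
density the system reduces to the decoupled linear model of
:mod:`evoforage.meanfield_low`.  Between periodic resets (which rescale the
whole population back to ``N0``, preserving phenotype fractions exactly) the
system is integrated with an adaptive explicit Runge-Kutta scheme.

The phenotype space is the Cartesian grid with components from
``{0, 2, 4, 6, 8, 10}`` (6**5 = 7776 phenotypes); a restricted mode pins all
but one component to fixed values for desk-scale runs.

``curl_check`` demonstrates that this vector field is not conservative — the
matrix of mixed partial derivatives is asymmetric — so the dynamics cannot be
written as gradient ascent on any scalar fitness landscape.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .environment import BirthRates, ResourceWeights

__all__ = [
    "PhenotypeGrid",
    "MeanFieldState",
    "SummaryTable",
    "CurlCheckResult",
    "initial_state",
    "coupled_rhs",
    "integrate_with_resets",
    "summarize",
    "curl_check",
]

DEFAULT_GRID_VALUES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class PhenotypeGrid:
    """Cartesian grid of discretized phenotypes.

    ``values_per_component`` lists, per component, the hopping-rate values
    that component may take.  The full default grid is
    ``{0,2,4,6,8,10}**5`` (7776 phenotypes); pinning components to single
    values yields restricted grids.
    """

    values_per_component: tuple[tuple[float, ...], ...]

    @classmethod
    def default(
        cls, K: int = 5, values: tuple[float, ...] = DEFAULT_GRID_VALUES
    ) -> "PhenotypeGrid":
        return cls(tuple(tuple(values) for _ in range(K)))

    @classmethod
    def pinned(
        cls,
        pins: dict[int, float],
        K: int = 5,
        values: tuple[float, ...] = DEFAULT_GRID_VALUES,
    ) -> "PhenotypeGrid":
        """Grid with the components in ``pins`` (0-based index -> value)
        fixed and all others free on ``values``."""
        comps = [
            (float(pins[j]),) if j in pins else tuple(values) for j in range(K)
        ]
        return cls(tuple(comps))

    @property
    def K(self) -> int:
        return len(self.values_per_component)

    @property
    def size(self) -> int:
        out = 1
        for v in self.values_per_component:
            out *= len(v)
        return out

    @property
    def phenotypes(self) -> np.ndarray:
        """(G, K) array of all phenotype vectors, lexicographic order."""
        return np.array(
            list(itertools.product(*self.values_per_component)), dtype=float
        )


@dataclass
class MeanFieldState:
    """Expected counts ``n`` over (level k x grid phenotype), with the site
    budget ``M`` and level weights that define the occupancy bounds
    ``sum_g n_kg <= w_k M``."""

    n: np.ndarray  # (K, G)
    M: float
    weights: ResourceWeights
    grid: PhenotypeGrid

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.shape != (self.weights.K, self.grid.size):
            raise ValueError(
                f"n must have shape ({self.weights.K}, {self.grid.size})"
            )

    @property
    def level_occupancy(self) -> np.ndarray:
        """Occupied fraction ``rho_k`` of each level."""
        return self.n.sum(axis=1) / (self.weights.w * self.M)

    def check_feasible(self, tol: float = 1e-8) -> None:
        cap = self.weights.w * self.M
        if np.any(self.n < -tol * cap[:, None]):
            raise ValueError("negative expected counts beyond tolerance")
        excess = self.n.sum(axis=1) - cap
        if np.any(excess > tol * cap):
            raise ValueError("per-level occupancy bound violated")


@dataclass
class SummaryTable:
    """Per-iteration phenotype-fraction statistics of a reset run."""

    iterations: np.ndarray
    means: np.ndarray  # (n_rows, K) component means <gamma_j>
    stds: np.ndarray  # (n_rows, K) component standard deviations
    fractions: np.ndarray | None = None  # (n_rows, G) if recorded
    grid: PhenotypeGrid | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        K = self.means.shape[1]
        data = {"iteration": self.iterations}
        for j in range(K):
            data[f"mean_g{j + 1}"] = self.means[:, j]
        for j in range(K):
            data[f"std_g{j + 1}"] = self.stds[:, j]
        return pd.DataFrame(data)


def initial_state(
    N0: float, M: float, weights: ResourceWeights, grid: PhenotypeGrid
) -> MeanFieldState:
    """Uniform start: every grid phenotype holds ``N0/G`` expected agents,
    allocated across levels proportionally to ``w`` (uniform site placement
    implies level occupancy proportional to level frequency)."""
    if N0 > M:
        raise ValueError(f"N0 = {N0} exceeds the site budget M = {M}")
    G = grid.size
    n = np.tile(weights.w[:, None] * (N0 / G), (1, G))
    return MeanFieldState(n=n, M=float(M), weights=weights, grid=grid)


def _rate_tables(
    grid: PhenotypeGrid, births: BirthRates
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(level, phenotype) tables of b_k + gamma_k and gamma_k."""
    phen = grid.phenotypes  # (G, K)
    gam = phen.T  # (K, G)
    return births.b[:, None] + gam, gam


def coupled_rhs(state: MeanFieldState, births: BirthRates) -> np.ndarray:
    """Time derivative of the expected-count array (same shape as
    ``state.n``)."""
    rates, gam = _rate_tables(state.grid, births)
    return _rhs_arrays(
        state.n, rates, gam, state.weights.w, state.M
    )


def _rhs_arrays(
    n: np.ndarray,
    rates: np.ndarray,
    gam: np.ndarray,
    w: np.ndarray,
    M: float,
) -> np.ndarray:
    avail = w * (1.0 - n.sum(axis=1) / (w * M))  # w_k (1 - rho_k)
    influx = (rates * n).sum(axis=0)  # (G,) sum_i (b_i+g_i) n_ig
    return avail[:, None] * influx[None, :] - avail.sum() * gam * n


def integrate_with_resets(
    initial: MeanFieldState,
    births: BirthRates,
    T: float = 0.3,
    n_iterations: int = 700,
    N0: float | None = None,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    record_fractions: bool = False,
    occupancy_guard: float = 1e-6,
) -> SummaryTable:
    """Integrate the coupled model on ``[0, T]`` and rescale the whole
    population to ``N0`` (which leaves phenotype fractions exactly
    unchanged), repeated ``n_iterations`` times.

    Statistics are recorded at iteration 0 (the initial state) and after
    every reset.  Integration aborts if an occupancy factor drops below
    ``-occupancy_guard`` — feasibly initialized dynamics keep the factors
    non-negative without clipping.
    """
    initial.check_feasible()
    if N0 is None:
        N0 = float(initial.n.sum())
    w = initial.weights.w
    M = initial.M
    rates, gam = _rate_tables(initial.grid, births)
    K, G = initial.n.shape

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return _rhs_arrays(y.reshape(K, G), rates, gam, w, M).ravel()

    n_rows = n_iterations + 1
    means = np.empty((n_rows, K))
    stds = np.empty((n_rows, K))
    fracs = np.empty((n_rows, G)) if record_fractions else None

    state = MeanFieldState(initial.n.copy(), M, initial.weights, initial.grid)
    f, mu, sd = summarize(state)
    means[0], stds[0] = mu, sd
    if fracs is not None:
        fracs[0] = f

    n = state.n
    for it in range(1, n_rows):
        sol = solve_ivp(
            rhs, (0.0, T), n.ravel(), method="RK45", rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at iteration {it}: {sol.message}")
        n = sol.y[:, -1].reshape(K, G)
        occ = 1.0 - n.sum(axis=1) / (w * M)
        if np.any(occ < -occupancy_guard):
            raise RuntimeError(
                f"occupancy factor dropped to {occ.min():.3e} at iteration "
                f"{it}; infeasible trajectory"
            )
        n *= N0 / n.sum()  # reset: scalar rescale, fractions preserved
        state.n = n
        f, mu, sd = summarize(state)
        means[it], stds[it] = mu, sd
        if fracs is not None:
            fracs[it] = f

    return SummaryTable(
        iterations=np.arange(n_rows),
        means=means,
        stds=stds,
        fractions=fracs,
        grid=initial.grid,
    )


def summarize(
    state: MeanFieldState,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phenotype fractions ``f_g = N_g / sum N``, component means
    ``<gamma_j> = sum_g gamma_j f_g`` and standard deviations
    ``sqrt(sum_g gamma_j^2 f_g - <gamma_j>^2)``."""
    N_g = state.n.sum(axis=0)
    total = N_g.sum()
    if total <= 0:
        raise ValueError("total expected count is zero; statistics undefined")
    f = N_g / total
    phen = state.grid.phenotypes  # (G, K)
    mean = f @ phen
    second = f @ phen**2
    var = np.maximum(second - mean**2, 0.0)
    return f, mean, np.sqrt(var)


@dataclass(frozen=True)
class CurlCheckResult:
    """Asymmetry of the mixed partial derivatives of the coupled vector
    field ``Q``: ``A[(k,g),(j,a)] = dQ_kg/dn_ja - dQ_ja/dn_kg``."""

    analytic: np.ndarray
    finite_difference: np.ndarray
    max_abs: float


def _analytic_jacobian(
    n: np.ndarray,
    rates: np.ndarray,
    gam: np.ndarray,
    w: np.ndarray,
    M: float,
) -> np.ndarray:
    """Exact Jacobian dQ_kg/dn_ja, flattened to (K*G, K*G) with row-major
    (k, g) indexing."""
    K, G = n.shape
    avail = w * (1.0 - n.sum(axis=1) / (w * M))
    influx = (rates * n).sum(axis=0)  # (G,)
    phi = avail.sum()
    J = np.zeros((K, G, K, G))
    eye_g = np.eye(G)
    # -delta_jk/M * influx_g  (any alpha)
    for k in range(K):
        J[k, :, k, :] += -influx[:, None] / M
    # + gamma_k n_kg / M  (any j, alpha)
    J += (gam * n)[:, :, None, None] / M
    # + w_k(1-rho_k) (b_j + gamma^g_j) delta_ga
    J += avail[:, None, None, None] * rates.T[None, :, :, None] * eye_g[None, :, None, :]
    # - phi gamma^g_k delta_jk delta_ga
    for k in range(K):
        J[k, :, k, :] -= phi * gam[k][:, None] * eye_g
    return J.reshape(K * G, K * G)


def curl_check(
    state: MeanFieldState,
    births: BirthRates,
    *,
    fd_step: float = 1e-4,
) -> CurlCheckResult:
    """Mixed-partials asymmetry of the coupled vector field at ``state``.

    Evaluated twice — from the analytic Jacobian and from central finite
    differences of the right-hand side — and returned together with the
    maximum absolute analytic asymmetry.  A nonzero result shows the field
    is not conservative (no underlying scalar objective).
    """
    rates, gam = _rate_tables(state.grid, births)
    w, M = state.weights.w, state.M
    n = state.n
    K, G = n.shape

    J = _analytic_jacobian(n, rates, gam, w, M)
    analytic = J - J.T

    dim = K * G
    J_fd = np.empty((dim, dim))
    flat = n.ravel().copy()
    for m in range(dim):
        h = fd_step * max(1.0, abs(flat[m]))
        up, dn_ = flat.copy(), flat.copy()
        up[m] += h
        dn_[m] -= h
        qp = _rhs_arrays(up.reshape(K, G), rates, gam, w, M).ravel()
        qm = _rhs_arrays(dn_.reshape(K, G), rates, gam, w, M).ravel()
        J_fd[:, m] = (qp - qm) / (2.0 * h)
    fd = J_fd - J_fd.T
    return CurlCheckResult(
        analytic=analytic,
        finite_difference=fd,
        max_abs=float(np.abs(analytic).max()),
    )
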