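"""Agent-based Gillespie simulation of birth, relocation and catastrophes.

Agents live on the periodic lattice, at most one per site.  An agent at a site
of resource level ``k`` gives birth at rate ``b_k`` and attempts to relocate at
rate ``gamma_k``, where ``gamma`` is the agent's heritable phenotype vector
(one hopping rate per resource level, bounded in ``[gamma_min, gamma_max]``).

Events follow the direct Gillespie method with *two-step* target selection:
the waiting time is exponential with the population's total rate; an agent and
action (birth vs. hop) are chosen proportionally to their rates; only then is
the target site drawn uniformly from the 2d = 4 orthogonal neighbours.  If the
target is occupied the attempt fails — the clock still advances but the state
is unchanged.  Successful births place an offspring carrying the parent's
phenotype plus i.i.d. Gaussian noise (s.d. ``sigma``) clipped to the bounds.

There are no deaths between catastrophes.  After every period ``T`` a
catastrophe culls a uniformly random subset of agents back to the initial
population size ``N0``, blind to phenotype and position — the model's sole
selection mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import BirthRates, ResourceLattice

__all__ = [
    "SimConfig",
    "PopulationState",
    "SummaryTrajectory",
    "init_population",
    "total_rate",
    "mutate_phenotype",
    "gillespie_step",
    "run_iteration",
    "catastrophe",
    "run_evolution",
]

_NEIGHBOR_STEPS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)], dtype=np.int64)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of an evolutionary run.

    Defaults are the standard study conditions: ``N0 = 500`` agents, period
    ``T = 0.3`` (arbitrary time units), reproduction noise ``sigma = 0.05``,
    phenotype bounds ``[0, 10]``.
    """

    N0: int = 500
    T: float = 0.3
    sigma: float = 0.05
    gamma_min: float = 0.0
    gamma_max: float = 10.0
    n_iterations: int = 100
    seed: int | None = None
    snapshot_at: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not self.gamma_min < self.gamma_max:
            raise ValueError("gamma_min must be below gamma_max")
        if self.N0 < 1:
            raise ValueError("N0 must be at least 1")


class PopulationState:
    """Mutable set of agents with an occupancy index and a simulation clock.

    Agent attributes are stored column-wise in growable numpy arrays; the
    occupancy grid maps each site to the index of the agent on it (or -1).
    Per-agent birth and hop rates are cached and the total event rate is
    maintained incrementally as agents are added or moved.
    """

    def __init__(
        self,
        lattice: ResourceLattice,
        births: BirthRates,
        positions: np.ndarray,
        phenotypes: np.ndarray,
    ) -> None:
        n = len(positions)
        cap = max(16, 2 * n)
        self.lattice = lattice
        self.births = births
        self.time = 0.0
        self.iteration = 0
        self._n = n
        self._x = np.empty(cap, np.int64)
        self._y = np.empty(cap, np.int64)
        self._phen = np.empty((cap, births.K), float)
        self._rate_b = np.empty(cap, float)
        self._rate_g = np.empty(cap, float)
        self._x[:n] = positions[:, 0]
        self._y[:n] = positions[:, 1]
        self._phen[:n] = phenotypes
        lev = lattice.levels[self._x[:n], self._y[:n]] - 1
        self._rate_b[:n] = births.b[lev]
        self._rate_g[:n] = self._phen[np.arange(n), lev]
        self.occupancy = np.full((lattice.L, lattice.L), -1, np.int64)
        if len(np.unique(positions, axis=0)) != n:
            raise ValueError("agents must occupy distinct sites")
        self.occupancy[self._x[:n], self._y[:n]] = np.arange(n)
        self._total = float(self._rate_b[:n].sum() + self._rate_g[:n].sum())

    # -- views ---------------------------------------------------------------

    @property
    def n_agents(self) -> int:
        return self._n

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of agent coordinates (read-only view)."""
        return np.stack([self._x[: self._n], self._y[: self._n]], axis=1)

    @property
    def phenotypes(self) -> np.ndarray:
        return self._phen[: self._n]

    @property
    def agent_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-agent (birth, hop) rate arrays at the agents' current sites."""
        return self._rate_b[: self._n], self._rate_g[: self._n]

    @property
    def total_event_rate(self) -> float:
        """Incrementally maintained total rate; cross-check with
        :func:`total_rate`."""
        return self._total

    def levels(self) -> np.ndarray:
        """1-based resource level of each agent's current site."""
        return self.lattice.levels[self._x[: self._n], self._y[: self._n]]

    # -- mutation ------------------------------------------------------------

    def _grow(self) -> None:
        for name in ("_x", "_y", "_rate_b", "_rate_g"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.empty_like(arr)]))
        self._phen = np.concatenate([self._phen, np.empty_like(self._phen)])

    def add_agent(self, x: int, y: int, phenotype: np.ndarray) -> None:
        if self.occupancy[x, y] != -1:
            raise ValueError(f"site ({x}, {y}) already occupied")
        if self._n == len(self._x):
            self._grow()
        i = self._n
        self._x[i] = x
        self._y[i] = y
        self._phen[i] = phenotype
        lev = self.lattice.levels[x, y] - 1
        self._rate_b[i] = self.births.b[lev]
        self._rate_g[i] = phenotype[lev]
        self.occupancy[x, y] = i
        self._n += 1
        self._total += self._rate_b[i] + self._rate_g[i]

    def move_agent(self, i: int, x: int, y: int) -> None:
        if self.occupancy[x, y] != -1:
            raise ValueError(f"site ({x}, {y}) already occupied")
        self._total -= self._rate_b[i] + self._rate_g[i]
        self.occupancy[self._x[i], self._y[i]] = -1
        self._x[i] = x
        self._y[i] = y
        lev = self.lattice.levels[x, y] - 1
        self._rate_b[i] = self.births.b[lev]
        self._rate_g[i] = self._phen[i, lev]
        self.occupancy[x, y] = i
        self._total += self._rate_b[i] + self._rate_g[i]

    def keep_subset(self, idx: np.ndarray) -> None:
        """Retain only the agents listed in ``idx`` (catastrophe survivors)."""
        n = len(idx)
        self._x[:n] = self._x[idx]
        self._y[:n] = self._y[idx]
        self._phen[:n] = self._phen[idx]
        self._rate_b[:n] = self._rate_b[idx]
        self._rate_g[:n] = self._rate_g[idx]
        self._n = n
        self.occupancy.fill(-1)
        self.occupancy[self._x[:n], self._y[:n]] = np.arange(n)
        self._total = float(self._rate_b[:n].sum() + self._rate_g[:n].sum())

    def refresh_rates(self) -> None:
        """Recompute the cached per-agent rates and the total (needed after
        editing phenotypes in place)."""
        n = self._n
        lev = self.lattice.levels[self._x[:n], self._y[:n]] - 1
        self._rate_b[:n] = self.births.b[lev]
        self._rate_g[:n] = self._phen[np.arange(n), lev]
        self._total = float(self._rate_b[:n].sum() + self._rate_g[:n].sum())

    def check_consistency(self) -> None:
        """Assert the occupancy index and agent list agree (single occupancy)."""
        occ_sites = np.argwhere(self.occupancy >= 0)
        assert len(occ_sites) == self._n, "occupied-site count != agent count"
        idx = self.occupancy[self._x[: self._n], self._y[: self._n]]
        assert np.array_equal(np.sort(idx), np.arange(self._n)), (
            "occupancy index inconsistent with agent positions"
        )


@dataclass
class SummaryTrajectory:
    """Per-iteration summary of an evolutionary run.

    Row 0 describes the initial population; row ``l >= 1`` the population at
    the end of iteration ``l``, *before* that iteration's catastrophe.
    ``snapshots`` maps an iteration index to the full per-agent table recorded
    there (post-cull, i.e. the population entering the next iteration).
    """

    iterations: np.ndarray
    count_before_cull: np.ndarray
    means: np.ndarray  # (n_rows, K)
    stds: np.ndarray  # (n_rows, K)
    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        K = self.means.shape[1]
        data = {"iteration": self.iterations, "count_before_cull": self.count_before_cull}
        for j in range(K):
            data[f"mean_g{j + 1}"] = self.means[:, j]
        for j in range(K):
            data[f"std_g{j + 1}"] = self.stds[:, j]
        return pd.DataFrame(data)


def init_population(
    N0: int,
    lattice: ResourceLattice,
    births: BirthRates,
    bounds: tuple[float, float] = (0.0, 10.0),
    seed: int | np.random.Generator | None = None,
) -> PopulationState:
    """Place ``N0`` agents on distinct uniformly random sites with phenotype
    components i.i.d. uniform on ``[gamma_min, gamma_max]``."""
    if N0 > lattice.M:
        raise ValueError(f"N0 = {N0} exceeds lattice capacity M = {lattice.M}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(lattice.M, size=N0, replace=False)
    xs, ys = np.unravel_index(flat, (lattice.L, lattice.L))
    lo, hi = bounds
    phen = rng.uniform(lo, hi, size=(N0, births.K))
    return PopulationState(
        lattice, births, np.stack([xs, ys], axis=1), phen
    )


def total_rate(
    pop: PopulationState, lattice: ResourceLattice, births: BirthRates
) -> float:
    """Recompute ``sum_agents [b(s_x) + gamma(s_x)]`` from scratch.

    The simulation maintains this quantity incrementally
    (``pop.total_event_rate``); this full recomputation is the reference.
    """
    lev = lattice.levels[pop.positions[:, 0], pop.positions[:, 1]] - 1
    b = births.b[lev]
    g = pop.phenotypes[np.arange(pop.n_agents), lev]
    return float(b.sum() + g.sum())


def mutate_phenotype(
    parent: np.ndarray,
    sigma: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring phenotype: parent plus N(0, sigma^2) per component, clipped
    to the closest boundary value."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    child = parent + rng.normal(0.0, sigma, size=parent.shape)
    np.clip(child, bounds[0], bounds[1], out=child)
    return child


def gillespie_step(
    pop: PopulationState,
    lattice: ResourceLattice,
    births: BirthRates,
    rng: np.random.Generator,
    sigma: float = 0.05,
    bounds: tuple[float, float] = (0.0, 10.0),
    t_max: float | None = None,
) -> PopulationState:
    """Advance the population by one Gillespie event.

    The clock advances by an exponential waiting time with the current total
    rate.  If ``t_max`` is given and the event would occur beyond it, the
    clock is set to ``t_max`` and no event takes place (also the behaviour
    when the total rate is zero).  Otherwise one agent is picked with
    probability proportional to ``b + gamma`` at its site; the action is a
    birth with probability ``b/(b+gamma)``, else a hop; the target is a
    uniformly random orthogonal neighbour, and an occupied target makes the
    attempt fail with no state change.
    """
    tot = pop.total_event_rate
    if tot <= 0.0:
        if t_max is None:
            raise RuntimeError("no event possible: total rate is zero")
        pop.time = t_max
        return pop
    dt = rng.exponential(1.0 / tot)
    if t_max is not None and pop.time + dt >= t_max:
        pop.time = t_max
        return pop
    pop.time += dt

    rb, rg = pop.agent_rates
    r = rng.random() * tot
    cum = np.cumsum(rb + rg)
    # guard against roundoff pushing r past the last cumulative value
    a = min(int(np.searchsorted(cum, r, side="right")), pop.n_agents - 1)
    prev = cum[a - 1] if a > 0 else 0.0
    is_birth = (r - prev) < rb[a]

    step = _NEIGHBOR_STEPS[rng.integers(0, 4)]
    L = lattice.L
    tx = (pop._x[a] + step[0]) % L
    ty = (pop._y[a] + step[1]) % L
    if pop.occupancy[tx, ty] != -1:
        return pop  # unsuccessful attempt: clock advanced, nothing else
    if is_birth:
        child = mutate_phenotype(pop.phenotypes[a], sigma, bounds, rng)
        pop.add_agent(tx, ty, child)
    else:
        pop.move_agent(a, tx, ty)
    return pop


def run_iteration(
    pop: PopulationState,
    lattice: ResourceLattice,
    births: BirthRates,
    T: float,
    rng: np.random.Generator,
    sigma: float = 0.05,
    bounds: tuple[float, float] = (0.0, 10.0),
) -> PopulationState:
    """Run Gillespie events until the clock reaches ``T``, then reset the
    clock to 0 and increment the iteration counter."""
    if T <= 0:
        raise ValueError("T must be positive")
    while pop.time < T:
        gillespie_step(pop, lattice, births, rng, sigma, bounds, t_max=T)
    pop.time = 0.0
    pop.iteration += 1
    return pop


def catastrophe(
    pop: PopulationState, N0: int, rng: np.random.Generator
) -> PopulationState:
    """Cull a uniformly random subset back to ``N0`` agents (phenotype- and
    location-blind).  No-op when the population does not exceed ``N0``."""
    if pop.n_agents > N0:
        keep = rng.choice(pop.n_agents, size=N0, replace=False)
        pop.keep_subset(keep)
    return pop


def _snapshot_frame(pop: PopulationState, iteration: int) -> pd.DataFrame:
    lev = pop.levels()
    data = {
        "x": pop.positions[:, 0],
        "y": pop.positions[:, 1],
        "level": lev,
    }
    for j in range(pop.births.K):
        data[f"g{j + 1}"] = pop.phenotypes[:, j].copy()
    frame = pd.DataFrame(data)
    frame["iteration"] = iteration
    return frame


def run_evolution(
    config: SimConfig,
    lattice: ResourceLattice,
    births: BirthRates,
) -> SummaryTrajectory:
    """Alternate growth iterations and catastrophes for
    ``config.n_iterations``.

    A master seed spawns independent streams for initialization, event
    dynamics, and culling, so culling randomness can be held fixed across
    parameter sweeps.  Phenotype means and standard deviations are recorded
    every iteration (pre-cull); full per-agent snapshots only at the
    iterations listed in ``config.snapshot_at`` (post-cull).
    """
    ss = np.random.SeedSequence(config.seed)
    init_rng, dyn_rng, cull_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    bounds = (config.gamma_min, config.gamma_max)
    pop = init_population(config.N0, lattice, births, bounds, init_rng)

    n_rows = config.n_iterations + 1
    counts = np.empty(n_rows, np.int64)
    means = np.empty((n_rows, births.K))
    stds = np.empty((n_rows, births.K))
    snapshots: dict[int, pd.DataFrame] = {}

    counts[0] = pop.n_agents
    means[0] = pop.phenotypes.mean(axis=0)
    stds[0] = pop.phenotypes.std(axis=0)
    if 0 in config.snapshot_at:
        snapshots[0] = _snapshot_frame(pop, 0)

    for it in range(1, config.n_iterations + 1):
        run_iteration(
            pop, lattice, births, config.T, dyn_rng, config.sigma, bounds
        )
        counts[it] = pop.n_agents
        means[it] = pop.phenotypes.mean(axis=0)
        stds[it] = pop.phenotypes.std(axis=0)
        catastrophe(pop, config.N0, cull_rng)
        if it in config.snapshot_at:
            snapshots[it] = _snapshot_frame(pop, it)

    return SummaryTrajectory(
        iterations=np.arange(n_rows),
        count_before_cull=counts,
        means=means,
        stds=stds,
        snapshots=snapshots,
    )
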