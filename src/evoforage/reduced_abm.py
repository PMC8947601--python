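"""Stochastic 5-state agent-based model without spatial structure.

Each agent carries only a resource-level index and a phenotype.  An agent at
level ``k`` births at rate ``b_k`` and hops at rate ``gamma_k``; the target
level of either action is drawn from the level-frequency distribution ``w``,
and the attempt succeeds with probability equal to the target level's current
vacancy fraction ``1 - count/capacity`` (the stochastic realization of the
coupled mean-field occupancy factors; the well-mixed counterpart of lattice
blocking).  Reproduction noise, clipping and catastrophes are shared with the
full lattice model.

Comparing this model with the spatial one isolates the effect of the
well-mixed approximation: the 5-state dynamics converge on the mean-field
timescale (hundreds of catastrophes) rather than the spatial model's tens of
thousands.
"""

from __future__ import annotations

import warnings

import numpy as np

from .abm import SimConfig, SummaryTrajectory, mutate_phenotype
from .environment import BirthRates, ResourceWeights

__all__ = ["level_capacities", "run_reduced"]


def level_capacities(weights: ResourceWeights, M: int) -> np.ndarray:
    """Integer per-level capacities, ``round(w_k * M)`` half-up.

    Warns when rounding makes the capacities not sum to ``M``.
    """
    cap = np.floor(weights.w * M + 0.5).astype(np.int64)
    if cap.sum() != M:
        warnings.warn(
            f"rounded level capacities sum to {cap.sum()} != M = {M}",
            stacklevel=2,
        )
    return cap


def run_reduced(
    config: SimConfig,
    weights: ResourceWeights,
    births: BirthRates,
    M: int,
    initial_phenotypes: np.ndarray | None = None,
) -> SummaryTrajectory:
    """Gillespie dynamics of the 5-state model with periodic catastrophes.

    Mirrors :func:`evoforage.abm.run_evolution`: independent RNG streams for
    initialization, dynamics and culling; per-iteration pre-cull phenotype
    means/standard deviations; growth capped by the per-level capacities.

    ``initial_phenotypes`` overrides the uniform phenotype draw: a single
    (K,) vector shared by all agents, or an (N0, K) array — useful for
    fixed-phenotype competition experiments and mean-field cross-checks.
    """
    if config.N0 > M:
        raise ValueError(f"N0 = {config.N0} exceeds total capacity M = {M}")
    K = weights.K
    cap = level_capacities(weights, M)
    ss = np.random.SeedSequence(config.seed)
    init_rng, dyn_rng, cull_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    bounds = (config.gamma_min, config.gamma_max)

    # initial placement: levels by w, thinned by capacity
    n = config.N0
    size = max(16, 2 * n)
    level = np.empty(size, np.int64)  # 0-based level index
    phen = np.empty((size, K), float)
    counts = np.zeros(K, np.int64)
    placed = 0
    while placed < n:
        k = init_rng.choice(K, p=weights.w)
        if counts[k] < cap[k]:
            level[placed] = k
            counts[k] += 1
            placed += 1
    if initial_phenotypes is None:
        phen[:n] = init_rng.uniform(*bounds, size=(n, K))
    else:
        init = np.asarray(initial_phenotypes, dtype=float)
        phen[:n] = init if init.ndim == 2 else np.tile(init, (n, 1))

    n_rows = config.n_iterations + 1
    traj_counts = np.empty(n_rows, np.int64)
    means = np.empty((n_rows, K))
    stds = np.empty((n_rows, K))
    traj_counts[0] = n
    means[0] = phen[:n].mean(axis=0)
    stds[0] = phen[:n].std(axis=0)

    b = births.b
    for it in range(1, n_rows):
        t = 0.0
        while True:
            rb = b[level[:n]]
            rg = phen[np.arange(n), level[:n]]
            tot = rb.sum() + rg.sum()
            if tot <= 0:
                break
            t += dyn_rng.exponential(1.0 / tot)
            if t >= config.T:
                break
            r = dyn_rng.random() * tot
            cum = np.cumsum(rb + rg)
            a = min(int(np.searchsorted(cum, r, side="right")), n - 1)
            prev = cum[a - 1] if a > 0 else 0.0
            is_birth = (r - prev) < rb[a]
            target = dyn_rng.choice(K, p=weights.w)
            vacancy = 1.0 - counts[target] / cap[target] if cap[target] > 0 else 0.0
            if dyn_rng.random() >= vacancy:
                continue  # blocked: clock advanced, state unchanged
            if is_birth:
                if n == len(level):
                    level = np.concatenate([level, np.empty_like(level)])
                    phen = np.concatenate([phen, np.empty_like(phen)])
                phen[n] = mutate_phenotype(
                    phen[a], config.sigma, bounds, dyn_rng
                )
                level[n] = target
                counts[target] += 1
                n += 1
            else:
                counts[level[a]] -= 1
                level[a] = target
                counts[target] += 1

        traj_counts[it] = n
        means[it] = phen[:n].mean(axis=0)
        stds[it] = phen[:n].std(axis=0)
        if n > config.N0:
            keep = cull_rng.choice(n, size=config.N0, replace=False)
            level[: config.N0] = level[keep]
            phen[: config.N0] = phen[keep]
            n = config.N0
            counts = np.bincount(level[:n], minlength=K)

    return SummaryTrajectory(
        iterations=np.arange(n_rows),
        count_before_cull=traj_counts,
        means=means,
        stds=stds,
    )
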