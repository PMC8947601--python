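# Methods

## Model definition

The environment is an `L × L` lattice (periodic boundaries, `M = L²` sites,
default `L = 128`).  Each site carries one of `K = 5` resource levels,
sampled i.i.d. from `w_k = e^{−ck} / Σ_j e^{−cj}` (`c = 0`: uniform).  The
lattice is generated once and held fixed across all catastrophes of a run;
independent runs may re-randomize it.  Levels are labelled 1-based (`S₁…S₅`)
to match standard usage; sites are indexed 0-based internally.

Agents occupy sites exclusively (capacity 1).  The phenotype is the vector
of per-level relocation rates **γ** ∈ [γ_min, γ_max]⁵ = [0, 10]⁵; the upper
bound stands in for un-modelled metabolic constraints.  Per-capita birth
rates `b = (b₁ ≤ … ≤ b₅)` attach to sites, not phenotypes: default
`(0, 1, 2, 3, 4)` in the lattice simulations and `(0, 1, 2, 3, 5)` in
mean-field runs, where the slightly larger `b₅` compensates the mean-field
shift of the critical birth rate so both models sit on the same side of the
γ₄ transition.

### Gillespie dynamics (two-step target selection)

The total event rate is `Σ_agents [b(s_x) + γ(s_x)]`, maintained
incrementally (only the moved or born agent's contribution changes; tests
assert equality with full recomputation).  Waiting times are exponential in
that rate.  The chosen agent acts as birth with probability `b/(b+γ)`, else
hop; only then is the target drawn uniformly from the 4 neighbours.  An
occupied target makes the attempt fail — the clock still advances.  This
two-step scheme is the canonical implementation here; the alternative
one-step scheme (each of the 2d directed events entered separately into the
total rate) is equivalent only after rescaling all rates by 1/2d, which is
why the mean-field equations below carry bare rates.  Events that would
occur beyond the period horizon `T` do not execute.  Offspring phenotypes
are the parent's plus i.i.d. N(0, σ²) per component (σ = 0.05), clipped to
the nearest bound.  After each period `T = 0.3` (arbitrary time units) a
catastrophe keeps a uniform random subset of `N₀` agents; if the population
does not exceed `N₀` (e.g. degenerate all-zero birth rates) nothing is
culled.  One master seed spawns three independent RNG streams —
initialization, dynamics, culling — so culling randomness can be held fixed
across parameter sweeps.

### Low-density linear model

With blocking neglected, each phenotype's expected per-level counts obey
`dn/dt = M_γ n` with `M_γ[k,i] = w_k(b_i + γ_i) − δ_ki γ_k`.  Propagation
uses the dense matrix exponential.  Eigenvalues come from a general dense
solver; the claim that the spectrum is purely real with a single positive
eigenvalue is *asserted* (|Im| < 1e−9) rather than assumed, and verified
over 50 000 uniform-random rate draws in the acceptance suite.  The reset
map multiplies every phenotype's vector by one common scalar, so phenotype
fractions are preserved exactly and the long-run survivor is the argmax of
`Λ_γ`; `fixed_point_check` verifies this by direct iteration.  Ties in the
grid argmax are reported as a set (relative tolerance 1e−10), never broken
silently.  All-zero birth rates return `Λ = 0` with a warning.

The transition boundary `B₅c(c)` is the root of
`argmax_{γ₄∈[0,10]} Λ(γ₄; b₅, c) = 5` with γ₁,₂,₃ = 10 and γ₅ = 0 held at
their optima.  The inner argmax is continuous (bounded scalar minimization,
tolerance 1e−6); the outer root-find is Brent's method to 1e−3 in `b₅`.
Because the argmax sweeps through the interior only in a narrow `b₅`
window, the objective behaves as a sign change and bisection-style
convergence is what matters.  Whether the boundary should re-optimize all
five components jointly is genuinely open; pinning the other components at
their optima is the definition adopted here, consistent with treating γ₄ as
the order parameter.

### Coupled nonlinear model

The occupancy-coupled system (see README) is integrated per period with
SciPy's adaptive explicit Runge–Kutta 5(4) scheme, rtol 1e−6 / atol 1e−9;
rates ≤ 10 and `T = 0.3` make the system non-stiff.  The phenotype space is
the grid `{0,2,4,6,8,10}⁵` (7776 phenotypes); the initial state gives every
grid phenotype the mass `N₀/G`, spread over levels proportionally to `w_k`
(uniform placement implies it), using the real-valued capacities `w_k M`
directly.  Occupancy factors are not clipped during integration — feasibly
initialized trajectories keep them non-negative — but a guard aborts if a
factor drops below −1e−6, and feasibility (non-negativity, per-level bounds)
is checked on the initial state.  Resets rescale the whole array by
`N₀/Σn`, preserving fractions to machine precision (tested at 1e−12).

A restricted mode pins components (typically γ₁,₂,₃ = 10, γ₅ = 0, leaving
γ₄ ∈ {0,…,10}) and shrinks 7776 phenotypes to 6.  At 3.1% density the
restricted and full-grid runs agree on the γ₄ trajectory to ~0.01 at
iteration 700, because the pinned components are under strong uniform
selection; the restriction is the desk-scale surrogate used by the
acceptance script.  Long-run statistics are taken at 2000 reset iterations,
the point at which the mean γ₄ at 3.1% density has closed to within a
quarter grid step of its asymptote (8.85 at 700 iterations, 9.75 at 2000,
limit 10).

`curl_check` differentiates the coupled vector field analytically per
phenotype pair (exact for all pairs, including the density-dependent terms)
and cross-checks against central finite differences; the asymmetry of the
Jacobian proves the field is not conservative, so the dynamics cannot be
gradient ascent on any scalar objective.

### Reduced 5-state stochastic model

Agents carry a level index instead of coordinates.  Birth and hop rates are
as in the lattice model; the target *level* of either action is drawn from
`w`, and the attempt succeeds with probability equal to the target level's
vacancy fraction `1 − count_k/capacity_k`.  No reference prescribes this
blocking rule; vacancy-fraction acceptance is this package's choice, made
because it is the exact stochastic realization of the coupled model's
occupancy factors and reduces to the lattice rule when agents are well
mixed.  Capacities round half-up from `w_k M`, with a warning when rounding
breaks `Σ capacities = M`.  Mutation, clipping and catastrophe logic are
imported from the lattice module, so a fix there propagates.

## What the generator emulates — and what passing tests do not show

All inputs are synthetic by design: the environment generator *is* the
study's environment model (i.i.d. levels, fixed in time, non-depleting).
Real foraging landscapes are spatially correlated, time-varying and
consumable, and real organisms sense more than their current site; results
here say nothing about those regimes.  Within the model, the 5-state
reductions assume well-mixedness.  That assumption fails quantitatively on
the lattice: a recurrent 2-d walk on quenched disorder discovers rare rich
sites more slowly than the level-frequency argument implies, so per-level
counts match the linear model only on horizons shorter than the hopping
time (verified at T = 0.05), fall measurably short on the richest level
over a full period (~20% at T = 0.3 for a maximal explorer), and the full
spatial model needs ~30× more catastrophes to converge than the 5-state
models.  The diagnostics module measures this directly: the site-averaged
well-mixed error is an algebraic zero on every snapshot, while its spread
and the nearest-neighbour occupancy covariance peak at intermediate
densities.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in well under a minute: one-period ABM growth uses the standard
`L = 128`, `N₀ = 500` with 20 replicate seeds; selection-trajectory checks
use `L = 64` / 250 iterations (lattice) and `M = 4800` / 500 iterations
(reduced model); the coupled model uses the restricted 6-phenotype grid.
The full-scale experiments (20 000 iterations × 20 trials, full 7776-
phenotype density sweeps) reproduce at proportionally longer runtimes via
the same entry points, e.g. `evoforage abm --iterations 20000`.

## Known limitations

* Two-step event selection only; the one-step scheme is documented above
  but not implemented.
* No stochastic (asynchronous) death, sexual reproduction, metabolic
  budgets, resource consumption, agent memory or sensing beyond the current
  site; no spatially correlated environments.
* The spatially resolved mean-field equations are used only to justify the
  5-state reduction, not integrated.
* Near-tied phenotypes (`Λ` gaps → 0) sort arbitrarily slowly under the
  reset map; `fixed_point_check` bounds its iteration count and reports
  coexistence below the survivor threshold instead of running forever.
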