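# Methods

## Model structure and assumptions

All dynamics are deterministic mass-action ODEs over concentrations in
arbitrary units and dimensionless time. Antibody and the B-cell clone
producing it are identified (one state per clone); T-cell biology enters
only through the stimulation coefficient `k4`. Somatic hypermutation is
modeled as an *expected* redistribution of production flux, not as
stochastic sampling — there is no random number generation in the core.

**Single-antibody system.** States: complex `x`, free antibody `y`,
antigen `z`; processes: reversible binding (`k2`, `k_minus2`), complex
clearance (`k3`), complex-stimulated antibody production (`k4`), antibody
decay (`k6`), and — for pathogens — antigen replication/degradation
(`k1`, `k5`). Self-antigens are held constant (`dz/dt = 0`): the host
replenishes them as fast as binding consumes them. The deletion-vs-expansion
dichotomy is purely kinetic: production `k4·x` competes with clearance
`k3·x`, so the sign of the clone's net growth flips with `k4`.

**Competition variant.** Several clones with individual `k2_j`,
`k_minus2_j` share one pathogen; the antigen balance sums each clone's
binding fluxes on top of net replication. This is the natural mass-action
generalization; it reduces exactly to the single-antibody pathogen system
for one clone, which the tests check.

**Repertoire system.** Nine affinity classes, each a copy of the
self-antigen kinetics with class-specific `k2_i` (1e−13 … 1e−5, one decade
per class) and shared `k_minus2 = 1e−18`, so log10-Kd runs −5 … −13 and
class 5 sits at the mean of the empirical log10-Kd distribution
Normal(−9, 1) (taken as given; re-fitting it is out of scope). Of the
production flux `k4·x_i`, a fraction `1 − p` is an exact copy and a
fraction `p` is redistributed by the mutation kernel. Mutation acts only
on *production*; existing antibody never converts.

## The mutation kernel

A mutant offspring's log10-Kd is conceptually redrawn from Normal(−9, 1).
All mass strictly on the weaker-binding side of class *i*'s unit bin is
lumped into class *i−1*, all mass on the stronger side into class *i+1*,
and the bin's own mass is "stay". Class indices ascend with binding
strength, which fixes the direction of each lump; the worked class-6
numbers (0.6915 toward class 5, 0.2417 stay, 0.0668 toward class 7) pin
the convention down. Mass that would leave the grid at either end is
folded into "stay" — this keeps rows summing to 1 without inventing
classes, and the affected mass is < 3e−4 under the defaults, so results
are insensitive to the choice. "Stay" is computed as
`1 − p_weaker − p_stronger` so rows sum to 1 exactly in floating point.
`mu`, `sigma` and the bin width are parameters (defaults −9, 1, 1) so
finer discretizations can be explored, but only the 9-class presets are
shipped. Class skipping (more than one class per mutation event) is
deliberately outside the construction: the tails are lumped, not spread.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` with LSODA (adaptive,
  stiffness-switching), sampled on a uniform grid. Default tolerances
  `rtol = 1e−8`, `atol = 1e−6` (state magnitudes span 1 … 3e7).
* Negative undershoot beyond `−10·atol` raises an integration error
  rather than being clipped: clipping would mask stiffness failures.
* The `shm_foreign` preset overrides the tolerances to `rtol = 1e−10`,
  `atol = 1e−12` because the maturation cascade passes through
  intermediate classes whose concentrations sit many decades below the
  seeded clone; at the default `atol` those fluxes are treated as noise
  and the p = 0 member's bare exponential decay to ~1e−4 wobbles
  negative past the undershoot guard.
* Reduction checks (repertoire at `p = 0` vs per-class single-antibody
  runs, 1e−6 relative) integrate both sides at `rtol = 1e−10` so solver
  error sits well below the comparison tolerance.
* The fixed-step RK4 oracle used in tests is hand-written and independent
  of scipy's adaptive code path; it runs at `dt = t_end/1e5`.
* Ties in `dominant_class` break toward the lower class index —
  deterministic, and ties are measure-zero in practice.
* Composition is reported as NaN when total antibody is exactly zero.

## Scenario presets and horizons

The five presets carry the canonical parameter sets; time is
dimensionless and the experiments state no time scale, so horizons are
package constants fixed by stated stopping rules:

| preset | t_end | stopping rule |
|---|---|---|
| `clonal_deletion` | 20 | strong binder crosses 10% of y(0) at t ≈ 9.4; contrast fully developed |
| `pathogen_selection` | 200 | pathogen cleared; clone abundances separated by affinity |
| `shm_self_tolerance` | 300 | every class, including slow mid-grid ones fed by mutation, past its peak |
| `shm_foreign` | 1000 | strong-binder takeoff overtakes the seeded clone's decay (t ≈ 800) |
| `aging_sweep` | 400 | composition shift saturates (class 7 dominant at p = 0.2 from t ≈ 100) |

`aging_sweep` also reports a ladder of intermediate times (0, ⅛, ¼, ½,
¾, 1 × t_end) to expose the composition's evolution. The `shm_foreign`
preset seeds the weakest-binding class (k2 = 1e−13) so affinity
maturation out of a poor repertoire is observable; the seeded class is a
constructor argument for users who want a different starting point.

## What the scenarios do and do not emulate

The presets *are* the study conditions: initial concentrations (y(0) =
1e5 or a normal-composition 1e6, z(0) = 2e6 … 3e7) and rate constants are
the published sets, not fitted to data. They capture the qualitative
mechanisms — deletion orderings, maturation cascades, composition drift —
under constant antigen and a single shared `k4` per scenario. They do not
model T-cell populations explicitly, regulatory suppression, stochastic
extinction of small clones (concentrations are continuous, so a clone can
shrink to 1e−10 and still re-expand), antigen depletion by a successful
self-response, or calendar-time units. Passing tests therefore certify
the mechanism's internal kinetic logic, not quantitative agreement with
any organism.

## Known limitations

* With `k4 > k3` and no SHM, strong-binding classes grow exponentially
  without saturation (no carrying capacity); long horizons produce very
  large finite numbers (≈1e34 in `aging_sweep` at p = 0) that are
  meaningful only as orderings.
* The mutation kernel is affinity-space only; sequence-level effects,
  lethal mutations and class-skipping are not represented.
* `metrics` identifies Model 2 trajectories by their leading `z` column;
  hand-built trajectories must follow the `z, x_1.., y_1..` layout.
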