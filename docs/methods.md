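# Methods

## Model

`gogrow` simulates a population of tumor cells on a 2-D periodic square
lattice using a lattice-gas cellular automaton (LGCA). Each node carries
`K` channels, each holding at most one cell (exclusion principle): `b = 4`
velocity channels (east, north, west, south) hold migratory cells, the
remaining `K − b` rest channels hold proliferative cells. `K` is the local
carrying capacity; `ϱ = n/K` is the local density. One time step composes
three operators, applied independently at every node:

1. **Reaction** — every cell dies with probability `r_d`; every surviving
   resting cell divides with probability `r_b` into a free rest channel of
   the same node (the attempt silently fails at capacity); every surviving
   cell then redraws its phenotype, resting with probability `r_s(ϱ)` and
   moving otherwise, where

       r_s(ϱ) = ½ (1 + tanh(κ (ϱ − θ))),   ϱ ∈ [0, 1].

2. **Reorientation** — a uniform random permutation of the velocity-channel
   occupancies at each node.
3. **Propagation** — each migratory cell moves one lattice unit in its
   channel direction (deterministic, periodic wrap).

`κ > 0` is *attractive* plasticity (motility falls with crowding — contact
inhibition of migration); `κ < 0` is *repulsive* (cells escape crowded
regions); `θ` is the density at which both phenotypes are equally likely.

### Rules the operator composition does not fix

The published rule set constrains the operators but not every microscopic
tie-break. The following choices are this package's own, each isolated
behind one function so alternatives are a local change:

* **Reaction sub-order** death → birth → switch, all using the node density
  measured at entry to the reaction step for `r_s`. This keeps the switch
  consistent with the fast-switching mean-field derivation.
* **Phenotype redraw semantics**: each cell's next phenotype is resting
  with probability `r_s` regardless of its current phenotype, which
  reproduces the equilibrium fractions `r_s` / `1 − r_s`. Cells are
  processed in uniformly random per-node order; a cell whose target class
  has no free channel at its turn keeps its class (blocking preserves the
  exclusion principle without losing cells). Offspring born in the same
  step do not redraw until the next step.
* **Birth conflicts** are resolved by capping simultaneous divisions at the
  number of free rest channels, filled in uniformly random channel order —
  equivalent in law to sequential resolution in random cell order.
* **Destination channels** within a class are taken first-free rather than
  uniformly at random: channels of a class are exchangeable under every
  operator (reorientation re-randomizes velocity channels immediately), so
  the law is unchanged.
* **Extinction** is the absorbing state `n_total = 0`; simulations halt
  there and flag it.

One root seed drives a single `numpy` generator consumed in a fixed
documented order (death draws, birth counts, birth placement, switch
desires, switch processing order, reorientation), so every trajectory is
bit-reproducible from its seed.

## Mean-field companion

Assuming phenotype switching equilibrates much faster than birth/death, the
resting fraction at density ρ is `r_s(ρ)` and the automaton coarse-grains
to

    ∂t ρ = ∂x( D(ρ) ∂x ρ ) + F(ρ),
    F(ρ) = R_b r_s(ρ) ρ (1 − ρ) − R_d ρ,

with `R_b ≈ r_b/τ`, `R_d ≈ r_d/τ`; all figure-level work uses `τ = 1` so
the rates are per automaton step. `find_fixed_points` scans `F` on a
20 001-point grid, polishes roots by Brent bisection (tolerance 1e−10) and
classifies stability by the sign of the analytic `F′` (|F′| < 1e−8 is
labelled marginal); these tolerances resolve all reference cases with two
orders of magnitude to spare. The regime is *bistable* iff ρ = 0 is stable
and a stable positive root exists — the emergent Allee effect: bistability
holds exactly when `κ > 0` and `r_s(ϱ) r_b < r_d` at low density. That
inequality is evaluated at the reference density `ϱ = 0.25` throughout
(the value used for the phase-diagram boundary curve); the boundary itself
is the closed form `κ(θ) = artanh(2 r_d/r_b − 1)/(0.25 − θ)`.

### Density-dependent diffusivity

The low-density expansion of `D(ρ)` is implemented with coefficients
`c0 = 1 − r_s(0)/2`, `c1 = −r_s′(0)`, `c2 = −(3/2) r_s″(0)` (exposed in
`expansion_coefficients`, a one-line change if a different reading is
preferred), alongside the moving-fraction form `D0 (1 − r_s(ρ))` as a
cross-check. The two forms share the leading density dependence but differ
in the constant term (`1 − r_s(0)/2` versus `1 − r_s(0)`); the test suite
asserts only the shared slope and the package does not silently reconcile
them. Values are clamped below at 0 with a warning when the expansion
leaves its validity range (`ρ ≪ 1`).

### PDE solver

Explicit conservative finite volumes: interface diffusivity is the
arithmetic mean of adjacent cells, zero-flux (default) or periodic
boundaries, explicit Euler stepping under the CFL bound
`dt ≤ dx²/(2 max D)` (violations refuse to run). With no kinetics and
zero-flux boundaries mass is conserved to round-off. Implicit stepping is
out of scope.

## Experiments and their scaled-down defaults

The reference parameterization is `r_b = 0.2`, `r_d = 0.01`, `K = 8`,
`b = 4`, disk radius 10, with the default initial condition placing one
resting and one moving cell per occupied disk node (local density 2/K =
0.25) and occupancy probability 0.25. The full-scale studies use a
10⁴-node lattice and 1000–5000 steps; the packaged test/acceptance
configuration uses a 50×50 lattice, 500–2000 steps and 20 replicates so
the whole suite runs on one CPU in minutes. The growth rate of a run is
the least-squares slope of `log n_rest` versus step over the last half of
the run (the standard exponential-rate estimator; the late window avoids
the initial transient), with an explicit sentinel for extinct runs.

### Initial densities and the critical regime

At the study point (κ = 4.4, θ = 0.75) the kinetic term is bistable with
unstable threshold ϱ* ≈ 0.466. The default disk (local density 0.25) is
therefore *subcritical*: on the scaled-down lattice every such colony
decays, and within a 500-step horizon the extinction frequency is governed
by the death clock (1/r_d = 100 steps), falling from ≈0.9 at occupancy
0.05 to 0 at occupancy 1 simply because larger colonies take longer to die
out. This monotone non-increase with initial density is the Allee-effect
signature the extinction study asserts, over the occupancy grid
{0.05, 0.1, 0.25, 0.5, 1.0}.

Genuinely persistent colonies require initial local densities near or
above the threshold; the disk builder therefore accepts a channels-per-node
option. The stationary-distribution study occupies 2 rest + 2 velocity
channels (local density 0.5 ≈ ϱ*). A pilot scan located the critical
window: at node-occupancy 0.5 every replicate extinguishes, at 1.0 every
replicate persists, and mid-window (0.65) both outcomes occur with
substantial probability. The packaged study uses occupancy 0.65 (critical
regime, bimodal final-density distribution: an extinct pile at 0 and a
persistent mode near the upper stable state) versus 1.0 (supercritical,
unimodal), run for 2000 steps so the persistent mode separates cleanly
from zero.

### Kernel density estimation and modality

Final averaged densities live on [0, 1] with an atom at 0 (extinct runs),
so the Gaussian KDE reflects boundary mass at 0 and 1 (the estimate then
integrates to 1 on the interval) and uses Silverman's rule on the raw
samples; all-identical samples require an explicit bandwidth. Modality is
the count of local maxima with prominence above 5% of the global maximum,
with the exterior density taken as 0 so boundary modes count.

## What the synthetic conditions do and do not show

All experiments generate their own lattice states; there is no external
data. Passing tests demonstrate the model's internal consistency (operator
invariants, agreement with its own mean-field limit, the predicted regime
dichotomy and its density dependence) at desk scale. They do not calibrate
the model to biological tumors: lattice spacing, step duration and the
rate constants are unitless, the microenvironment is collapsed into local
density, and the scaled-down lattice exaggerates finite-size fluctuation
effects (e.g. the nucleation probability of a persistent colony depends on
lattice size and horizon). Hexagonal/3-D lattices, non-periodic
boundaries, traveling-wave analysis and any therapy-level interpretation
are out of scope.

## Known limitations

* The reaction sub-order and blocking rules are choices among equivalents
  the published rule set does not distinguish; alternative orders would
  change microscopic trajectories (not the qualitative regimes).
* The diffusivity expansion's constant term is ambiguous (see above); PDE
  work that depends on absolute diffusivity scale should prefer the
  `exact` moving-fraction form.
* `growth_rate_estimate` assumes exponential dynamics inside its window;
  for saturating populations it underestimates the early-phase rate.
* The explicit PDE scheme is first-order in time; error constants are
  adequate for the benchmarks shipped, not for stiff parameter regimes.
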