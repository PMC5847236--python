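# Methods

## The agent-based model

One realization lives on a finite rectangular lattice of `Lx x Ly` sites
(default 200 x 20), 1-based coordinates, at most one agent per site.  Green
agents are residents present at `t = 0`; red agents are invaders injected
later.  Time is discrete.  Per step, with `N` agents present at the step
start, `N` sequential uniform-with-replacement draws are made from the
step-start agent list and each drawn agent immediately attempts one move —
so on average each agent moves once per step, but an individual may be drawn
several times or not at all.  Draws landing on agents that already left the
lattice earlier in the same step are skipped (the selection event is still
consumed).  Injection then runs once; agents injected mid-step become
eligible from the next step.

### Motility rules

A move attempt picks a target one site up/down/left/right.

* *Gentleman*: direction drawn uniformly; the move succeeds only onto a
  vacant in-lattice target, otherwise it aborts.
* *Simple shover*: direction drawn uniformly; an occupied target triggers a
  shove of the contiguous occupied run starting there, shifted one site along
  the direction up to the first vacancy.  Horizontal shoves always succeed —
  a run reaching a vertical boundary pushes its far agent off the lattice.
  Vertical shoves abort when the column is occupied to the horizontal
  boundary (no vacancy to absorb the chain).
* *Smart shover*: all four directions are scored by shoving effort (number of
  agents the move would displace; a vacant target scores 0), infeasible
  vertical directions are discarded, and a minimum-effort move is executed,
  ties broken uniformly at random over the fixed scan order up, down, left,
  right.  Horizontal moves are always feasible, so smart shovers never abort.

### Boundaries

Horizontal boundaries (`y = 1, Ly`) reflect: voluntary vertical steps off the
lattice abort.  Vertical boundaries (`x = 1, Lx`) absorb: agents shoved
across them are removed permanently.  A *voluntary* horizontal step off the
lattice also removes the agent by default — this makes the vertical
boundaries uniformly absorbing, consistent with the homogeneous boundary
conditions of the continuum model; set `horizontal_exit=False` to abort such
steps instead (with gentlemen-only dynamics and no injection, the population
is then exactly conserved, a property the tests assert).

### Injection

Each step, `attempts_per_step = 4` entry attempts each draw a site uniformly
with replacement from the invasion region (a vacant drawn site is always
occupied by a new red agent).  The three geometries are the 2D band
(`x in [90,109]`, all rows; 400 sites), the horizontal midline (20 sites) and
the upper horizontal boundary (20 sites).  On an occupied site the protocol
mirrors the invader's motility personality: gentlemen abort; simple shovers
shove the resident chain in a uniformly drawn direction (aborting on blocked
vertical columns); smart shovers shove along a feasible minimum-effort
direction and therefore always succeed.  Within-step site draws are
independent (nothing forbids two attempts landing on the same site).  The
per-site entry probability on an empty lattice is `4/400 = 0.01` per step for
the band.

### Seeding, randomness, reproducibility

Residents are seeded i.i.d.: each site holds a green agent with probability
`c_G` (a Bernoulli field, which makes the initial profile's sampling error
analytically checkable); an exact-count mode (`round(c_G * Lx * Ly)` agents on
a uniform random site subset) is available behind a flag.  All randomness
flows through one `numpy.random.Generator`; a realization is a pure function
of its config including the seed.  Ensembles spawn per-realization generators
with `SeedSequence(root_seed).spawn(n)`, so results are bit-reproducible and
independent of worker count and execution order.  The hot loops are
numba-compiled; the jitted kernels consume the same generator stream, so the
compiled and wrapped paths are one implementation, not two.

### Within-step ordering

The motility sweep runs before injection by default, which makes the sweep
length `N` independent of the current step's entries.  The reverse order is
available (`injection_first=True`) for sensitivity checks; the study
scenarios are insensitive to it.

## Observables

* **Snapshots**: full occupancy grids at requested record times, exportable
  as plain CSV (codes 0/1/2 = empty/red/green) with a JSON sidecar stating
  the 1-based coordinate convention.
* **Site-occupancy profiles**: occupancy fraction vs `x`, averaged over the
  y-dimension and realizations (the full 2D means are also stored).
* **Cell-count curves**: per-step red/green/total means and standard
  deviations across realizations.
* **Compactness**: the x-variance of a profile normalized to a distribution
  over `x`; a uniform profile over a 20-column band gives (20^2 - 1)/12 =
  33.25, and smart shovers produce a smaller red-profile variance than simple
  shovers (their minimum-effort rule wastes less displacement).

## Mean-field continuum limit

Assuming independent site occupancies (mean-field closure), gradient
expansion of the lattice master equation gives 1D advection–diffusion systems
for the column-averaged concentrations `R(x,t)`, `G(x,t)`, `C = R + G`, with
`D0 = 1/4` — the diffusivity of an unbiased 4-direction unit-spacing walk
with one move attempt per agent per step.  The displacement ("push") terms
come from the probability that a shover chain reaches a site, the geometric
sum `sum_m P(x-m) prod_{l<m} C(x-l)` with `P` the pusher density; its
gradient expansion produces the `(1-C)` power denominators below.

**Both species simple shovers** (pusher density `C`):

    dR/dt = D0 d/dx [ D(C) dR/dx + R V(C) dC/dx ] + S_R
    dG/dt = D0 d/dx [ D(C) dG/dx + G V(C) dC/dx ]
    D(C) = 1/(1-C),  V(C) = (3-C)/(1-C)^3

In the single-species limit (`G = 0`) the flux collapses to an effective
diffusivity `(1+C)/(1-C)^3`.

**Gentlemen residents, shover invaders** (pusher density `R`; gentlemen move
by exclusion only but are displaced by invader chains):

    dR/dt = D0 d/dx [ D(R,C) dR/dx + R V(R,C) dC/dx ] + S_R
    dG/dt = D0 d/dx [ A(R,C) dG/dx + G ( B(C) dR/dx + (1 + V(R,C)) dC/dx ) ]
    D(R,C) = 1 + 2R(2-C)/(1-C)^2      V(R,C) = R(3-C)/(1-C)^3
    A(R,C) = (1-C) + R/(1-C)          B(C)   = (3-C)/(1-C)^2

Consistency limits asserted by the tests: at `R = 0` the G equation reduces
to linear diffusion `D0 G_xx` (plain exclusion); at `G = 0` both mixed
equations collapse to the single-shover `(1+C)/(1-C)^3` law; a small
sinusoidal perturbation of the two-shover system about density `c0` decays at
rate `D0 [D(c0) + c0 V(c0)] k^2`.  The mixed coefficients keep the
species-diffusion matrix positive-definite; substituting the two-shover
`D(C)` into the mixed R equation loses parabolicity once `R` is appreciable
and the integration blows up in finite time — a useful diagnostic that the
cross-coefficients belong together.

**Source.** Entries add invader mass at `S_R = P_entry H(C) E(x)`, where
`E` is the indicator of the invasion interval `[Zl, Zr] = [90, 109]` and
`H(C)` switches entries off at full occupancy (`H = 1` for `C < 1`, `0` at
`C = 1`; entry into an empty region plainly succeeds, so `H(0) = 1`).
`P_entry` is the column-averaged entry rate `attempts/(width * Ly) =
4/(20*20) = 0.01` per site per step — for the 2D band this equals the
per-site entry probability `4/400`.  The normalization matters: the total
injected mass must be `integral(S_R * Ly) dx ≈ 4` cells per step, matching
the lattice protocol; an extra `1/Ly` on top of the per-site probability
would inject 20x too little and makes lattice–continuum agreement
impossible.  For gentlemen invaders `S_R` carries an extra factor `(1 - C)`
(entries abort on occupied sites).

## Numerics

* Method of lines on a uniform node grid, `dx = 0.1` by default; conservative
  finite-volume differencing with arithmetic-mean face coefficients, so the
  semi-discrete mass balance `d/dt integral(R+G) = integral(S_R) - boundary
  outflux` holds to rounding (asserted at 1e-6, observed ~1e-16).
* Stiff adaptive implicit integration: LSODA with a banded Jacobian
  (interleaved species, bandwidth 3), `rtol = 1e-6`, `atol = 1e-9`.
* `H` is smoothed over a width `eps_H = 1e-3` below full occupancy to avoid
  discontinuity-induced step collapse; `1 - C` inside flux coefficients is
  floored at 1e-6 purely to guard the solver's trial steps (the solution
  itself stays below full occupancy).
* Boundary conditions at `x = 0, Lx` are homogeneous Dirichlet `R = G = 0`
  by default, matching the absorbing vertical lattice boundaries; homogeneous
  Neumann is available via config (used by the eigenmode-decay tests, where
  `cos(pi x / L)` is then an exact mode).  At the study horizons the profiles
  are near zero at the boundaries, so the choice is immaterial for the band
  comparisons.
* Grid independence: halving `dx` changes the continuum-comparison profiles
  at `t = 250` by ~0.6% in max norm (asserted < 1%).

## Lattice–continuum comparison

`compare_to_ensemble` interpolates the ensemble's integer-column profile onto
the PDE grid and reports per-species max-norm and RMS gaps plus the location
of each maximum.  For the continuum-comparison scenario (`c_G = 0.2`
gentlemen background, simple-shover invaders, band source, `t = 250`, 60
realizations) the total-occupancy gap away from the band edges is ≤ 0.1
(band-edge neighborhoods of ±2 columns are excluded: the sharp indicator
edges of `E(x)` are not resolved by the column-averaged ensemble there).
The continuum model under-predicts the green occupancy in the displaced-green
crowding flanks — the humps the invaders plough up on either side of the
band, which exceed 0.5 occupancy by `t = 250` — because the mean-field
closure ignores the strong local correlations of near-jammed regions.  The
maximum green gap localizes to those flanks (on the hump shoulder, a few
columns outside its >0.5 peak).

## What the study conditions are

All defaults are the study's conditions: 200 x 20 lattice, 4 entry attempts
per step, record times {50, 100, 250}, horizon 250 steps, ensembles of 300
realizations for production figures.  The test-suite and the acceptance
script use 60-realization ensembles — at that size every ordering and
profile comparison asserted is far outside Monte-Carlo noise (count SDs are
a few tens of cells against differences of hundreds; profile SEs ~0.01
against gaps ~0.08) — and fixed seeds so runs are deterministic.  Stochastic
ordering claims are tested with one-sided Welch comparisons at significance
0.01; the narrative "practically indistinguishable" count curves are
operationalized as a ≤10% maximum relative gap for `t >= 50` (an
interpretation, not a measured constant).

## What the generator does and does not emulate

The model emulates volume exclusion, chain displacement, and entry-protocol
crowding; it deliberately omits proliferation, death away from boundaries,
adhesion, chemotaxis, cell deformation, and off-lattice geometry.  Passing
tests therefore validate the mechanism comparison among these idealized
motility rules, not quantitative agreement with any particular cell-biology
experiment.

## Known limitations

* The mean-field comparison is 1D in `x`; no 2D continuum solve is provided.
* The mean-field closure degrades where occupancies approach 1 (e.g. a
  `c_G = 0.6` background drives green pile-ups to near-jamming, where the
  continuum model is unreliable) — the continuum comparison is therefore run
  at `c_G = 0.2`.
* Smart-shover *injection* uses the minimum-effort direction rule, mirroring
  the smart motility rule; success is guaranteed either way, but the
  direction policy for injections is a modelling choice.
* For a failed simple-shover injection attempt, neither the site nor the
  direction is redrawn (one draw each per attempt), mirroring the motility
  rule.
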