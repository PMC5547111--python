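# Methods

## Models

An `InteractionModel` is a directed invasion tournament on `n` species
plus rates: invasion `sigma`, reproduction `mu` (both default 1, the
field's convention) and a per-species intraspecific competition vector
`p`.  Three presets:

* **rps** — `A -> B -> C -> A`; species `i` is preyed on by `i - 1`
  (so the loss term of `a` is `-sigma * c`).
* **erps** — the five-species single cycle `i -> i+1 (mod 5)`.
* **rpsls** — the regular five-species tournament (each species invades
  two and is invaded by two).  All such tournaments are isomorphic, but
  once the rate vector `p` is pinned to labels A–E the orientation
  matters.  We use the rotational orientation in which species `i`
  invades `i+1` and `i+3` (predators `i+2`, `i+4`).  This is the unique
  labeling (up to rotation) for which the bifurcation scan in `p_e` at
  `(p_a..p_d) = (0.3, 1.1, 2.5, 0.7)` produces a three-species phase
  with onset at exactly `p_e = 8`, the structure the other orientation
  ("invades the next two") cannot produce at all under this rate
  assignment: there the scan terminates in a no-attractor regime above
  `p_e ~ 2.3` and no three-species states ever stabilize.

Custom tournaments are accepted verbatim after an irreflexivity check.

## Mean-field layer

`da_i/dt = a_i [mu (1 - rho) - sigma * sum_{pred} a_j - (p_i/2) a_i]`.
The `1/2` reflects pair double counting: the underlying pairwise process
kills one member of a same-species pair at rate `p_i` per (unordered)
pair.

**Fixed points.** On a support S the equilibrium conditions are linear:
`sum_j [mu + sigma * 1(j preys on i) + (p_i/2) d_ij] a_j = mu` for
`i in S`.  All `2^n` supports are solved exactly (`numpy.linalg.solve`);
a candidate is kept when every supported density is strictly positive
(threshold 1e-10).  Singular support systems are skipped.  For `n = 3`
the enumeration reproduces the closed forms quoted in the README to
1e-10, which the test suite asserts on random rate vectors.

**Stability.** The Jacobian is analytic,
`J_ij = d_ij (g_i - (p_i/2) a_i) - a_i (mu + sigma * 1(j preys on i))`
with `g_i` the per-capita growth; it is cross-checked against central
finite differences.  Classification uses a tolerance of 1e-9 on
eigenvalue real parts; anything within it of zero is `marginal`.

**Heteroclinic cycle.** The boundary cycle connects the single-species
saddles `d_i = 2 mu / (2 mu + p_i)`.  At vertex `i` the off-support
eigenvalues are `mu (1 - d_i) - sigma d_i` for the prey of `i` and
`mu (1 - d_i)` for the others.  The cycle is called attracting when the
product over vertices of `|most negative transverse| / (largest positive
transverse)` exceeds 1 — the classical saddle-ratio criterion.  For RPS
with `sigma = mu = 1` this reduces to `prod_i (2 - p_i) / p_i > 1`, and
its flip coincides (to numerical precision) with the interior point's
leading eigenvalue crossing zero, so either computation can define the
lower phase boundary; the scan uses fixed-point stability and the
acceptance script cross-checks the two.

**Bifurcation scans.** For each grid value of the scanned `p_i` the
model is rebuilt and all fixed points classified.  The phase label is
the support size of the stable fixed point, `0` when none is stable
(extinction regime: the attracting set lies on the boundary), `-1` if
stable points of different support sizes coexist (not observed on the
shipped scans).  Phase changes are refined by bisection to 1e-3.  At
exact transcritical crossings both exchanging equilibria are marginal at
the crossing, so the refined scan would report a zero-width phase-0
sliver (two thresholds ~1e-3 apart); threshold pairs closer than five
refinement tolerances are merged into a single threshold.  This is how
the RPS scan reports `p_a = 4` and the RPSLS scan `p_e = 8` as single
boundaries.

Computed boundaries for the shipped parameter sets: RPS
`(p_b, p_c) = (1, 0.5)`: 1.500 and 4.000.  ERPS
`(1.9, 2, ., 1.3, 0.7)` scanning `p_c`: 2.510, 5.535, 5.714 (phases
0 / 5 / 4 / 3).  RPSLS `(0.3, 1.1, 2.5, 0.7, .)` scanning `p_e`: the
five-species window is [1.705, 2.213], four species up to 8.000, three
transitive-triple species beyond (the scan also shows a stable
four-species window [1.356, 1.705] below the five-species phase).

**Integration.** `scipy.integrate.solve_ivp` with LSODA, rtol 1e-9,
atol 1e-12; "extinct at t_max" means density < 1e-6, far below `1/N`
for any simulated lattice.  Negative undershoots at the tolerance scale
are clamped in the returned trajectory.

## Lattice layer

Periodic `L x L` lattice, von Neumann neighborhoods, sites empty or
holding one individual.  An elementary attempt draws an occupied site
(empty draws are redrawn and consume no time) and a random neighbor and
executes at most one enabled reaction with probability `rate / Lambda`,
`Lambda = sigma + mu + max_i p_i + eps`:

* invasion at `sigma` if the neighbor is the focal species' prey (the
  prey's site is emptied);
* reproduction at `mu` into an empty neighbor;
* intraspecific kill at `p_X / 2` per ordered draw if the neighbor is a
  conspecific — a same-species pair can be drawn in either order, so
  the pair fires at `p_X`, matching the `(p_X/2) a^2` mean-field term
  (using `p_X` per draw doubles the effective rate and demonstrably
  shifts every lattice threshold);
* exchange at `eps = 2 M N` if the neighbor is a conspecific or empty
  (the literal reading; `permissive_swap=True` also swaps with other
  species — the shipped results are insensitive to the choice).

**Clock.** One generation is `round(Lambda * N)` attempts, so each
reaction channel fires at its nominal rate per neighbor pair per
generation and the lattice generation is commensurate with the ODE/PDE
time unit and with the mobility definition.  (With `N` attempts per
generation every effective rate, including the exchange rate, would be
smaller by `Lambda`; the effective mobility `M / Lambda` then falls
below the classic critical mobility and the lattice sits in a
spiral-coexistence regime that contradicts both the mean-field phase
structure and the well-known high-mobility extinction benchmark of the
symmetric game.)

The kernel is a numba njit routine with an inline xorshift64* stream
(seeded via splitmix64 from the run seed), ~30 ns per attempt on one
core.  All randomness fans out of a single `RunConfig.seed` through
`numpy.random.SeedSequence` (separate init and dynamics streams), and
snapshots are taken inside the kernel, so requesting snapshots cannot
perturb a trajectory.  Event counts (births, interspecific deaths,
intraspecific deaths, moves) are recorded per species per generation as
integers; site counts reconcile with the cumulative log exactly, which
the suite asserts on every tested run.

Default initial condition: each site independently species `i` with
probability `1/n` (no empties); fully configurable.

## PDE layer

Pseudo-spectral on the periodic unit square, `G x G` collocation points
(default 128 in the CLI; the tests use 32–64), Fourier multipliers
`-(2 pi k)^2`, integrating-factor RK4: diffusion advanced exactly by
`exp(-M k^2 dt)`, reaction by classical RK4.  Quadratic nonlinearities
are dealiased by 2/3-rule truncation.  Spectral ringing can undershoot
zero; fields are clipped to zero after each step with the removed mass
accumulated in `DensityField.clipped_mass` (at tolerance scale in all
shipped runs).  A uniform field reduces the PDE to the ODE; the suite
checks agreement to 1e-6, spectral Laplacians of sinusoid products to
1e-10, and grid-doubling invariance of t=50 spatial means to 1e-4.

## Diagnostics

From the event log: `H_i = R_i - C_i`, `S_i = H_i - I_i`, and the
population reconstruction `P_i(t) = P_i(0) + sum S_i` — all exact at
the integer-count level (`BalanceSeries` stores counts and scales by
`N` on access).  In coexistence `H_i` stays positive while `S_i`
averages to zero; a species' persistence shows up as normal diffusion of
the cumulative `S_i`.  `diffusion_exponent` estimates the mean-squared
displacement of the cumulative sum over all time origins (and over
realizations when an ensemble is given) and fits a log-log slope.  For
the lattice coexistence runs the usable lag window is bounded above by
the deterministic rotation about the interior focus (eigenvalues
`-0.039 +/- 0.150i` at `p = (2.5, 1, 0.5)`, period ~42 generations);
lags 1–20 give exponents 0.99–1.13 across the three species over ten
seeds.  Longer lags are dominated by the oscillation and then by
saturation, as expected for a stationary population.

`classify_coexistence`: a species survives a run iff its density stays
above the tolerance over the final fifth of the trajectory (tolerance 0
for lattice runs — extinction is absorbing; 1e-6 for ODE/PDE means).

## Problem sizes in the shipped tests

Scans use grid steps 0.05 (tests) or 0.01 (acceptance script) with
bisection refinement to 1e-3.  Lattice consistency runs use 100 x 100
lattices, `M = 1e-3`, ten seeds per parameter point and horizons of
400 generations in the three- and two-species regimes and 600 at
`p_a = 100`; the diffusion diagnostic reuses the ten three-species runs
(transient of 100 generations discarded).  PDE tests use G = 32–64 and
horizons of 10–200 time units.

## Known limitations

* At `p_a = 100` the mean-field attractor is the pair state
  `(0.0067, 0.658, 0)`; on a 100x100 lattice that is ~65 predator
  individuals, whose drift extinction was not observed within 15,000
  generations.  Single-survivor outcomes at such parameters are
  therefore fluctuation events on much longer horizons (or smaller
  populations) than the shipped tests run; the corresponding lattice
  consistency check expects them and is known to fail at these horizons.
* The synthetic initial conditions (product-measure lattices, uniform
  fields with small seeded perturbations) do not emulate spatially
  structured real communities; passing tests demonstrate internal
  consistency of the three layers, not realism of any particular
  ecosystem.
* Interspecific rates are uniform (`sigma` shared by all invasion
  pairs); mutation, long-range migration and off-lattice movement are
  out of scope.
* Two-parameter phase diagrams and limit-cycle continuation are not
  implemented; scans vary a single intraspecific rate.
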