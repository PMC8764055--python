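# Methods

## Model

Species occupy lattice units; a unit may hold at most one individual of
each species, and (in the two-species model) both species at once — there
is no spatial exclusion, so the only interspecific coupling is the shared
barrier.  Geometry is a half-infinite 1D array (seeded with one individual
at unit 0) or a 2D strip of `box_length` rows by `L` periodic columns
(seeded with a fully occupied first row).

Dynamics are random sequential updates.  A unit is drawn uniformly over the
allocated box:

* an **empty** draw counts toward the clock and does nothing;
* an **occupied** draw whose occupants all lack a free neighbour is redrawn
  without counting;
* otherwise the draw counts and the unit updates: every occupant species
  runs one **duplication trial** (uniform among in-box neighbours empty of
  that species) and then every occupant one **migration trial** (uniform
  over the 2·dimension lattice directions; a draw pointing outside the box
  or onto the species' own kind fails silently).  Co-occupied units run
  each round in fresh uniform species order.

A trial on a *closed* target increments that species' trial counter on the
target by one; a trial on an *open* target succeeds (duplication adds an
individual, migration moves one).  Openness is re-evaluated from the
current counters at every attempt: single species `n >= N`; two species
`zeta*n1 + n2 > N` or `n1 + zeta*n2 > N` (strict, real arithmetic).  For
`zeta >= 0` the counters' monotonicity makes openness monotone (verified in
tests); for `zeta < 0` a transiently open unused unit can re-close as the
rival's counter grows.

One **time step** elapses when counted selections reach the allocated unit
count, so each unit is selected on average once per step and the velocity
unit is lattice units per step.

Why migration draws *directions* rather than existing neighbours: at the 1D
seed unit both species' trials would otherwise hit the single in-box
neighbour in lockstep, leaving `n1 = n2` forever — and at `zeta = -1`,
where openness requires `|n1 - n2| > N`, the invasion could never start.
Drawing directions (with boundary draws failing like own-kind draws)
restores the stochastic asymmetry between the two counters; interior units
are unaffected.  The fully competitive barrier then opens by a random walk
of `n1 - n2`, taking ~N² trials per unit, which is what makes competitive
invasion so much more sensitive to barrier intensity than cooperative
invasion (velocity decay exponent ~2 versus ~1).

## Engines

`lattice.py` implements the rules literally (the *reference engine*):
object-level state, one draw at a time, redraws bounded at 10⁴.
`_engine.py` implements the identical process event-driven: since empty
draws change nothing and blocked occupied draws are discarded, each counted
selection is uniform over the *countable* units (empty + active), so the
engine keeps the active set explicitly, draws the geometric number of
counted no-ops between actions, and executes only actions.  This is an
exact reformulation, not an approximation; the test suite checks
distributional agreement of front moments between the engines in 1D and 2D
(3 SE at 500 replicates), and roughness agreement was verified during
development.  Production paths (ensembles, sweeps, the acceptance script)
use the fast engine; trajectories are bit-reproducible per engine and seed.

## Box sizing and the clock

Because blocked bulk units are redrawn without counting, their draws are
reassigned to the rest of the lattice; as the occupied region grows this
accelerates the effective clock by a factor 1/(1 - occupied fraction).
Ensembles therefore allocate ~20 box units per expected unit of front
travel (velocity estimated by a short pilot), keeping the occupied fraction
under ~5% for the whole run; the mean-squared-displacement diagnostic slope
then sits at ~1 as it should for diffusive front fluctuations.  Because the
box is proportional to expected travel in every cell of a sweep, the small
residual rescaling is common across cells and cancels in exponent fits.
All replicates of a cell share one box (one time unit); a front overflow
restarts the whole cell with a doubled box.  Long adaptive runs instead
*grow* the box in place (`Simulation.grow`).

## Estimators

* **Velocity** `V`: OLS slope of the ensemble-mean front versus time.
  Default window drops the first 20% of recorded times (transient).
* **Diffusion** `D`: slope of the ensemble variance versus time.  At
  finite times the front carries a stationary O(1) jitter about its mean
  advance, so Var(X; t) = D·t + c with a nuisance offset c.  The default
  estimator is the free-intercept OLS slope; exponent pipelines use the
  endpoint difference of the variance curve across the window
  (`method="endpoints"`), which is equally unbiased but has a measurably
  smaller sampling spread because the variance curve is one autocorrelated
  path (seed-to-seed sd of the fitted N-decay exponent: 0.12 versus 0.17
  for OLS at 300 replicates x 2000 steps).  A zero-intercept fit is *not*
  used: it folds c into D and visibly flattens the D(N) decay at large N.
  The log-log slope of variance versus time is attached as a random-walk
  diagnostic (expected ~1).  Per-replicate increment pooling was evaluated
  and rejected — finite-lag increments pick the jitter up twice
  (Var(dX) = D·h + 2c) and bias the decay flat.
* **Power laws**: OLS in log-log coordinates; decay fits report the
  positive `gamma` of `y ~ x^-gamma`, growth fits the positive `alpha` of
  `y ~ x^alpha`.  Decay fits of V and D versus N default to the upper half
  of the N grid (the large-N regime where the laws hold), falling back to
  the full grid when the upper half has fewer than 3 points.
* **Interface width**: `W = sqrt((1/L) sum (X_i - H)^2)` with the
  population divisor; ensembles average W per time (an rms-of-W² switch
  exists; exponents agree within quoted uncertainties).  `X_i` is the
  per-column maximum occupied row, matching the 1D front definition.
* **Saturation**: `W_sat` is the mean of W over the final 25% of recorded
  times.  Flatness is judged by a paired tail-slope statistic: each
  replicate contributes the log-ratio of its tail-half means over the
  log-time separation, giving a slope with a meaningful standard error;
  the tail is accepted when |slope| <= 0.05 + 2 SE (an ensemble cannot
  resolve slopes below its own noise floor, and a naive log-log regression
  on the noisy ensemble mean is variance-dominated).  Run lengths come
  from a 10-replicate pilot that extends in growing chunks until two
  consecutive tails are flat (competitive widths grow in stages — a fast
  opening spread, then slow domain-wall creep — so a single flat window
  can be a local plateau); the full ensemble then runs 1.3x longer and
  must itself pass the flatness test, doubling the run length otherwise.
* **Growth exponent** `beta`: log-log slope of W(t) from t = 5 (past
  lattice discreteness) to the first crossing of W_sat/2; windows reaching
  past 0.8·W_sat are rejected.
* **Family–Vicsek collapse**: curves rescaled to (t/L^z, W/L^alpha); the
  score is the mean squared log-deviation between curves on the common
  overlap (diagnostic only).

## Synthetic-data scope

All inputs are generated by the simulator itself; the only external inputs
the analysis layer accepts are front time series in the documented CSV
layout.  The generator emulates the idealized study conditions — perfectly
mixed selection, homogeneous barrier intensity, exactly two species, no
death, no spatial exclusion, no mechanics or chemotaxis.  Passing tests
therefore certify the statistical machinery and the stated dynamics, not
any claim about real tumour or ecological fronts, whose barriers are
spatially heterogeneous and whose populations exclude each other in space.

## Problem sizes

Default experiment scales were chosen as the smallest giving stable
exponent fits: 300 replicates x 2000 steps for the 1D N-sweeps
(grid N = 5...80; the fully competitive sweep instead fixes run length per
N so the mean front travels ~60 units); 200 replicates x 800 steps for the
2D Langevin sweeps over L = 8...64 at N = 10; >= 100 replicates run to
width saturation for the roughening studies (L = 8...64 at N = 10, and
N = 2...40 at L = 20).  The preset configurations accept a `--scale`
multiplier for convergence studies.

## Known limitations

* The 1D fully competitive velocity decay measures `gamma_V ~ 1.95-2.0` at
  N = 5...40 — the asymptotic value of the counter-difference random-walk
  mechanism is exactly 2, and shorter (pre-asymptotic) runs yield smaller
  effective exponents.
* The 2D saturated-width scaling is where this implementation's results
  are most sensitive to rule details.  Under the rules above, a lagging
  column receives barrier trials from three sides and a leading column
  from one, so stronger barriers *smooth* the cooperative/neutral front:
  measured `alpha_L ~ 0.42-0.48` for both interaction regimes, `W_sat`
  *decreasing* with N for `zeta >= 0` and nearly flat for `zeta = -1`.
  These trends are robust to run length (plateaus stable over 20x time
  spans), system size, ensemble reduction and engine choice.  The
  qualitative orderings — competitive fronts far rougher than
  cooperative/neutral ones at equal N and L, velocity increasing with
  zeta, beta rising with N under competition — are reproduced and tested.
* For `zeta >= 0` the interface saturates within ~10 steps at sub-unit
  width at moderate L, leaving no resolvable power-law growth window: beta
  is effectively unmeasurable there, and only its competitive-regime
  behaviour is quantitative.
* `gamma_L` (decay of D_H with L) is measured per interaction value with
  ~±0.1 spread at 200 replicates; the cooperative value tends to sit
  slightly above 1.
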