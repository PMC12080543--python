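# Methods

## Model

A signed directed network on `N` agents has a fixed edge structure; each
directed link carries a sign in {−1, +1} that may change over time. One
elementary update:

1. **Sample an ego-based triad.** On a complete graph, an ordered triple
   (A, B, C) is drawn uniformly from all `N(N−1)(N−2)` possibilities; the
   triad consists of A→B, A→C and the inner link B→C. On general graphs
   (pruned of links that sit in no ego-triad) the draw is hierarchical:
   focal A uniform among agents with at least one eligible out-neighbour,
   B uniform among A's out-neighbours that share an eligible third agent,
   C uniform among agents with an A→C link and at least one directed link
   between B and C, and the inner direction uniform among the existing
   one(s). Eligibility-filtered uniform sampling induces the same
   conditional law as rejection sampling; we filter because it never
   stalls on sparse graphs. "Neighbour" here means out-neighbour — the
   focal agent must own both of its links in the triad.
2. **Evaluate stability.** With probability `q` by status theory: the
   triad is unstable iff its three order relations (a positive link ranks
   the target above the source) admit no consistent ranking, which
   happens exactly for the sign triples (+,−,+) and (−,+,−). Otherwise by
   structural balance: unstable iff the product of the three signs is
   negative (one or three negative links).
3. **Repair.** A stable triad is left alone. Otherwise the focal agent
   flips exactly one of its two out-links: a uniform choice when they
   share a sign; when they differ, the negative link with probability
   `p_st` (status branch) or `p_sbt` (balance branch), else the positive
   one. The inner link is never touched.

The eight triad classes are labelled `XY#` with X = B/U (balanced or
not), Y = H/N (hierarchical or not) and # = number of negative links at
the focal agent. Balance and hierarchy interact: the status branch
destroys the nonhierarchical BN1/UN1 and can create the unbalanced UH0,
so neither theory's absorbing structure survives unless all links are
positive — the *paradise* state, absorbing under both theories.

All three parameters are probabilities in [0, 1]. `q` weighs status
against balance; `p_sbt` expresses the preference for forming positive
relations, `p_st` the preference for respecting others (both are
conflict-avoidance propensities, applied only to mixed-sign focal pairs).

## Mean-field analysis

Assume each sign is an independent Bernoulli(ρ) variable. Each unstable
class then occurs with a known probability and contributes a known
expected flip direction; summing the six channels (UH0, UN1, UH1, UH2 on
the balance branch; UN1, BN1 on the status branch) gives the drift of the
positive-link density. `mean_field.drift` is coded channel by channel;
that it factors algebraically as `(1−ρ)·Q(ρ)`, with

    Q(ρ) = [2(1−q)(2p_sbt−1)] ρ² − [2(1−q) + (1−2p_st) q] ρ + (1−q),

is asserted by a property test rather than assumed, so the factored
quadratic and the per-channel derivation cross-check each other.

`quasistationary_roots` solves `Q` in closed form. Numerical choices:

* leading coefficient below 1e−12 → linear branch (robust near
  `p_sbt = 0.5` and `q = 1`); |discriminant| below 1e−12 → double root;
* interior roots are those in [0, 1); ρ = 1 is always appended;
* stability is classified from the drift sign at ρ̂ ± 1e−6 (one-sided at
  the boundaries); a double root shows the same drift sign on both sides
  and is labelled *marginal*;
* regimes: *disordered* (an interior stable root), *bistable* (interior
  stable root + interior unstable root + stable paradise; the unstable
  root is the separatrix), *paradise* (no interior stable root). At
  `q = 1, p_st = 0.5` the drift vanishes identically — every density is
  frozen; this is reported as a disordered portrait with only the
  marginal ρ = 1, since nothing flows to paradise.

`classify_transition` sweeps one parameter and separates two critical
events, both located by `brentq` to 1e−14 between bracketing grid points:

* a **fold** — discriminant zero with the merging double root strictly
  inside (0, 1): the stable/unstable interior pair annihilates and the
  density jumps — a discontinuous transition;
* a **Q(1) = 0 crossing** — ρ = 1 becomes a root of `Q`. If the companion
  root (`c/a`) is outside (0, 1) the interior stable root itself reaches
  1: a continuous transition. If the companion root is interior the
  crossing is instead the *onset of bistability* (the separatrix enters
  [0, 1]); the sweep is then classified discontinuous even when the fold
  itself lies beyond the swept range, and the reported critical value is
  the onset in that case.

Closed-form consequences reproduced by the tests: the balance-only
(`q = 0`) paradise onset at `p_sbt = 0.75` (from `Q(1) = 4p_sbt − 3` —
notably *not* the 0.5 of triad-focused balance dynamics); the boundary
between continuous and discontinuous `p_sbt`-sweeps at `p_st = 0.5`; and
exact `q`-independence of the interior root at `p_st = 0.5`, where the
factor (1−q) cancels.

## Simulation engine

Time is counted in elementary updates; a *sweep* is `L` updates, `L` the
number of directed edges. The engine keeps signs in a flat Python list
(dense `N×N` for complete graphs, per-edge for general graphs) and
consumes uniforms pre-drawn in per-sweep blocks from a single
`numpy.random.Generator` — one seeded stream per run, drawn in a fixed
order (triple, theory, link choice), so runs replay exactly. At the
problem sizes used here (≈10⁶ updates per complete-graph run) this costs
well under a second per run and avoids any compilation machinery.

Default schedule: 50 sweeps burn-in, 50 sweeps measurement, density
sampled every sweep. Stationarity check: the first- and second-half
window means must agree within 3 pooled standard errors, else the window
doubles, at most 3 times, after which the result is flagged
non-stationary. Paradise (all signs positive) is detected after every
flip and stops the run. On sparse graphs frozen unbalanced motifs can
exist (e.g. a reciprocal inner pair that no focal agent can repair);
`has_unstable_triad` provides the exhaustive full-stability check.

Problem sizes used by the test suite, chosen so the whole suite runs in a
couple of minutes: complete graphs with N = 100 (matching the phase
analysis) for the simulation-vs-analytics grid, N = 32 for deviation
illustrations, N = 50 triangle-rich networks for fitting experiments.

## Synthetic generators

`complete` gives all `N(N−1)` links; `random_directed` is an Erdős–Rényi
digraph; `triangle_rich` emulates the sparse-but-clustered structure of
empirical social networks: a Watts–Strogatz ring skeleton (k neighbours,
rewiring probability 0.1), each undirected pair realised as a reciprocal
link pair with probability `p_reciprocal` and as a single random
direction otherwise. Signs are always i.i.d. Bernoulli(ρ₀); the default
ρ₀ = 0.5 mirrors the standard initial condition for complete graphs,
with 0–0.9 supported for basin-of-attraction studies.

What the generators do **not** emulate: degree heterogeneity, community
structure, reciprocity correlated with sign, or temporal accumulation of
links — all present in real online and school networks. Passing tests on
these fixtures therefore validates the machinery and the model's internal
consistency, not the model's fit to any particular real dataset.

## Census and deviations

The census enumerates *every* ordered focal triple whose three links
exist, both inner directions counted separately when both exist — the
static census is then the stationary expectation of the dynamic sampling.
It is computed exactly with sparse indicator-matrix products
(`(X_aᵀ X_b)[B,C]` counts focal agents with given out-link signs), so it
scales to sparse empirical networks without dense-matrix memory.

Deviations are relative densities minus 1/3 within the one-negative group
(UH0, UN1, UH1) and the two-negative group (BH1, BN1, BH2) — the uniform
level expected under balance dynamics alone. Empty groups yield NaN
deviations, which propagate and are excluded from fitting, never silently
zeroed. A deviation of −0.25 therefore means an 8% within-group
abundance, +0.4 means 73%, a ratio of about nine.

## Fitting

`fit` re-simulates the dynamics on the observed topology (signs
re-initialised i.i.d. at the observed density by default — the target is
a quasistationary statistic, not a trajectory), averages the deviation
vector over census snapshots and repetitions (deviations are averaged
first, then scored; the alternative of averaging per-repetition scores
would add a uniform noise-floor term to every grid point), and scores
each grid point by the mean squared error against the observed
deviations. Parameter sets within 110% of the best error form the
selected set; reported means and standard deviations are taken over it,
and the per-parameter uncertainty is `sqrt(sd² + (step/2)²)` — the
quadrature combination of selection spread and grid resolution. Grid
points whose repetitions all end non-stationary or in paradise (undefined
deviations) are excluded with a warning. Grid defaults mirror the
protocol for large networks (Δq = 0.025, Δp = 0.1); the recovery tests
use coarser explicit grids.

The error uses deviations only by default. An optional `rho_weight` adds
`rho_weight · (ρ_sim − ρ_obs)²`: the density is part of what the search
is meant to match, and on small fixtures (~10³ triads) it is decisive —
without it the (p_sbt, p_st) direction is a near-flat ridge whose
expected-deviation differences sit below the observation noise of a
single snapshot, and the 110% rule then selects a single noise-favoured
point. The parameter-recovery experiment therefore enables the density
term; the deviations-only default is kept for comparability.

A related caution: the strong anticorrelation between fitted `p_st` and
`q` reported for ensembles of real networks is a property of those data,
not of the fitting procedure; desk-scale fixtures with constant true `q`
do not reproduce it reliably. The model mechanism behind it is, however,
exact: wherever `p_st > 0.5`, the interior root increases in both `q` and
`p_st`, so holding the positive-link density fixed forces `p_st` down as
`q` rises. The test suite asserts that trade-off direction analytically.

## Known limitations

* The mean-field solution ignores sign correlations; its accuracy
  degrades near the transition surfaces (measured bias up to ≈0.03 at
  N = 100 close to `Q(1) = 0`) and for very small N.
* Dynamics on general graphs assumes the pruned topology is fixed;
  networks whose every edge lies outside ego-triads cannot be simulated.
* Weighted, neutral or temporal links and multilayer networks are out of
  scope, as are homophily mechanisms and longer-cycle balance measures.
* File I/O supports arbitrarily large SNAP-style edge lists, but the
  complete-graph engine materialises a dense sign matrix and is intended
  for N up to a few thousand.
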