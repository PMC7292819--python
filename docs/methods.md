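# Methods

## The growth law

The package studies a density growth law derived from an individual-based
picture: agents live on a hexagonal lattice (six neighbours per site), and
each agent's proliferation and death rates depend on its number of occupied
neighbours `n ∈ {0, …, 6}`. In the well-mixed (mean-field) limit the scaled
density `C(t) ∈ [0, 1]` (`C = 1` is the maximum packing density) obeys

    (1/C) dC/dt = (1 − C) Σ_{n=0..5} γ_n binom(5, n) Cⁿ (1 − C)^{5−n} − γ_6 C⁶

with net growth coefficients

    γ_n = p_n − 6 d_n / (6 − n)   (n ≤ 5),      γ_6 = d_6 ,

where `p_n`, `d_n` are the per-neighbour-count proliferation and death
rates. The binomial weights are the distribution of an agent's occupied
neighbours when occupancy is spatially independent at density `C`; the
`(6 − n)/6` factor inside `γ_n` is the probability that a proliferation
attempt finds its uniformly chosen target site empty (the identity
`binom(6, n)(6 − n)/6 = binom(5, n)` connects the two bookkeepings).

The *binary switch* closure sets

    p_n = r,  d_n = r·α   for n ≤ M,        p_n = R,  d_n = R·β   for n > M,

with threshold `M ∈ {0, …, 5}`, rates `r, R ≥ 0` (per hour in the data
application) and death-to-proliferation ratios `α, β ∈ [0, 1]`. With
`r = R` and `α = β` the law collapses exactly to logistic growth with
carrying capacity `1 − α`; the collapse is used as an internal consistency
check throughout the test suite. `dC/dt` is a degree-7 polynomial in `C`
with a structural root at `C = 0`; `C = 1` is a root exactly when `R·β = 0`.

## Equilibria and stability

All equilibria are polynomial roots in `[0, 1]`. The implementation:

1. expands `dC/dt` exactly (coefficient arithmetic on
   `numpy.polynomial.Polynomial`),
2. deflates the structural roots at 0 and (when `R·β = 0`) at 1 *before*
   the companion-matrix eigen-solve — eigenvalues of an m-fold root scatter
   like `eps^(1/m)` and are useless for multiplicity detection at high
   order,
3. clusters the remaining real roots within `1e-6` in `C`, then attempts to
   merge adjacent clusters within `1e-4` when the merged cluster passes the
   tangency residual checks (`|p| < 1e-9`, successive derivatives below
   `1e-7` relative to the next one). This recovers double roots (scatter
   ~`1e-8`) and triple roots (scatter ~`1e-5`) reliably,
4. Newton-polishes each representative on the appropriate derivative and
   enforces a residual `|dC/dt| < 1e-9` at every reported root.

Stability of interior roots follows the multiplicity rule (odd multiplicity:
sign of the m-th derivative; even: semi-stable). Boundary roots at 0 and 1
are classified one-sidedly from the m-th derivative sign — pointwise sign
probes next to a high-multiplicity boundary root are destroyed by
cancellation, so they are not used.

Exact tangency is a measure-zero event in parameter space; the tolerances
above are what make the manifold/point regimes *reachable* in floating
point. Parameters within ~`1e-5` of a tangential manifold may therefore be
labelled as on-manifold; this is a deliberate resolution choice, not an
error. The regime taxonomy maps the (count, stability, multiplicity)
signature to one of: Extinction, Logistic (reported only on the exact
no-switch condition `r = R ∧ α = β`), Weak Allee, Triple Point, Junction
Point, Strong Allee, Reverse Allee, Positive/Negative Tangential Manifold,
Hyper-Allee. A stable triple contact at the packed state `C = 1` with
`R = 0` is structural to that slice (a `(1 − C)^{6−M}` factor) and is
classified as Weak Allee, not as a triple point. The single parameter
combination `M = 0, α = 1, R = 0` (and any all-zero-rate set) makes the
growth law identically zero; it raises `DegenerateGrowthError`, and regime
maps label that cell `None`.

## Bifurcation structure (closed forms)

Three slices admit closed forms, stored as rational-function coefficient
tables and *independently* validated:

* `r = 0`: one interior equilibrium `C1` iff `β < (5 − M)/6` and `M ≤ 4`,
  via the one-to-one map `β = f(C1)` (`case1_beta_of_C1`); inverse by
  bracketed Brent iteration (`xtol = 1e-12`).
* `R = 0`: `C = 1` is always an equilibrium; a second interior equilibrium
  appears iff `α > (6 − M)/6`, via `α = g(C1)` (`case2_alpha_of_C1`).
* `r, R > 0` (with `r` normalised to 1 — other values only rescale time and
  are rescaled internally): the per-capita law `V(C)` is linear in `R` and
  `α` separately, so the tangential manifold (`V = V' = 0` at a double root
  `Ĉ`) is solvable as a 2×2 linear system. `tangential_point` solves that
  system; the closed forms `tangential_R`/`tangential_alpha` are the
  transcribed rational functions. The test suite requires the two routes to
  agree to 1e-9 (relative), which guards against transcription errors in
  the long polynomials — the dominant risk here.

The triple point (`β = H(𝒞)`, where the double root becomes a stable triple
root) is cross-validated against the second-derivative condition
`V''(𝒞) = 0` along the manifold; the junction point (`β = J(C̃)`, where the
manifold's `α` reaches 1) against the identity `G(C̃, J(C̃)) = 1`. At
`β = 0` the triple point sits at `C = 1` (so no negative branch exists
there); at `β = (5 − M)/6` both landmarks collapse to `C = 0` and the
manifold vanishes. For `M = 0` and `M = 5` the manifold does not exist.
Beyond the junction point the tangency system yields `R < 0` or `α > 1`;
`tangential_point` rejects those as outside the admissible ranges.

Numerically, the tangency system and the rational closed forms are
evaluated in extended precision (the system turns singular along a curve
in `(Ĉ, β)`, and the `G` denominator nearly cancels close to the junction
point), and the junction point is polished by Newton iteration on the
pole-free polynomial `num − den`. As `β → 0` the junction point coalesces
with a pole of `G` (root–pole distance of order `β²`), so for
`β ≲ 0.01·(5 − M)/6` the identity `G(C̃, β) = 1` is representability
limited in double precision (conditioning of order `eps/β²`); residual
checks are run above that range.

## Stochastic lattice model

Exact Gillespie simulation on a periodic rhombic domain with axial offsets
`(1,0), (−1,0), (0,1), (0,−1), (1,−1), (−1,1)` — uniform 6-degree adjacency
and no edge effects. Occupied sites are bucketed by neighbour count, giving
O(1) event selection and O(1) bucket updates per event. The event menu per
occupied site: death at `d_n`, proliferation attempt at `p_n` (uniform
target among the 6 neighbours, aborted if occupied), movement attempt at
rate `m` (same abort rule); `n` is evaluated when the event fires. Sites
with `n = 6` cannot place a daughter, so their attempt rate is dropped from
the menu (a pure efficiency choice — such attempts always abort).

The continuum law assumes spatial independence of occupancy. Motility is
the mixing knob: at `m ≈ 10 × max(p, d)` residual pair correlations still
bias the ensemble mean by up to ~0.04 in density in the test regimes;
measured bias is ~0.02 at 50× and ~0.01 at 100× (the Monte-Carlo noise
floor of 20 realisations on a 100×100 lattice). The default is therefore
`m = 100 × max(p, d)`, exposed in `AbmConfig.motility`. Agreement tests use
20 realisations of a 100×100 lattice over 4 time units with a 0.02
tolerance on `max_t |mean − ODE|`.

## Calibration

Several growth curves with different seeding densities are fitted
simultaneously with shared `(r, R, α, β, M)` and one fitted initial density
per curve; the objective is the plain sum of squared density residuals over
all curves' concatenated observations. This objective implicitly assumes
additive, homoscedastic observation noise.

Since `M` is discrete, `fit()` runs one continuous optimisation per
`M ∈ {0..5}` and keeps the smallest SSE. The continuous search is
Nelder-Mead (adaptive variant) on transformed coordinates — `log` for
`r, R`, `logit` for `α, β` and the initial densities — which enforces the
parameter ranges without constraints; raw simplex steps could otherwise
leave `[0, 1]`. The simplex method is local, so each fit uses jittered
restarts (default 5; the first run starts unperturbed from a data-driven
initial guess: observed initial densities, rates from the early log-slope
of the lowest-density curve, death ratios 0.1). Fits are deterministic for
a given seed. Rates above 500/h are rejected with a sloped penalty: they
are absurd on the hour timescale of the data and would otherwise stall the
integrator.

Inside the objective the ODE is integrated with a compiled fixed-step RK4
(step ≤ 1 h, shrunk as `0.2/max(r, R)` for fast rates), which matches the
adaptive RK45 reference solver (`rtol 1e-8, atol 1e-10`) to better than
`1e-6` in density — three orders of magnitude below observation noise — at
roughly 100× the speed. The public `solve_trajectory` keeps the adaptive
solver.

### Synthetic data generator

`generate_synthetic_growth` emulates the design of the U87 glioblastoma
monolayer assays this model has been applied to: three curves from seeding
densities 0.02/0.06/0.2, sampled every 3 h over 0–120 h (41 points per
curve; the real assays' exact sampling times are not published), densities
pre-scaled to [0, 1], plus iid Gaussian noise (default σ = 0.005) clipped
to [0, 1]. What it does *not* emulate: heteroscedastic counting noise,
temporal correlation of measurement error, plate-to-plate effects, or any
spatial structure — so recovery tests certify the estimation machinery
under the model's own assumptions, not robustness to real-data
misspecification. The packaged reference table
(`load_reference_fits`) carries the published per-`M` estimates for those
assays and is used as ground truth for recovery experiments.

Recovery under these conditions (10 seeds): `r`, `R`, `β` and the initial
densities come back tightly; `α` is weakly identified — at low densities
the data constrain mainly the net rate `r(1 − α)`, so `α` can wander
substantially at σ = 0.005. The frozen acceptance bounds reflect that
anisotropy; model selection still picks the generating threshold `M = 1`
in the large majority of seeds (2 restarts per `M` in the selection runs,
which keeps the full 10-seed experiment within a few minutes).

## Problem sizes in the test suite

Dense scans use 21×21 `(α, R)` grids over 16 `(M, β)` combinations; the
root-finder oracle comparison uses 2000 random parameter sets against a
2001-point sign-change bisection scan; closed-form fidelity uses 500-point
grids per `M`. Lattice agreement uses 2 regimes × 20 realisations of a
100×100 lattice. These sizes resolve the claimed structure while keeping
the default suite fast.

## Known limitations

* Single switch only; no multi-threshold generalisation, no spatial PDE
  limit, no alternative local-density measures (next-nearest neighbours,
  weighted averages).
* No uncertainty quantification on calibrated parameters (no profile
  likelihood or bootstrap); the per-`M` table is a point-estimate ranking.
* Regime labels within ~`1e-5` of a bifurcation manifold are resolution
  limited (see above).
* The lattice simulator supports uniformly random initial conditions only;
  no invasion fronts or agent tracking.
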