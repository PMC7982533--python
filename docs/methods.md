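# Methods

## The model

Test-day fat-yield records are analyzed with a univariate random-regression
animal model, one parity at a time:

    y_ijmnpt = G_i + YS_j + HTD_m + sum_{f=0}^{2} c_f age_n^f
             + sum_{r=0}^{2} beta_r phi_r(x_t)
             + sum_{r=0}^{ka-1} a_pr phi_r(x_t)
             + sum_{r=0}^{kpe-1} p_pr phi_r(x_t) + e_ijmnpt

where `G` is the ecotype, `YS` the calving year-season, `HTD` the
herd-test-date contemporary group, the `c_f` a quadratic regression on
calving age, the `beta_r` the fixed mean lactation curve, and `a_p`, `p_p`
the animal's additive-genetic and permanent-environment regression
coefficient vectors.  Days in milk t in [5, 270] are standardized as
x = -1 + 2 (t - 5)/265, and phi_r are orthonormal Legendre polynomials,
phi_r(x) = sqrt((2r+1)/2) P_r(x).  Random effects follow

    a ~ N(0, A ⊗ Ka),   p ~ N(0, I ⊗ Kpe),   e ~ N(0, diag(sigma_e^2(class)))

with A the pedigree numerator relationship matrix and the residual variance
constant within each of nine DIM classes (5-30, 31-60, ..., 241-270).  The
coefficient-covariance matrices are covariance functions: phi(x_s)' Ka
phi(x_t) is the additive covariance between days s and t.

Identifiability: phi_0 is constant, so the fixed curve contributes only
phi_1, phi_2 alongside the age-polynomial intercept; one reference level is
dropped per fixed factor, and any residual exact collinearity (ecotype is
nested within herd, hence within HTD) is removed by pivoted QR and logged.

## Persistency measures and variance propagation

Daily EBV curves are EBV(t) = phi(x_t)' a_hat.  Three persistency measures
and total yield are linear contrasts w of the coefficients:

* PM1 = mean EBV days 226-270 minus mean EBV days 44-62 (divisors 1/45 and
  1/19, the true window lengths);
* PM2 = per-day mean of (EBV_t - EBV_248) over days 53-247;
* PM3 = EBV(257) - EBV(80);
* TOTAL270 = sum of daily EBVs over days 5-270 (266 days; a per-day mean
  convention is also exposed).

Small absolute PM values mean a flat (persistent) genetic curve.  Variances
propagate analytically: sigma2_a = w' Ka w, sigma2_pe = w' Kpe w, and the
residual variance of a measure assumes independent daily residuals with the
pooled (records-weighted) sigma_e^2: multipliers 1/45 + 1/19 for PM1,
1 + 1/195 for per-day PM2, 2 for PM3, and 266 for the 270-day sum.
h^2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e,m) is invariant to the
sum-vs-mean convention when all three components use the same one.  Genetic
correlations are normalized quadratic forms in Ka.

Two published details are deliberately not reproduced because they are
internally inconsistent: the printed PM1 divisors ("1/44", "1/21") conflict
with the stated windows (45 and 19 days) and with the printed leading zero
of the contrast; and the printed PM2 residual multiplier (48,620) is not
derivable under either scale convention (sum: 195 + 195^2 = 38,220;
per-day: 1 + 1/195).  Both are implemented from first principles.  The
printed vector labelled for PM1 is likewise not reproducible from its
verbal definition under any scaling we tried; the vectors labelled for PM2
and PM3 are reproduced exactly but with their labels swapped relative to
the verbal definitions, which this package follows.

## REML engine

Ka, Kpe and the residual class variances are estimated by restricted
maximum likelihood, logL = -1/2 [log|V| + log|X'V^-1 X| + y'Py] (constant
omitted).  The engine absorbs each animal's permanent-environment equations
analytically — records of animal i get working covariance
V_i = Phi_i Kpe Phi_i' + R_i — leaving a system in the fixed effects and
the additive equations with A^-1 ⊗ Ka^-1.  Iteration is EM with
average-information (AI) acceleration:

* EM updates use the exact conditional expectations; the required
  prediction-error covariance blocks (additive blocks on the A^-1 sparsity
  pattern, per-animal pe blocks, per-record leverages) are recovered from
  the absorbed system's inverse by block algebra.  EM steps are monotone in
  logL and serve as the fallback.
* The analytic gradient comes from the same trace quantities; the AI matrix
  is (1/2) F' P F with F the columns dV/dtheta_k Py, each P-product costing
  one extra solve.  An AI proposal is accepted only if it does not decrease
  logL (step halving, positive-definite projection by eigenvalue clipping);
  otherwise the EM step is taken.  The first 3 iterations are plain EM.

Numerics: the absorbed coefficient matrix (~5,400 equations at the study
scale) is factorized densely (LAPACK Cholesky; the full inverse via potri)
for EM/AI iterations, and sparsely (SuperLU with the symmetric MMD
ordering) for likelihood-only evaluations during step control.  log|A| is
accumulated from the pedigree L D L' decomposition; inbreeding enters A^-1
through Meuwissen-Luo coefficients.  Convergence is |dlogL| < tol
(default 1e-6, max 500 iterations); non-convergence returns the last
iterate flagged, not an exception.  Starting values are
Ka = Kpe = 0.1 var(y) I, sigma_e^2 = 0.8 var(y); well-conditioned
simulations reach the same optimum from different PD starts (tested).

Everything is verified against dense first-principles oracles at small n:
the likelihood against the textbook V-matrix formula, the gradient against
finite differences, the BLUP solution against the joint-MVN conditional
mean, and A^-1 against the dense inverse of the tabular A.

Model choice across orders of fit reports a table (ka, kpe, NP, logL) with
NP = ka(ka+1)/2 + kpe(kpe+1)/2 + 9 (the nine residual classes are what
makes NP match the published parameter counts, e.g. 21 for (3,3) and 45 for
(5,6), although the published variance-propagation formulas treat sigma_e^2
as a single constant — the pooled scalar exported for propagation bridges
the two).  Default selection is likelihood-ratio testing among nested pairs
at P < 0.05, preferring the fewest parameters; raw max-logL selection is a
flag.  The published selection narrative is contradictory (the text selects
by maximum log-likelihood, but the starred models for lactations 2 and 3
have the lowest logL of their columns); both orderings are therefore
reported and the rule is explicit.

## Synthetic data generator

The generator emulates the *structure* of the edited recording data — the
real records are proprietary, so all numerical results in this repository
are synthetic-data results.  Structure constants: DIM 5-270; 4-9 tests per
lactation (herd-level test-date grids every 30 days with random per-herd
offsets create genuine HTD contemporary groups and this test-count range);
3 ecotypes assigned at herd level; 4 calendar-quarter seasons; calving
years 1996-2012; per-parity calving-age windows 24-60 / 39-76 / 54-100
months; per-parity edits exactly as listed (DIM range, test count, age
window), with an exclusion log.

Generating parameters (defaults, kg^2; chosen once so that the DIM-class
summary lands at means ~0.43-0.51 kg and SD ~0.25 kg and the implied PM
heritabilities sit inside the published 0.19-0.48 range):

* Ka   = [[0.012, 0.002, 0.001], [0.002, 0.006, 0.0015], [0.001, 0.0015, 0.004]]
* Kpe  = [[0.014, 0.002, 0.001], [0.002, 0.007, 0.001], [0.001, 0.001, 0.004]]
* sigma_e^2 by class: 0.034 down to 0.028 (mild early-to-late heterogeneity)
* mean curve beta = (0.672, -0.004, -0.02); ecotype / year-season / HTD
  effect SDs 0.03 / 0.03 / 0.05 kg; age regression (0, 0.02, -0.01) on the
  window-scaled age.

These imply PM heritabilities 0.46 (PM1), 0.24 (PM2), 0.26 (PM3) and 0.46
for 270-day yield.  Breeding values are sampled by the pedigree recursion
(exactly N(0, A ⊗ Ka), animal-major), permanent-environment vectors iid
per animal-lactation.  Contemporary-group effect draws are centered over
their observed levels so the population mean is governed by the mean curve.
Everything is deterministic given the seed.

What the generator does not emulate: culling/selection over years, the
real rise-then-fall class-N pattern of test counts (a per-class sampling
weight hook exists instead), seasonal calving waves, and multi-parity
genetic correlations (each parity is simulated and analyzed separately, as
in the source analysis).  Recovery results therefore show the estimator is
correct under the model's own assumptions at desk scale, not that the real
data satisfy those assumptions.

## Study conditions and problem sizes

* REML recovery: 1,500 recorded animals x 6 tests (9,000 records) in
  half-sib/full-sib families from 150 founders, ka = kpe = 3, five seeds,
  fitted with tol 1e-3 and up to 30 iterations (the AI phase typically
  converges in 8-10).  Estimates are averaged over seeds before comparison.
* Trend calibration: ~450 recorded animals over 3 generations and ~13
  calving years from 250 founders.  The founder-rich base keeps annual
  cohort means approximately independent, so the OLS standard error on
  annual means is calibrated.  The null study (50 replicates) runs the full
  simulate-BLUP-measure-regress pipeline and pools the three PM measures;
  the coverage study (50 replicates) injects a gain of 0.01 kg/yr (drift of
  the flat coefficient per calving year) and applies the trend estimator to
  the true breeding values.
* Oracle checks run at n <= 50 records / n <= 200 pedigree animals.

Known desk-scale limitation: BLUP-estimated EBVs at these population sizes
attenuate genetic trends heavily (measured ~3-4x: an injected or
selection-generated gain of 0.01 kg/yr yields an EBV-based slope of
~0.003-0.004), because the time signal is partly absorbed by year-season
and herd-test-date fixed effects and cohort contrasts are shrunk at low
per-animal reliability.  Trend recovery from estimated EBVs requires
national-evaluation amounts of information (deep pedigrees, large progeny
groups); the coverage study therefore validates the estimator on true
breeding values, while the null study validates the full pipeline's type-I
behaviour.

## Numerical choices and degenerate inputs

* MME solves are direct (sparse LU, MMD ordering) with one step of
  iterative refinement; the relative-residual contract is 1e-10.
* PD maintenance: eigenvalue clipping at 1e-8 of the largest eigenvalue;
  residual variances floored at 1e-12.  Residual classes without records
  are left at their current value (zero gradient).
* Ties/degenerates: a zero-variance contrast makes a genetic correlation
  undefined (error, not NaN); a perfectly constant trend response returns
  slope 0 with p = 1; pedigree cycles and duplicate ids are structural
  errors naming the offender; unknown parents are unrelated non-inbred
  founders (no genetic groups).
* The calving-age covariate is centered at the parity-window midpoint and
  scaled to [-1, 1] before the quadratic regression (conditioning only; the
  model is an equivalent reparametrization of raw age powers).
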