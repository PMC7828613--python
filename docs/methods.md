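# Methods

## Scientific setting

The package analyses the association between household air pollution
(unclean cooking fuel) and adverse birth outcomes in a DHS-style national
survey: ~41.8k women aged 15–49 contributing ~127.5k birth records, nested
in 37 areas (36 states plus a capital territory) grouped into six
geopolitical regions. Stillbirth is recorded for every pregnancy; birth
weight and pregnancy duration have very low response (93.9% and 68.8%
missing respectively), so the low-birth-weight and preterm analyses run on
small complete-case subsets. Unclean fuel use (~89.3% prevalence) is
strongly graded in household wealth, which is why wealth is kept out of
the adjusted models.

Because the microdata are restricted, the package is validated two ways:
the descriptive layer is checked *exactly* against the published table's
printed counts, and the modelling layer is checked by parameter-recovery
and oracle-agreement experiments on synthetic cohorts with known truth.

## Probit STAR model

For outcome Y_i ∈ {0,1} of birth i,

    Pr(Y_i = 1) = Phi(eta_i)
    eta_i = gamma' x_i + f(age_i) + b_{m(i)} + u_{s(i)} + v_{s(i)}

- Fixed effects gamma: intercept, unclean-fuel indicator, and dummy-coded
  education (reference: no education) and region (reference:
  North-Central) in the fullest model. Flat priors, implemented as
  Gaussians with precision 1e-8 for numerical stability.
- Age smooth f: cubic B-splines on equidistant knots spanning the observed
  age range (20 interior knots by default), coefficients under a
  second-order random-walk prior with precision tau_beta * K, K = D2'D2.
  All three knobs are configurable; the defaults are the conventional
  P-spline choices and are deliberately generous — the penalty, not the
  basis size, controls effective smoothness.
- Mother random intercepts b: i.i.d. N(0, sigma_b^2); the device that
  absorbs correlation between births of the same mother.
- Structured spatial effect u: intrinsic CAR prior with precision
  tau_u * Q, Q = diag(degree) − adjacency; improper of rank n−1 on a
  connected graph. Disconnected graphs are rejected.
- Unstructured spatial effect v: i.i.d. N(0, sigma_v^2) per area.
- All variances: inverse-Gamma(a, b) with a = b = 0.001 (weakly
  informative), configurable.

### Sampler

Albert–Chib augmentation: z_i ~ N(eta_i, 1) truncated to (0, ∞) if
y_i = 1, (−∞, 0) otherwise; then all blocks have Gaussian full
conditionals and variances have inverse-Gamma conditionals with shape
a + rank/2 and scale b + quadratic_form/2 (rank: m−r for the spline,
n_mothers and n_areas for the i.i.d. blocks, n_areas−1 for the ICAR
block). Mother and unstructured-area updates are conditionally independent
scalar draws (vectorised via bincount); the spline and ICAR blocks use
dense Cholesky solves (m ≈ 24 and n_areas ≈ 37, so dense is cheap).

Truncated-normal draws use an inverse-CDF formulation written against the
*survival* function of the constrained tail, z = eta − Phi^{-1}((1−U)·
Phi(eta)) for the positive branch, which stays accurate when the
constraint pushes z far into a tail; arguments are clipped at 1e-300 and
the result is forced onto the correct side of zero at 1e-12.

Identifiability: the spline's fitted values and the structured spatial
vector are re-centred to mean zero every iteration, with the intercept
absorbing both shifts (centring rather than corner constraints; the
re-centred quantities are stored per draw and tested to ≤ 1e-8 — in
practice they sit at machine precision). Centring-only is also how the
u + v convolution pair is handled; no further joint constraint is applied.
When region fixed effects and state-level spatial effects appear together
(Model 4), the region contrasts and the state fields are partially
confounded; the spatial fields remain identified through within-region
contrasts, but region coefficients should be read with that caveat.

Degenerate inputs: areas with no observations keep their prior-only
conditional (the ICAR draw smooths them toward neighbours) rather than
raising. A variance draw above 1e6 is recorded as a divergence flag in the
draw log, not an exception.

Chain defaults follow the conventional schedule for this model family:
25,000 iterations, 5,000 burn-in. Thinning is 10 by default (storage;
2,000 stored draws). Effective sample size and split-chain R-hat are
reported per parameter in the fit summary; no automatic stopping.

### DIC

Dbar = mean stored deviance, with deviance −2 Σ[y log Phi(eta) +
(1−y) log Phi(−eta)]; D_hat = deviance at the posterior-mean parameters
(all stored blocks averaged, including the running mean of the mother
effects); pD = Dbar − D_hat; DIC = Dbar + pD. The identity DIC = Dbar + pD
holds exactly by construction and is asserted in tests; on a near-flat
fixed-effects fit pD reproduces the parameter count to a few percent.

### Model ladder

Model 1: fuel + both spatial components. Model 2: + mother effect.
Model 3: + age smooth. Model 4: + education and region (wealth excluded
for collinearity with fuel; requesting both emits a recorded warning).
Each model in a ladder run gets a deterministic seed offset from the
master seed so DIC comparisons never reuse a random stream. MCMC settings
are shared across outcomes in a pipeline run. Selection = smallest DIC
among completed fits; a failed fit is recorded in the manifest and the
ladder continues.

## Synthetic cohort generator

The generator emulates the survey's statistical structure: mothers are
assigned a uniform area on the contiguity graph, age from a truncated
normal(29.5, 9.5) on [15, 49], education and wealth from the published
marginal shares, and a fuel indicator whose log-odds fall by
`fuel_wealth_log_odds` (default 1.8) per wealth-quintile step — the
default gradient makes naive joint fuel+wealth fits unstable, reproducing
the collinearity that motivates excluding wealth. The base log-odds are
calibrated by root-finding so the *marginal* unclean prevalence equals the
configured 0.893 whatever the gradient. Births per mother are truncated
geometric on {1..15} with mean ≈ 3.05 (the ratio of the published birth
and mother totals). Outcomes are drawn Bernoulli(Phi(eta)) with eta built
from the recorded truth: fuel coefficient (default 0.14, the adjusted
stillbirth estimate's scale), a monotone scaled-logistic age effect
centred on [15, 49] (stillbirth risk rising with age), mother effects
(sigma 0.3), an ICAR field sampled exactly in the sum-to-zero eigenbasis
of Q (covariance sigma^2 · pinv(Q)) and an i.i.d. area field. The three
outcomes share this covariate and random-effect structure with
outcome-specific intercepts (Phi^{-1} of 0.143, 0.0727, 0.01); birth
weight and duration then receive independent missingness masks (93.9% and
68.8%).

On the age distribution: the published table's overall mean age (35.9)
conflicts with its own by-fuel means (~29.5); the generator follows the
by-fuel means.

What the generator does *not* emulate: the two-stage stratified cluster
sampling design and its weights (the models under study do not use them),
geographic coordinates, within-mother outcome trends over time, and any
missingness that depends on outcome or covariates (masks are independent
by design, and tested to be). Passing recovery tests therefore show the
estimator is correct *under the model's own assumptions*, not that the
model is robust to informative missingness or survey design effects.

A note on marginal outcome rates: with nonzero random-effect variances the
marginal stillbirth fraction exceeds Phi(intercept) (E[Phi(c + e)] >
Phi(c) for c < 0 and symmetric e), so the default cohort runs at ~19%
rather than 14.3%; the calibration checks use null effects, where the
intercept maps to the marginal rate exactly.

## Adjacency fixture

The 37-area contiguity graph shipped with the package is a hand-encoded
approximation of Nigeria's state adjacencies (connected, symmetric, no
self-loops, six populated regions). It exists so spatial code can be
exercised on a realistically irregular graph; nothing in the model code
depends on it being cartographically exact, and lattice generators are
provided for controlled tests.

## Descriptive layer

Prevalence ratios use the Katz log interval; odds ratios the Woolf
interval; neither applies continuity corrections, and zero cells raise
rather than being Haldane-corrected (the report generator records such
rows with blank estimates). These interval choices reproduce every
published interval at two decimals. Association tests use Pearson
chi-square without Yates correction, switching to Fisher's exact test for
2×2 tables with any expected cell below 5. The published table mixes
estimators by row type — prevalence ratios for binary birth-level and
smoking rows, odds ratios against a reference level for mother-level
categoricals — and the report generator applies the row-appropriate one.
The reference level is a parameter: the published region rows labelled
"South-East (ref)" numerically match odds ratios against South-West, so
no reference is hard-coded.

## Problem sizes and test design

Unit tests run on small cohorts (hundreds of mothers) and short chains.
The end-to-end experiments use reduced but honest scales chosen once:
oracle agreement at n = 5,000 births with 4,000 post-burn-in draws;
credible-interval coverage over 20 replicate cohorts of ~5,100 births with
3,000-iteration chains (expected ≥ 17/20 coverage of the generating fuel
effect at nominal 95%); the DIC ladder over 5 replicate cohorts of ~3,700
births comparing Models 1 and 3 (the pair the ordering claim concerns);
Katz coverage over 2,000 tables of 200 + 200 with true PR 2. Monte-Carlo
tolerances follow binomial/chi-squared error at those sizes (3–4 sd), and
stochastic tests are seeded, so the suite is deterministic.

## Known limitations

- Survey weights are not implemented anywhere; estimates are unweighted.
- Complete-case analysis only, as in the source analysis; with 93.9%
  missing birth weight the LBW model runs on ~6% of births and is
  correspondingly noisy.
- The ICAR and spline blocks use dense linear algebra — fine for tens of
  areas and ~24 basis functions, not for thousands of areas.
- pD can be negative for badly mixing chains (a known property of the
  plug-in DIC); the divergence log and R-hat columns are the diagnostics
  to watch.
- Region fixed effects together with state-level spatial effects
  (Model 4) are partially confounded by construction; see above.
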