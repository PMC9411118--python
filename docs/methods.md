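# Methods

This note documents the models implemented in `leafphos`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about behaviour on real field data.

## Leaf photosynthesis model

C3 net assimilation follows the Farquhar–von Caemmerer–Berry (FvCB) scheme:
the minimum of a Rubisco-carboxylation-limited rate
`A_c = Vcmax (Ci − Γ*)/(Ci + Km)` with `Km = Kc (1 + O/Ko)`, and an
RuBP-regeneration-limited rate `A_j = J (Ci − Γ*)/(4 Ci + 8 Γ*)`, minus day
respiration `R_d`. Because the package targets CO2-response curves measured
at saturating light, electron transport is taken at capacity (`J = Jmax`)
during curve fitting; the canopy engine instead passes `J` through a
non-rectangular hyperbola of absorbed light (see below). Triose-phosphate
(TPU) limitation is not modelled: curves are fitted with the two canonical
limitations only. Mesophyll conductance is infinite by default, so all rates
are apparent (Cc = Ci); a finite-gm mode (quadratic solution per limitation)
exists for sensitivity checks but is off by default.

### Temperature responses

All biochemical parameters are stored at 25 °C and scaled on evaluation:

- Kc, Ko, Γ* and R_d: Arrhenius, `exp((Ea/R)(1/298.15 − 1/T_K))`.
- Vcmax and Jmax: a peaked (deactivating) Arrhenius function with
  deactivation energy Hd and entropy term ΔS, normalised so the factor is
  exactly 1 at 25 °C.

Defaults are the Bernacchi in-vivo constants
(Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹, Γ*25 = 42.75 µmol mol⁻¹,
O = 210 mmol mol⁻¹, Ea = 79 430 / 36 380 / 37 830 J mol⁻¹) with
Kattge–Knorr acclimation of the entropy terms to growth temperature:
ΔS_V = 668.39 − 1.07·Tgrowth, ΔS_J = 659.70 − 0.75·Tgrowth (J mol⁻¹ K⁻¹),
Ha_V = 71 513, Ha_J = 49 884, Hd = 200 000 J mol⁻¹. Every constant is a
config key (`leafphos.coefficients.load_kinetics`) and is echoed into output
headers for provenance. Whether R_d should be temperature-corrected before
normalisation is genuinely open; the default applies Arrhenius with
Ea = 46 390 J mol⁻¹, and this is flagged as an assumption.

Normalisation to 25 °C is the exact multiplicative inverse of the forward
scaling; the round-trip identity holds to < 1e-10 relative and is tested for
every parameter class.

## Curve inversion

`fit_aci` minimises the sum of squared residuals of the forward model over
(Vcmax25, Jmax25, Rd25), scaling parameters to each point's measured leaf
temperature, so estimates come out at the 25 °C reference directly. Numerical
choices:

- hard `min(A_c, A_j)` in the objective (no hyperbolic smoothing): piecewise
  smooth almost everywhere and matching the conventional fitting behaviour;
- bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
  with bounds [1, 500] × [2, 1000] × [0, 50] µmol m⁻² s⁻¹ and three fixed,
  seed-free starting points; the best optimum is kept;
- `x_scale = (50, 100, 1)` conditions the problem; tolerances 1e-10 (xtol)
  and 1e-8 (ftol/gtol). If no start converges formally, the best solution is
  still returned but flagged `converged = False` — never silently dropped;
- the "CV of the initial slope" inclusion statistic is computed as the
  relative standard error of the fitted Vcmax25 from the Jacobian-based
  covariance at the optimum (s² (JᵀJ)⁻¹). The alternative reading — CV of a
  raw initial-slope regression — is not used; the fitted-parameter version
  is the better-defined estimator and is what the QC gate consumes.
- a warning (not an error) is issued when the Ci range does not span both a
  low (< 250) and a high (> 400 µmol mol⁻¹) region, where Vcmax and Jmax
  separate poorly.

On noiseless synthetic curves the inversion is exact to optimizer tolerance
across the physiological parameter range; with Gaussian instrument noise of
sd 0.5 µmol m⁻² s⁻¹ on an 11-point grid the empirical Vcmax CV is ≈ 4% and
the median absolute error ≈ 3%.

## Quality control and aggregation

Three inclusion rules, each tagged independently so a removed record lists
every rule it failed: mean gsw ≥ 30 mmol H2O m⁻² s⁻¹ (below this, diffusion
rather than biochemistry may limit assimilation), A_mass > 20 nmol g⁻¹ s⁻¹
(strict), and curve-fit CV < 30%. Records missing a QC field are removed
with a MISSING_FIELD tag rather than silently kept. The filter is
idempotent.

Leaves passing QC are averaged arithmetically to one record per species ×
site — the analysis unit. Mass-based fields are averaged directly (not as
ratios of group means): averaging order for ratio quantities is genuinely
ambiguous, and direct averaging keeps each basis internally consistent. The
mass/area identity `X_mass = 1000 · X_area / Ma` is therefore enforced per
leaf, not for group means. Conflicting continent labels within a group are a
data-integrity error.

## Trait statistics

All bivariate trait fits are on natural logs (traits are approximately
log-normal). Reported statistics mirror the conventional table layout:
slope, intercept, r², F, p and denominator degrees of freedom.

- **SMA** (standardised major axis), the symmetric secondary fit:
  slope = sign(r)·sd(ln y)/sd(ln x) through the means. The identity
  |b_SMA| = |b_OLS|/|r| is exact and is tested to 1e-10.
- **Separate-slopes test**: full interaction model ln y ~ ln x × group versus
  the parallel-slopes reduction, compared by F-test on the interaction
  block (built on explicit design matrices for speed; statsmodels OLS
  underneath). Groups with n < 3 are excluded with a warning entry. Under a
  common generating line the test's type-I rate calibrates to the nominal
  5% level (tested over 1 000 replicates).
- **N × P interaction model**: ln y ~ ln N + ln P + ln N·ln P (+ ln Ma),
  with rank-deficiency detection and term-wise 1-df F-tests (t²).
- **Leaf-P classing**: low is P_mass < threshold, moderate is ≥ threshold,
  default 0.92 mg g⁻¹; a threshold sweep reports both class slopes and the
  interaction p across thresholds, flagging (never dropping) thresholds that
  leave a class with n < 10.
- Derived contrasts: `fold_change(slope, k) = k^slope`;
  `class_contrast_at(x0)` is the percent offset between two ln-scale lines
  at x0.
- No multiple-testing correction is applied across continent-vs-remainder
  tests; raw p-values are reported, matching the convention of the headline
  tables this machinery mirrors.

## Published coefficients as data

`data/coefficients.yaml` ships the forward predictor equations (the
"methods" main-effects set used for canopy modelling, and the "table2"
full-dataset interaction set — the two differ, the interaction set giving a
somewhat stronger P effect), the Ma(N, P) model, the single-factor class
lines, the linear Jmax–Vcmax class lines, and the P-acquisition sigmoid.
Coefficients are data, not code: they are loaded at run time, selectable by
name, and never refitted by the predictor module. The mass- and area-basis
equations are independent fits; converting the mass prediction through the
Ma model approximately reproduces the area fit in rank (ρ > 0.95 over the
trait range) but not in value, so the two routes are never chained silently.
One shipped row — the all-P Jmax–N line (slope 0.310, intercept 8.564) — is
internally inconsistent with its class rows and is excluded from generator
defaults and verification.

The P-acquisition scalar `f(N:P) = 1/(1 + exp(−(N:P)/2 + 10))` has its
midpoint at N:P = 20 and rises sharply between 15 and 25, the range where
plant communities transition from N- to P-limitation. N:P is always the
mass ratio (g N per g P). Unlimited P supply is defined as the leaf P
ceiling at the minimum N:P of 5, i.e. P_mass = N_mass/5.

## Canopy scenario engine

The GPP engine is intentionally minimal plumbing around the published leaf
biochemistry: big-leaf canopy with Beer-law light extinction (k = 0.5),
capacity scaling (1 − e^(−k·LAI))/k, absorbed light fraction 1 − e^(−k·LAI),
non-rectangular-hyperbola light response (θ = 0.7, quantum yield 0.3 e⁻ per
photon), fixed Ci/Ca = 0.7, a 12-h half-sine photoperiod integrated in 48
steps over 365 days, and leaf temperature equal to growth temperature. None
of these constants is a published value; each is a `CanopyConfig` key. GPP
is gross — R_d is not subtracted. The unlimited-P scenario raises each
cell's leaf P to N/5, never lowering it; the P-acquisition scalar is
reported per cell as a diagnostic only, with no feedback. Zonal aggregation
uses 2° bands with cos-latitude weights.

This module verifies direction and structure — unlimited-P GPP ≥ limited-P
GPP cell-wise, zero reduction at N:P = 5, reduction monotone in observed P,
bit-identical reruns — not magnitude. Pan-tropical absolute numbers (e.g. a
~36% zonal GPP reduction, ~70 Pg C differences, zonal GPP levels) depend on
a full land-surface model with historical forcing and spin-up and are
explicitly out of scope here.

## Synthetic data

The generators emulate the *assumed statistical structure* of the field
compilation: bivariate log-normal (N, P) with squared log-correlation 0.39
(the dataset-scale value), defaults n = 446 records, ln N centred at
ln 20 mg g⁻¹ (sd 0.30), ln P centred at ln 0.92 mg g⁻¹ (sd 0.65, giving a
~50-fold P range at n ≈ 450); responses from the shipped coefficient sets
with Gaussian log-scale residuals; linear-scale Gaussian noise for A–Ci
curves (instrument noise); uniform-random continents with no continent
effect (matching the null finding for continent-specific slopes).

Residual spreads are not published; noise is calibrated to the printed r²
by the closed form `sd_resid² = var(fitted)·(1 − r²)/r²`, which makes the
expected r² match the target (verified against a grid-search oracle). This
is a reconstruction, and its labels carry through the generators'
docstrings.

What passing tests therefore establish: the estimators are unbiased and
correctly calibrated *under the generating model* — homoscedastic log-normal
residuals, no phylogenetic or spatial structure, no measurement error in
the nutrients. Real data violate all three to unknown degrees; the tests
say nothing about those violations.

A note on detection power: with noise calibrated to a class's r², the slope
standard error is slope·√((1−r²)/r²)/√n regardless of predictor spread, so
the separate-slopes test at the published class slopes, r² values and group
sizes has analytic power ≈ 0.88 at α = 0.05 — the suite tests the empirical
rate against that analytic value rather than against a rounder figure.

## Degenerate inputs and tie-breaks

Constant response in OLS → slope 0, r² = 0, p = 1 (F undefined → 0). Exactly
collinear design columns → explicit rank-deficiency error naming the terms.
A_c = A_j ties in the FvCB minimum resolve by value equality (the min is
well-defined; the objective is continuous there). Noiseless data in the
separate-slopes test are detected by an SSR threshold of 1e-12 × TSS and
return F = 0, p = 1 (or p = 0 if the parallel model is genuinely worse).
Temperature scaling outside [0, 50] °C is an input error; factor underflow
in normalisation raises rather than returning infinities.

## Problem sizes

Monte-Carlo checks use 500 replicates at the study's sample sizes (n = 111
for the J–V line, n = 446 for the interaction model), 200 seeds for
inversion-noise calibration, 1 000 replicates for type-I calibration, and
n = 10 000 for generator calibration — sizes at which the Monte-Carlo error
of each checked mean is several times smaller than the assertion tolerance.

## Known limitations

- No TPU limitation, C4 pathway, stomatal model or energy balance.
- No mixed-effects or phylogenetic regression; species-site means are
  treated as independent.
- The canopy engine's absolute GPP values are arbitrary up to its invented
  plumbing constants; only comparisons within a configuration are
  meaningful.
- Drought screening of curves (a judgement call in field compilations) has
  no computable rule and is not implemented.
- The QC CV rule is applied to the fitted Vcmax25 parameter; compilations
  that computed it from a raw initial-slope regression may retain a
  slightly different record set near the 30% boundary.
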