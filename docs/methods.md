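# Methods

## Problem setting

The package analyses annual, region-level, age-stratified counts of a
childhood disease (the motivating case is Kawasaki disease across 47
Japanese-prefecture-like regions) together with demographic and
climatic/socioeconomic covariates. Two epidemiological quantities are the
dependent variables throughout: incidence (all-age cases per 100,000
children aged 0–4 years) and mean patient age. Under the catalytic model
of infection with a constant force of infection λ and lasting immunity,
the mean age at first infection is approximately 1/λ, so mean patient age
serves as an inverse surrogate of the hazard of acquiring the aetiologic
agent — a quantity that incidence alone does not reliably reflect (e.g.
under endemic stability, a high hazard can coexist with low symptomatic
incidence).

## Age schemes and metrics

Cases arrive on a fine 19-class scheme: three-month classes up to 23
months, six-month classes at ages 2–3, one-year classes at 4–9, and an
open ≥10-year class. Census-resolution populations use the coarse
11-class scheme (<1 y, nine one-year classes, open ≥10 y) onto which the
fine classes nest exactly; aggregation conserves counts. Bounded-class
midpoints are interval midpoints in years ((lower+upper)/2/12 with
half-open month bounds); the open class has no natural midpoint and
defaults to 10.5 years (15 years is the conventional sensitivity
alternative — patients above 10 are rare, so results are insensitive).

Crude mean age is the case-weighted mean of midpoints. The adjusted mean
age reweights each class count by S_k/C_k — the ratio of the standard
population share to the local share — so that a region with an unusually
young pyramid is not reported as having young patients merely for
demographic reasons; when the local structure equals the standard the
adjustment is exactly neutral. Age-adjusted incidence uses direct
standardization. Pooled (per-region) variants sum the age-stratified
counts over the study period and use the period-averaged population
structure, damping epidemic-year and seasonal oscillation before
cross-sectional regression. Zero-case cells yield *missing* metric values,
never zero: a mean age of no patients is undefined, and a zero would bias
regressions.

## Normalization

Dependent variables are skewed; each analysis normalizes its own sample
with the one-parameter Box-Cox transform, θ estimated by maximizing the
profile log-likelihood (normal likelihood of the transformed sample plus
the Jacobian term (θ−1)Σln y). The default search interval is [−5, 15] —
generous because pooled mean-age samples can need exponents around 10 — 
scanned on an 81-point grid and refined by bounded scalar minimization;
the grid guards against local optima over so wide an interval. The
transform kernel is `scipy.special.boxcox`, which stays accurate and
monotone for |θ| near 0. θ is reported per dependent variable and
analysis in the run manifest. A configuration flag bypasses normalization
entirely for sensitivity runs; tests assert that retained coefficient
signs are unchanged.

## Cross-sectional and spatial regression

Period-pooled metrics per region are regressed on period-mean covariates
(a helper averages each covariate over the period, requiring ≥50% year
coverage). Regions are not independent samples — neighbours resemble each
other — so alongside OLS the package fits the spatial-lag model
Y = ρUY + Xβ + ε by maximum likelihood. The adjacency U is binary
(0/1 for geographic adjacency or a bridge/tunnel link), deliberately *not*
row-standardized; consequently the admissible ρ interval is
(1/ω_min, 1/ω_max) from U's extreme eigenvalues. The likelihood is
concentrated: β and σ² have closed forms given ρ, and the concentrated
log-likelihood (including log|I−ρU| = Σ log(1−ρω_i)) is maximized by
bounded scalar search. Standard errors come from the observed information
(numerical Hessian of the profile log-likelihood in (ρ, β)) with
normal-approximation p-values — standard ML practice; a likelihood-ratio
alternative would be asymptotically equivalent.

Backward elimination removes one covariate per step — the largest p-value
at or above α = 0.05 — and refits until all retained terms are
significant. One-at-a-time removal is the conventional reading of
"stepwise" and makes the retained set independent of column order when
p-values are distinct. If everything is eliminated, an intercept-only fit
is returned and flagged.

## Lagged panel regression

Exposure plausibly precedes effect by years (a cohort's infection hazard
reflects the fertility environment of its early childhood), so covariates
enter as window means over [j−G−W, j−G+W]: lag G, smoothing radius W,
both whole years. Windows with any missing year yield a missing value —
partial windows would silently change the effective lag near the record
start — which reproduces the natural shrinking of n as G grows beyond the
covariate record. Biennially surveyed covariates are first interpolated
linearly across single-year gaps (never extrapolated).

The panel model is Y_ij = α + X_ij β + ν_i + ε_ij with i.i.d. region
random effects ν_i and AR(1) errors ε_ij = φ ε_{i,j−1} + η_ij, one φ
pooled across regions. Estimation is deterministic two-step feasible GLS:

1. pooled OLS (consistent under random effects);
2. φ̂ from the lag-1 autocorrelation of within-region-demeaned residuals
   over consecutive-year pairs, plus the first-order small-T correction
   φ̂ + (1+3φ̂)/T̄ for the Nickell-type downward bias that within-region
   demeaning induces (at T ≈ 11 the raw estimate is biased low by ≈ 0.15);
3. Prais–Winsten quasi-differencing within each region's consecutive
   runs (run-initial rows scaled by √(1−φ̂²));
4. Swamy–Arora random-effects GLS on the transformed data: the within
   regression (keeping the quasi-differenced intercept column, which no
   longer demeans to zero) estimates the innovation variance, the between
   regression the random-effect variance, and partial demeaning with
   region-specific θ_i gives the GLS fit and classical standard errors.

Full ML (e.g. via a mixed-model routine) would be an admissible swap; the
two-step estimator was chosen for determinism, speed under grid search
(closed form, ~1 ms per fit), and because validation is by parameter
recovery, which it passes. Regions contributing fewer than 3 consecutive
years are dropped with a warning — φ is unidentified there.

"Overall R²" — the grid-search criterion — is the squared correlation
between the fixed-part prediction α̂ + Xβ̂ and the observations over
complete cases, the conventional "overall" statistic for panel models. The
grid search spans G ∈ [0, 30], W ∈ [1, 5] by default (configurable); W = 0
is excluded because point lags give unstable R²-versus-G profiles. The
dependent variable is restricted to a fit window (default 2000–2010: a
balanced 47-region panel there has n = 517). Ties break toward smaller G,
then smaller W. Multivariate fits reuse each covariate's
univariate-optimal (G, W) — specs are fixed per covariate before joint
modelling — then backward elimination proceeds as in the cross-sectional
case.

## Reconstruction

A univariate panel model (metric on lag-smoothed TFR) is applied to a
*national* TFR series: for each target year, the normalized prediction
α̂ + β̂·(window mean) is mapped back through the inverse Box-Cox.
Transferring a region-level model to the national series is a modelling
leap; the provenance manifest records every ingredient (covariate, G, W,
θ, coefficients, series span), making the step explicit and the output
bit-reproducible. Only the fixed part is used — random effects and AR
noise are region-level and average out nationally — so epidemic-year
excursions are not expected to be reproduced. Years whose window precedes
the series start are reported missing (no padding); predictions that leave
the admissible range of the inverse transform are clamped at zero and
logged.

## Synthetic-data generator

The generator emulates the structure of a nationwide surveillance panel:
47 regions on a near-square lattice adjacency (a stand-in for prefecture
contiguity), annual years 1979–2010, seven covariates (temperature,
rainfall, biennial physician density, population density, aged population,
higher education, TFR) drawn as spatially autocorrelated fields (SAR
construction on the row-normalized lattice, spatial parameter 0.5) with
deterministic temporal trends. TFR starts near 2.2, declines by 0.012/yr
in expectation with a floor at 0.8, carries a between-region level spread
(sd 0.25), a persistent region-specific AR(1) wander (stationary sd 0.15,
persistence 0.9), and year-to-year noise (sd 0.03). The wander matters
structurally: a shared trend plus white noise leaves the lag G
unidentified (every lag of a trend differs only by a constant the
intercept absorbs), whereas real regional fertility follows visibly
different decade-scale paths.

Two outcome generators share this scaffolding. The *linear-panel*
generator draws Y directly from the random-effect AR(1) model at an
embedded (G* = 15, W* = 2) with α = 10, β = −6, φ = 0.5, ν and η standard
deviations 0.3 — used for estimator validation by parameter recovery. The
*catalytic* generator sets a per-region-year hazard
λ = a + b·(windowed TFR) (identity link by default, a = 0.05, b = 0.35,
window G = 2, W = 1; a log link is available), distributes expected ages
at first presentation as Exponential(λ) over the fine age classes, thins
the mass below a passive-immunity cut-off (6 months; protection
probability 0 by default — the cut-off is a hypothesis-exploration switch,
not a calibrated value), and draws class counts as Poisson with intensity
scaled to cohort_size × case_fraction = 200 expected events per
region-year, roughly the caseload of a mid-sized prefecture. The positive
default b encodes the sibling-transmission interpretation: more children
per family, higher hazard, younger patients. Population pyramids take
cohort sizes proportional to the TFR lagged by each class's age, so crude
and adjusted mean ages genuinely differ. All outputs are byte-for-byte
reproducible from the scenario seed.

What the generator does *not* emulate: reporting-rate variation, epidemic
years, seasonality, contact-network or household structure, and any
quantitative maternal-antibody dynamics. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
fidelity of the model to real surveillance data.

## Validation design and numerical choices

- Box-Cox recovery: data generated as inverse-transform of a normal
  (N(8, 2.5), truncated to the admissible domain) at θ₀ = 1.8, n = 500;
  the 50-seed mean of θ̂ recovers θ₀ well within ±0.3 (per-seed SD ≈ 0.15).
- Spatial lag: Y = (I−ρU)⁻¹(Xβ+ε) on the 47-node lattice at ρ = 0.1; the
  200-seed mean of ρ̂ falls within two Monte-Carlo standard errors, and
  fixing ρ = 0 reproduces OLS to 10⁻⁶.
- Panel FGLS: 47×11 panels; 200-seed mean of β̂ within two MC-SE of −6,
  mean φ̂ within 0.1 of 0.5.
- Lag selection: (15, 2) is the modal selection over 100 seeds, with G
  within ±1 of 15 in well over 80%.
- Catalytic law: pooled mean age within 5% of 1/λ at ~10,000 events per
  region (class-midpoint discretization contributes a bias of order
  −0.05 y at λ = 0.5, inside that band), and a positive TFR→λ link yields
  a negative TFR–mean-age correlation across regions in ≥90% of seeds.
- Reconstruction: in-sample backcast correlates >0.9 with the generated
  national trajectory; a single hand-computed year matches to 10⁻¹⁰.

Tie-breaks, floors and tolerances: grid-search ties resolve at 10⁻¹² in
R²; the inverse Box-Cox clamps to a configurable floor (0 for
reconstructions) with a warning; |φ̂| ≥ 1 before correction is an error,
after correction it is clipped to ±0.99 with a warning; degenerate inputs
(constant samples, empty edge lists, rank-deficient designs, zero-case
cells) raise or yield missing values as documented per function.

## Known limitations

- The FGLS standard errors are conditional on φ̂ and the variance
  components; they do not propagate first-stage uncertainty.
- The spatial model offers no spatial-error variant and no Moran
  diagnostics; the adjacency is binary by design.
- The "overall R²" definition is one conventional choice among several;
  selection results can differ under within/between R² variants.
- Reconstruction transfers a panel coefficient to a national series; this
  is an assumption, flagged in provenance, not a tested property of real
  data.
- Windows may extend past the dependent year when W > G (the window rule
  is symmetric); such cells are legitimate under the formula and are
  limited in practice by covariate availability.
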