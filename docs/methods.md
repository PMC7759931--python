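# Methods

`ctradiomics` implements a pipeline relating CT radiomic heterogeneity of a
tracked lesion to the circulating-tumor-DNA mutant allele fraction
(ctDNA*maf*) measured longitudinally in blood plasma. This note documents the
models, the numerical choices, and what the synthetic data do and do not
emulate.

## The core model

Every inferential stage rests on a Gaussian random-intercept linear mixed
model. For patient *i* at visit *j*,

    y_ij = x_ij' β + b_i + e_ij,   b_i ~ N(0, σ²_patient),  e_ij ~ N(0, σ²_resid)

with `y = log(ctDNAmaf)` as the response. The random intercept absorbs the
within-patient clustering of repeated visits; fixed effects carry the
radiomic feature of interest and, in the volume-controlled analyses, the log
lesion volume.

**Estimation.** The likelihood is profiled analytically: for a fixed variance
ratio λ = σ²_patient/σ²_resid, the GLS coefficients, the residual quadratic
form and both log-determinants have closed per-patient forms (Woodbury
identity on the exchangeable within-patient covariance), leaving a smooth
one-dimensional REML/ML criterion in log λ. That criterion is minimised by a
coarse grid (26 points over log λ ∈ [−30, 20]) followed by bounded Brent
refinement to 1e−8; a boundary check maps the no-clustering case to exactly
σ²_patient = 0. The fitter agrees with `statsmodels.MixedLM` to ~1e−6 on β,
variance components, and both REML and ML log-likelihoods (asserted in the
test suite), while running two orders of magnitude faster — the screening and
Monte-Carlo stages perform ~10⁵ fits.

**Wald inference.** Degrees of freedom for per-coefficient t-tests use a
Satterthwaite approximation: the REML curvature in (σ²_patient, σ²_resid) is
obtained by central finite differences (relative step 1e−4) and
df_k = 2·Var(β̂_k)²/(gᵀ V g). When the between-patient variance sits at its
boundary, or the curvature matrix is not positive definite, df falls back to
n − p.

**Marginal R²** is the fixed-effects share of variance,
Var(Xβ̂)/(Var(Xβ̂)+σ²_patient+σ²_resid), with the 1/(n−1) variance convention
used by the R mixed-model ecosystem. Note that although quadratic fixed
designs nest linear ones, marginal R² re-estimates the variance components
per model, so the quadratic variant's R² can fall ~1e−2 below the linear
variant's on small cohorts; this is a property of the statistic, not a fit
failure, and the tests allow for it.

**Likelihood-ratio tests** compare nested fixed designs under ML only; the
code refuses REML fits there because restricted likelihoods are not
comparable across fixed-effect designs.

**Robust sensitivity fit.** An iteratively reweighted Huber scheme
(c = 1.345, residuals scaled by their MAD, rows reweighted by √w, ≤50
iterations to 1e−6 on β) provides the outlier sensitivity analysis. This is a
deliberate simplification of fully robust mixed-model estimators: it
down-weights gross response outliers (weights < 0.5 at ~3 MAD) while leaving
clean rows at weight 1, and is reported side-by-side with the REML fit, never
merged with it.

## Feature extraction

Extraction follows an absolute-bound, LIFEx-style configuration:

* spatial resampling to 1 mm isotropic voxels (trilinear for intensities,
  nearest-neighbour for the mask; both with cell-edge-aligned grids so the
  physical extent and the mask volume are preserved);
* discretisation of the fixed range [−400, 400] HU into 128 gray levels —
  bin(v) = ⌊(v+400)/6.25⌋+1 clipped to [1,128], so −400 maps to bin 1, 0 to
  bin 65, and +400 clips into bin 128; zone features use 32 levels over the
  same range;
* lesions below 1 cm³ (measured before resampling) are excluded unless
  explicitly overridden, and when several lesions exist the one attaining the
  greatest volume at any visit is tracked (ties: earliest attainment, then
  lowest id).

Texture matrices and their feature sets:

* **GLCM** — distance-1 co-occurrence over the 13 unique 3D directions,
  symmetrised and *pooled* into one normalised matrix before the features
  (Homogeneity, Energy, Contrast, Correlation, Entropy, Dissimilarity) are
  computed. Pooling (rather than per-direction averaging) is a dialect
  choice made for determinism and oracle-checkability.
* **GLRLM** — runs of equal level along the same 13 directions, pooled; every
  in-mask voxel belongs to exactly one run per direction, so Σ length×count
  per direction equals the voxel count (a tested invariant). Run percentage
  is normalised by 13·n so it stays in (0, 1].
* **GLZLM** — zones are 26-connected components of equal level on the 32-bin
  labels; Σ size×count equals the voxel count; ZP = N_zones/N_voxels.
* **NGLDM** — per-voxel absolute difference from the mean of the in-mask
  26-neighbourhood, accumulated per level; Coarseness, Busyness, Contrast
  follow the classical neighbourhood-difference definitions.

Degenerate cases are explicit: GLCM Correlation is NaN when a single gray
level is occupied; NGLDM Coarseness is capped at 1e6 when the neighbourhood
differences vanish (perfectly flat lesion); histogram skewness/kurtosis of a
constant region report 0. Sphericity uses voxel-face surface area (no
meshing) and is documented as approximate. Histogram entropy uses natural
logarithms.

The canonical panel has 39 named features (8 histogram/shape, 6 GLCM, 11
GLRLM, 3 NGLDM, 11 GLZLM); Min and Max are additionally computed and emitted
with an inclusion flag of `False`, since reasonable panels differ on their
membership. Sliding-window feature maps evaluate any non-shape feature on
the (2r+1)³ window around each in-mask voxel (default radius 1), windows with
fewer than two in-mask voxels mapping to NaN.

Every texture feature is verified against independent brute-force oracles
(pair enumeration, run walking, flood-fill zones, neighbourhood scans) to
1e−9 on hundreds of random small volumes, and all features are invariant to
axis permutation and to arbitrary changes outside the mask.

## Cohort assembly

Blood draws rarely coincide with imaging. Per sample, the assay rule prefers
shallow whole-genome sequencing (sWGS) when its tumour fraction is ≥ 3%
(its limit of detection, boundary included) and otherwise TAm-Seq; a
below-limit sWGS value is only used, flagged, when no TAm-Seq value exists.
maf is linearly interpolated *on the maf scale* to each imaging date; exact
dates pass through; outside the sampled range the nearest sample is used and
flagged as extrapolated. Zero maf is floored at 1e−6 (configurable) so the
log response is finite.

Assay agreement uses Lin's concordance correlation coefficient
CCC = 2·s_xy/(s_x²+s_y²+(x̄−ȳ)²) with 1/n moments, and a confidence interval
from the asymptotic variance of the Fisher-z-transformed estimate. Lesion
volume changes are categorised with RECIST-derived thresholds
(1±d)³−1: > +72.8% is a large increase, < −65.7% a large decrease; the exact
formula values are used rather than the rounded percentages they print as.

## Screening with spike-in calibration

Features are first mapped to an analysis scale by a per-feature transform
registry (identity, log, log(a+f), or log(log(f)+a); e.g. the low gray-level
run emphasis uses log(log(LGRE)+9)). Transforms are configuration, not
search; the defaults apply a log to strictly positive, typically
right-skewed texture magnitudes. z-scores store their training constants so
frozen models apply unchanged to new data.

Each feature is screened as the single predictor of log(maf) in the mixed
model (REML, Satterthwaite Wald t). One hundred spiked-in Gaussian
"[random…]" predictors — half with a per-patient shared component at the
configured intraclass correlation, half fully independent — are screened
alongside, and the Benjamini–Hochberg correction is applied to the combined
real+random p-value set at the 5% level, so the spike-ins calibrate the
multiplicity behaviour. In the volume-adjusted screen, log volume is a
second fixed effect and each feature also receives an ML likelihood-ratio
test against the volume-only model. Under a simulated global null the
fraction of screens with any BH discovery calibrates near 5% (tested).

Multivariate outliers are flagged by a deterministic reweighted
minimum-covariance-determinant-style estimate (coordinate-wise median/MAD
start, concentration steps on the half-sample, χ² consistency correction,
flags at the χ²₀.₉₇₅ quantile). This is a documented simplification of the
S-estimator family; when n ≤ 2p the scatter is shrunk halfway toward its
diagonal and the shrinkage is logged.

## Global selection

Two procedures respect the clustering while selecting predictors jointly:

* **LASSO for dependent data** — coordinate descent on the GLS-whitened
  problem with an unpenalised intercept; the variance components are
  re-estimated from the residuals at every λ and the whitening refreshed.
  The grid is 100 log-spaced values from λ_max down to λ_max/1000. The
  penalty is chosen by the *random-entry rule*: with one spiked random
  predictor per real predictor, λ* is the smallest λ whose active set still
  contains no random column; if a random column is active everywhere the
  selection is empty (with a warning).
* **Stepwise marginal-R²** — greedy forward addition (ML fits) halting when
  the best candidate is a random predictor or the gain drops below 1e−4,
  with backward drops of features whose removal costs less than the
  tolerance. Ties break by feature name, making the search deterministic.

Both recover a planted 3-feature signal among 36 correlated noise features
and 39 spike-ins in ≳95% of simulations at the default cohort size, and agree
with each other in the large majority.

## The PCA signature

The five real features with the smallest volume-adjusted LRT p-values are
transformed, z-scored, and summarised by the first principal axis of their
correlation matrix (eigendecomposition; an eigengap below 1e−8 is an error
rather than an arbitrary axis). The loading sign is fixed so the signature
correlates positively with |log(maf)| on the training rows — the axis sign is
otherwise meaningless. The signature S = Σ w_k·z(t_k(f_k)) is an affine
function of the transformed inputs and serialises to JSON (names, transforms,
standardisation constants, loadings) so it can be frozen and applied to new
feature tables. The signature is displayed against |log(maf)| while model
fits use log(maf); both conventions are supported in configuration.

## Correlation-matched Monte-Carlo null

To test whether the selected feature set (or its signature) predicts
log(maf) *beyond* lesion volume while honouring the selection step, the
pipeline simulates many datasets of random features with the same covariance
as the real features — including the feature–volume correlations, via exact
conditional-Gaussian simulation given the *observed* volume column — but
zero population correlation with the response: the generator never receives
the response (a structural guarantee, tested by inspecting its signature).
Optional patient dependence splits the conditional noise into shared
per-patient and visit-level parts at the configured intraclass correlation
without changing the marginal covariance.

Inside **every** null dataset the top-5-by-LRT selection is re-run before the
joint model is fitted, so the null distribution carries the same selection
bias as the real statistic; disabling re-selection is anti-conservative and
is rejected unless explicitly overridden. The empirical exceedance
probability uses the add-one rule (1 + #{null ≥ real})/(n_datasets + 1) and
is therefore never exactly zero. The default is 2500 datasets; desk-scale
runs use 99–500. Calibration (empirical p uniform on no-signal cohorts) and
power (p < 0.01 for a planted 5-feature signal at 500 datasets) are both
asserted in the test suite.

## Association triangle

Three pairwise relationships — log(maf) vs the signature, log(maf) vs
log(LDH), and the signature vs log(LDH) — are each fitted in linear and
quadratic variants (predictor centred before powers are formed). Model form
is chosen by residual diagnostics: the correlation of standardised residuals
with the squared centred fitted values of the linear fit (a curvature trend)
exceeding 0.1 selects the quadratic variant; the choice is logged and
overridable. Pairs whose best marginal R² stays below 0.1 are flagged
near-independent — the configuration in which two markers carry
complementary information. LDH values above the 246 U/L upper limit of
normal are counted in the report; a missing or constant LDH column degrades
to a partial report with a warning.

## Synthetic data: what it emulates, and what it does not

The generator produces cohorts with the statistical structure the analysis
assumes: ~15 patients with 1–12 visits (truncated-geometric counts averaging
~70 visits per cohort), per-patient log-volume random walks
(between-patient s.d. 1.5, step s.d. 0.5 on the log scale, ~60-day visit
intervals), log(maf) = −8.6 + 0.55·log(volume mm³) + patient intercept +
noise with an intraclass correlation of 0.4 among the random components and
residual s.d. 0.6 — which places the volume effect at a Wald t ≈ 7 and
marginal R² ≈ 0.5, the scale such studies report. Features are multivariate
Gaussian conditional on the realised log volume (default: 8 equicorrelated
features at ρ = 0.6 with ρ = 0.8 to volume), LDH is quadratic in log(maf)
(636 + 112·x + 6·x², noise s.d. 70 U/L, floored at 80), blood draws are
offset from imaging dates by a signed, day-rounded log-normal calibrated to
a 10-day median absolute offset with IQR ≈ (4, 34) days, and each sample
carries an sWGS value with a TAm-Seq follow-up when the sWGS value falls
below 3%. maf is clipped to [1e−6, 1] so the log response is defined.

Phantom lesions are ellipsoidal masks over constant, checkerboard, or
correlated-Gaussian-noise HU textures clipped to [−1000, 1000] HU.

What the synthetic data deliberately do **not** contain: CT anatomy or
scanner physics, non-Gaussian feature marginals, feature measurement error
correlated over time, informative visit schedules or dropout, multi-lesion
maf attribution, or assay-specific error structure. Passing tests therefore
demonstrate that the *procedures* are implemented correctly and behave as
designed under their own assumptions — not that those assumptions hold in
any particular clinical dataset.

## Problem sizes used in the tests

Simulation-based tests run at desk scale, chosen to keep the full suite
within a routine CI budget while leaving the statistical claims testable:
200 replicates for interval coverage, 100 for selection recovery, 200
global-null screens for FDR calibration, 30 cohorts × 99 null datasets for
Monte-Carlo calibration, 500 null datasets for the power check, and 500
random volumes ≤ 6×6×6 for texture-oracle equivalence. All stochastic tests
are seeded and reproduce bit-identically.

## Known limitations

* The run/zone/co-occurrence dialect (13-direction pooling, absolute-bound
  binning) is one of several in circulation; no bit-exact replication of any
  specific tool is claimed.
* The Huber reweighting and the deterministic MCD-style outlier step are
  simplifications of the fully robust estimators used in the literature.
* Satterthwaite df are approximate near the variance boundary (the code
  falls back to n − p there).
* The LASSO path re-estimates variance components between λ steps rather
  than jointly optimising the penalised likelihood; active sets can in
  principle reorder slightly along the path.
* maf interpolation happens on the maf scale; interpolating log(maf) would
  be equally defensible and is not currently offered.
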