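# Methods

`gdmnir` implements a chemometric screening pipeline for predicting a
binary clinical outcome — gestational diabetes mellitus (GDM) versus normal
glucose tolerance (NGT) — from near-infrared (NIR) transflectance spectra
of serum, together with a synthetic cohort generator that reproduces the
statistical structure such studies rely on. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic experiments do and do not demonstrate.

## Data model

Spectra live on a strictly descending wavenumber axis covering
10,500–4000 cm⁻¹. The instrument-style export is reflectance-like
transflectance intensity R; absorbance is A = log₁₀(1/R). Five instrumental
replicates per sample are averaged (on the reflectance scale, before
conversion) to one spectrum per subject. The axis is split into three
sub-ranges with distinct noise character — R1 (10,500–7600, high noise),
R2 (7600–5100, varying), R3 (5100–4000, low noise) — with closed bounds, so
the touching boundary points (7600, 5100) belong to both neighbours. The
default grid spacing is 2 cm⁻¹ (3251 points full-range); the spacing is
configurable because instrument exports at 4 cm⁻¹ resolution may be
re-sampled at either interval, and all interval reports are in cm⁻¹
regardless of spacing.

## Pretreatment

Row-wise operators are stateless (each spectrum transformed independently):
Savitzky–Golay smoothing or first/second derivative (polynomial order 2,
odd window width, derivatives in per-point units — the Δν factor cancels
after centering in every downstream model, and edges are handled by
polynomial extrapolation within the first/last window), standard normal
variate (SNV), iterative weighted-least-squares (WLS) baseline removal, and
2-norm normalization. Because they are stateless they may be applied before
cross-validation splitting without information leakage. The WLS baseline
uses a polynomial of order 2, asymmetric weights (1 on/below the current
baseline, 0.01 above), at most 100 iterations and a 10⁻⁶ max-norm tolerance
on the weight-vector change; these are conventional values — the method
itself fixes none.

Column scalers (mean centering for spectra, autoscaling for clinical
covariates) learn statistics and are always fitted inside the current
training partition. Constant columns under autoscaling receive scale 1 with
a warning rather than an error, because binary covariates are frequently
constant inside small folds.

The screening grid enumerates
{none | SM(W) | 1D(W) | 2D(W); W ∈ {3, 7, 15, 23}} × {none | SNV | WLS} ×
{none | 2-norm}, each terminated by mean centering: 78 unique combinations.
The canonical operator order (filter → scatter/baseline → normalization →
centering) is the conventional one in spectral preprocessing and is
configurable. A reduced 12-spec grid (width 15 only, no 2-norm stage) is
provided for fast screening. Specs serialize to a compact string form
("1D(W=15)+MC", "WLS+N+MC") that parses back bit-exactly.

## PLS-LDA

Classification is formulated as regression of a binary-coded response
(1 = GDM, 0 = NGT) on the predictor matrix. PLS1 compresses X into scores
T = XR of maximal covariance with y; regressing y on the scores gives
ŷ = Tq = XRq = Xb. Components are extracted by NIPALS with X-deflation
(for a single response each component is a closed-form step, no inner
iteration). The transformed weights satisfy R = W(PᵀW)⁻¹ with PᵀW unit
upper triangular. One fit with A components exposes the whole nested
coefficient path b₁…b_A, so the predictions of every smaller model come
from a single decomposition — the inner cross-validation loop depends on
this for speed. Degenerate cases: a constant response yields the all-zero
coefficient model; requesting more components than the effective rank
truncates with a warning.

The real-valued ŷ is thresholded by one-dimensional two-class LDA with
pooled within-class variance: y_thres = (m₀+m₁)/2 + σ²·ln(π₀/π₁)/(m₁−m₀).
Priors default to equal — model selection optimizes the non-error rate,
which weights the classes equally, and both cohorts are strongly imbalanced
— with proportional priors available. Orientation follows the sign of
m₁−m₀; exact ties at the threshold go to NGT, deterministically.

## SO-PLS-LDA (two blocks)

Sequential and orthogonalized PLS: (1) PLS of y on block 1 (A₁ components);
(2) orthogonalization of block 2 against the block-1 scores,
X₂,orth = X₂ − T₁(T₁ᵀT₁)⁻¹T₁ᵀX₂ (pseudo-inverse if T₁ is rank-deficient);
(3) PLS of the first-stage residuals e₁ = y − ŷ on X₂,orth (A₂ components).
Predictions sum both contributions, ŷ_SO = X₁b₁ + X₂,orth b₂,orth, and LDA
thresholds ŷ_SO. New samples are orthogonalized with the training
projection, using block-1 scores predicted from X₁ — the standard SO-PLS
prediction convention. A₂ = 0 reduces exactly to single-block PLS-LDA;
block order matters, and both orders are runnable. The (A₁, A₂) pair is
chosen by an exhaustive grid inside the inner loop, maximizing inner NER,
with ties broken to the smallest A₁+A₂ and then smallest A₁ — a global
grid rather than sequential per-block selection, for determinism.

## Repeated double cross-validation

The outer loop (20 random segments) estimates performance on samples never
used for fitting or selection; the inner loop (10 segments inside each
outer-training set) picks the component count by pooled inner NER (ties to
the simplest model). The whole procedure is repeated 50 times with
re-randomized splits; everything learned — centering means, autoscaling
SDs, LDA thresholds, component counts — is computed strictly inside the
current training partition. Partitions are plain random with near-equal
sizes, re-drawn (bounded retries) until every training complement contains
both classes; per-segment stratification is impossible with 8 cases and 20
segments, so none is attempted. The master seed spawns one child stream
per repetition, so individual repetitions are reproducible in isolation,
and identical seed + config gives byte-identical outputs.

Figures of merit: specificity, sensitivity, NER = (Sp+Se)/2 per repetition
from the pooled outer predictions; AUROC per repetition by the rank/pair
(Mann–Whitney) formulation on the pooled predicted responses (ties count
one half), then mean ± sample SD over repetitions. ROC curves are averaged
vertically on a fixed 101-point false-positive-rate grid with endpoints
pinned at (0,0) and (1,1).

### Row-space compression

Inside grid screening, each (range × pretreatment) cell's matrix is rotated
onto its row-space basis (thin SVD of the centered matrix) before the DCV
engine runs. PLS-LDA depends on the variables only through inner products
of row differences, so this fixed orthogonal rotation changes no score,
threshold or prediction (verified to machine precision in the tests); it
reduces every fit from O(n·p) to O(n²) and makes the full screening
practical on one CPU. Reports that need variable-space quantities (VIP)
run uncompressed.

## VIP

Variable importance in projection for single-response PLS:
VIPⱼ = √(p·Σₐ SSₐ(wⱼₐ/‖wₐ‖)² / Σₐ SSₐ) with SSₐ = qₐ²·tₐᵀtₐ, so the mean
squared VIP is exactly 1 and scores above 1 flag relevant variables
(strict inequality). VIPs are averaged over all outer-fold models of all
repetitions, weighting each model equally. Selected variables are reported
as contiguous wavenumber intervals; runs separated by at most 3 unselected
points (configurable) are merged, so an interval is "mainly" composed of
relevant variables. For SO-PLS models, VIP is computed per block from that
block's sub-model.

## Synthetic cohorts

No public dataset exists for this problem, so the generator is a stand-in
that emulates the statistical features the pipeline exercises — it makes
no claims about the chemistry of real serum.

Each subject's absorbance spectrum is a smooth polynomial baseline plus
Gaussian bands: broad water bands near 6900 and 5150 cm⁻¹, carbohydrate
and protein/CH combination bands at 4700, 4600, 4350, 4260 cm⁻¹, a
5600 cm⁻¹ shoulder and weak high-wavenumber overtones. Band amplitudes
vary between subjects with coefficient of variation 0.12 (serum-constituent
scale biological variability); case subjects' bands inside the configured
effect interval — by default 4762–4348 cm⁻¹, a carbohydrate-associated
region — are scaled by 1+δ with δ = 0.20, a multiplicative
(concentration-like) effect spread over the three bands in that interval
so the realized effect is stable even with only 8 cases. The dominant
6900 cm⁻¹ water band additionally jitters in position between subjects
(SD 6 cm⁻¹), emulating thermally/solute-driven shifts of the water
overtone — the main nuisance variance outside R3. A per-sample
multiplicative scatter factor (SD 0.02) models transflectance path-length
variation. Replicate-level additive noise has piecewise-constant SD per
region (10×, 3×, 1× a base SD of 0.01 AU for R1/R2/R3 — i.e. 0.1 AU
replicate noise in the high-wavenumber region, large relative to its weak
overtone features, as in real serum transflectance data) and, crucially,
per-region correlation lengths (30, 10, 0 grid points): the high-noise
region's noise is slow and wavy ("sequential"), not white. Correlated
noise concentrates its power in few directions and genuinely degrades
full-range PLS models, which is the mechanism that makes range selection
matter — with white noise alone, full-range models are merely diluted and
tie with R3.

The covariate generator draws the 28 clinical variables (age, BMI and
menarche age Gaussian per class; 24 binary covariates Bernoulli per class;
month of last period categorical) with per-class parameters defaulting to
the published cohort tables for the two scenarios (67/15 and 39/8
subjects). Spectra and covariates come from independent child streams of
the config seed, so either table regenerates alone, byte-identically.

What the synthetic experiments show: that the full pipeline — replicate
averaging, absorbance conversion, range extraction, the pretreatment grid,
leakage-free double cross-validation, and NER-based ranking — recovers a
class effect confined to R3 and ranks ranges correctly under realistic
noise, and that a null cohort scores at chance. What they do not show:
anything about real serum spectra; the generator's band library and noise
model are parameters, not measurements, and single-cohort flukes (a
spurious full-range win, a weak realized effect) still occur at these
small cohort sizes, exactly as they would in practice.

## Problem sizes in the shipped experiments

The recovery experiment uses the second-trimester scenario (39 controls,
8 cases, 5 replicates), the reduced 12-spec grid over all four ranges, 10
DCV repetitions and 10 cohort seeds; the deterministic-rule baselines run
the full 50 repetitions. These sizes were chosen so the complete
experiment battery runs comfortably on a single CPU while keeping every
qualitative conclusion stable under the fixed seeds.

## Known limitations

- The published pretreatment count (80 combinations) cannot be
  reconstructed exactly; the default grid enumerates 78 and the builder is
  config-driven, so any enumeration can be reproduced.
- PLS variant (NIPALS), LDA priors (equal), AUROC pooling (per repetition,
  pooled outer predictions) and the VIP averaging population (all
  outer-fold models) are documented defaults where the methodology leaves
  choices open; an independent SIMPLS implementation cross-checks NIPALS
  in the tests.
- Only two-block SO-PLS is implemented; longer block chains are out of
  scope.
- With 8 cases, count-based metrics are coarse (sensitivity moves in
  steps of 1/8) and cohort-level sampling flukes are an irreducible source
  of run-to-run variability across generator seeds.
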