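# Methods

This note documents the models, conventions and numerical choices behind
`ftirsurv`, and what the synthetic cohorts do and do not establish about
real data.

## Spectral model and preprocessing

A spectrum is absorbance sampled on a strictly increasing wavenumber grid
(canonical acquisition: 800–3500 cm⁻¹ at 2 cm⁻¹, 1351 points).  Files may
store wavenumbers descending; they are canonicalised to ascending on read,
and duplicate wavenumbers are an error rather than being averaged — a
duplicate almost always indicates an acquisition or export mistake and
averaging would hide it.  The JCAMP-DX reader supports the common AFFN
export dialect (`XYDATA=(X++(Y..Y))` and `XYPOINTS`); compressed
SQZ/DIF/DUP encodings are rejected with an explicit message rather than
half-supported.

Preprocessing order is fixed: **baseline → normalisation → (optional)
smoothing → band windowing.**

* *Baseline*: default is the rubberband — subtract the lower convex hull of
  the (ν, A) point set, computed over the full recorded range.  It is
  parameter-free, exact on linear backgrounds, and the standard scheme
  family in FTIR vendor software.  An iteratively refit polynomial baseline
  (points above the fit excluded each round until the support set is
  stable) is available for curved backgrounds.
* *Normalisation*: default is vector (unit Euclidean norm) over the full
  recorded range, not the analysis band.  Peak *position* inside a band is
  invariant to any global positive scaling, so the feature is unaffected by
  this choice; normalising over the full range keeps group mean and
  difference spectra comparable across the whole spectrum.  Min–max
  normalisation is available.  Windowing deliberately does not commute with
  normalisation; the pipeline always normalises first (regression-tested).
* *Smoothing*: off by default — at the synthetic noise levels the apex
  estimate does not need it.  When enabled, Savitzky–Golay (default window
  7, order 2) requires a uniform grid and reproduces polynomials up to its
  order exactly.

The analysis band defaults to the **closed** interval [950, 1100] cm⁻¹
(76 points on the 2 cm⁻¹ grid).  The band is configurable, e.g. to
[900, 1100], and the configured value is echoed into every report.

## Peak feature

Per replicate, the feature is the wavenumber of the absorbance maximum in
the band.  Two apex modes:

* `grid` (default): the maximal sample, ties broken deterministically
  toward the lowest wavenumber.  This matches the acquisition resolution
  and keeps per-patient values integer-valued on a 2 cm⁻¹ grid.
* `quadratic`: vertex of the parabola through the discrete maximum and its
  two neighbours, clamped to the band, reported at 0.1 cm⁻¹; a maximum at a
  band edge falls back to the grid value with a warning.  Used where
  sub-grid resolution matters (e.g. the parameter-recovery checks).

Replicate peak positions are aggregated by arithmetic mean (median
configurable) and rounded half-up to 1 cm⁻¹.  Aggregating the *positions*
of replicate peaks is the default; averaging the replicate *spectra* first
and picking a single peak is available via `aggregate="spectra"` — the two
differ only under asymmetric noise.  A patient without t_b spectra is
excluded (t_b anchors every analysis); a missing t_n only blanks the
t_b − t_n shift, and all drops are counted in the report.

## Cutoff selection

For each feature against the unfavourable-outcome label (progression,
relapse or death during follow-up), the ROC curve is built over all
distinct observed scores plus ±∞ sentinels, with exact-fraction Se/Sp.  The
selected threshold minimises

    cost(t) = c · w₊ · (1 − Se(t)) + w₋ · (1 − Sp(t)),

with cost ratio c = C_FN/C_FP = 2 by default (a missed poor-prognosis
patient is twice as costly as an over-called one).  With prevalence
weighting on (default) the class weights w are the observed class counts —
expected cost on the observed cohort; with it off, equal weights reduce
the criterion to the cost-tilted Youden index Se + Sp/c, and at c = 1 to
the classic Youden J.  The exact weighted-Youden variant used by legacy
statistics packages differs between implementations, so both variants are
exposed and the active one is recorded in the report rather than silently
assumed.  Ties among cost-minimising thresholds go to higher sensitivity,
then to the lower threshold.  The reported threshold is an attainable
boundary value so the printed rule (`x ≥ t` including the boundary,
`x < t` excluding it) reproduces the classification exactly.

Orientation is fixed per feature by the direction that is adverse on
domain grounds: high t_b (`≥`), small or negative chemotherapy shift
t_t − t_b (`<`), and t_b − t_n near or above zero (`≥`) mark the high-risk
arm.  Auto-orientation (choose the direction with AUC ≥ 0.5) is available
behind a flag.  No multiple-testing correction is applied anywhere; all
p-values are reported raw and a two-sided 0.05 threshold is used only for
flagging, never for filtering.

## Rank tests

Mann–Whitney U is computed from midranks; the two-sided p-value is exact by
enumeration when there are no ties and C(n₁+n₂, n₁) ≤ 10⁵, otherwise the
normal approximation with tie and continuity corrections is used (both via
scipy behind this module's switching rule).  Correlations with percent
necrosis use Spearman's rank correlation — at cohort sizes near n = 27 with
non-normal, range-bounded features a rank correlation is the defensible
default — with the t-approximation on n − 2 degrees of freedom.

## Survival analysis

Times are months throughout; the reporting horizon is 36 months
("3-year" rates), evaluated right-continuously on the Kaplan–Meier step
function.  KM estimation and the log-rank test delegate to lifelines; the
usual tie convention holds (events precede censorings at equal times).

The Cox proportional-hazards fitter is implemented in this package:
Newton–Raphson on the partial likelihood with analytic gradient and
Hessian, step-halving to keep the likelihood ascending, convergence when
the score max-norm < 1e-8 or the log-likelihood change < 1e-10 (max 100
iterations).  Both Efron and Breslow tie corrections are provided; Efron is
the default for its better behaviour with many ties at small n, and the
two agree to 1e-8 on tie-free data (tested, with lifelines' Efron fit as
an independent cross-check).  Monotone likelihood (perfect separation) is
flagged when |β| exceeds 15 — on small dichotomised cohorts an arm with no
events is common, and the fit is returned with the flag rather than
failing, leaving the huge HR visibly accompanied by an unbounded CI.
Confidence intervals use the fixed normal multiplier 1.96; the overall
model p is a likelihood-ratio test against the null.

Backward-Wald elimination refits after removing the covariate with the
largest Wald p while that p exceeds `alpha_remove` (default 0.10), never
removing the last covariate.  Because elimination on small cohorts is
unstable, the report always carries the full (no-elimination) model
alongside the eliminated one, plus the elimination trace.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: 27
patients, triplicate spectra per tissue, 7 of 27 without normal bone, and
outcomes over a 14–74-month follow-up.  Spectra are sums of Gaussian bands
(centres near 1080, 1240, 1400, 1545, 1655, 2852, 2925, 3290 cm⁻¹) plus
the signal band near 1030 cm⁻¹, a random linear baseline a + b·ν
(a ∈ [0, 0.05], b ∈ [0, 2·10⁻⁴]) and white absorbance noise
(σ = 0.01 of the main-band amplitude, consistent with 32-scan-averaged
ATR-FTIR acquisition).  The signal band uses σ = 5 cm⁻¹ (FWHM ≈ 12 cm⁻¹),
at the narrow end of realistic tissue bands so the apex is well defined
against noise; both width and noise are configurable.

The tumour-at-biopsy centre is c_b = 1024 + 7.5·r + ε with latent risk
r ~ Bernoulli(14/27) and ε ~ N(0, 4.5²) cm⁻¹ — these levels put the
low/high-risk medians near 1024 / 1031.5 cm⁻¹ and the t_b feature's
discriminative AUC near 0.87 (binormal Φ(Δ/(σ√2))).  Post-chemotherapy
centres shift +7 cm⁻¹ for low-risk (responder) and −0.5 cm⁻¹ for
high-risk patients; normal bone sits +16 / +1 cm⁻¹ right of the tumour
respectively (extra tissue noise σ = 4 cm⁻¹); replicates jitter the centre
by N(0, 1.5²).  Progression is exponential with hazard
0.0055 · exp(β·r) per month (low-risk 36-month PFS ≈ 0.82) and β = log 10
by default; death follows progression after an Exp(1/12-per-month) delay;
censoring is administrative at 74 months with a 70% fraction censored
uniformly on [12, 74] (median follow-up ≈ 29 months).  Clinical covariates
(gender, age, extent, site, necrosis, treatment flags) are drawn with
realistic marginals but **independently of the risk class**: the planted
prognostic signal is purely spectral.

Planted truth (risk classes, true centres, true event times) is returned
alongside the observed data and is never read by the analysis pipeline.
Identical config + seed reproduces a cohort bit for bit.

What passing tests on these cohorts show: the pipeline recovers planted
band positions through baseline/normalisation, selects cost-optimal
thresholds, estimates hazard ratios with nominal CI coverage, and is
calibrated under the null.  What they do not show: robustness to
Mie/resonant scattering, water-vapour lines, ATR penetration-depth effects,
Lorentzian/Voigt line shapes, overlapping-band interference, or clinical
covariates correlated with the spectral signal — none of which the
generator models.

## Problem sizes in the test suite

Calibration checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerance while keeping the suite quick: 1,000 score sets
for the AUC identity, 500 spectra for peak recovery (≥ 95% within
1 cm⁻¹), n = 2,000 patients for the binormal AUC comparison (±0.03),
100 replicates of n = 500 for Cox CI coverage (≥ 90%), and 1,000
27-patient replicates for log-rank type-I error (±3 binomial SEs around
5%).

## Known limitations

* The rubberband baseline assumes broad, convex background drift; sharp
  negative artefacts would distort the hull.
* Grid-mode peak positions inherit the 2 cm⁻¹ acquisition quantisation;
  sub-grid claims need `apex_mode="quadratic"`.
* The Cox fitter targets small covariate counts (the intended use is ≤ ~6
  covariates); it makes no attempt at penalised or high-dimensional fits.
* Backward Wald selection p-values are not corrected for the selection
  itself; they are descriptive, as in the study designs this mirrors.
* With separation (common when a dichotomy perfectly predicts events on a
  27-patient cohort) the flagged coefficient is reported as-is; Firth-type
  penalisation is out of scope.
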