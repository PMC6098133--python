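# ftirsurv

Prognostic analysis of ATR-FTIR tissue spectra for bone-tumour cohorts:
from raw absorbance spectra to band-peak biomarkers, cost-weighted ROC
cutoffs and survival stratification.

## The problem

In paediatric bone sarcoma, treatment outcome varies widely and the
routinely used clinical risk factors (metastases, tumour site, histological
response to neoadjuvant chemotherapy) leave an unmet need for better
prognostic markers.  Attenuated-total-reflection Fourier-transform infrared
(ATR-FTIR) spectroscopy measures the bulk biochemical composition of a
tissue section; in the 950–1100 cm⁻¹ region (phosphates, carbohydrates,
nucleic-acid backbone) the *position* of the absorbance maximum shifts with
tissue state and is a candidate spectral biomarker.

This package implements that analysis as a tested pipeline.  For each
patient it extracts the peak wavenumber of the analysis band from
triplicate spectra of three tissue types —

* **t_b** — tumour at diagnostic biopsy (pre-treatment),
* **t_t** — tumour resected after neoadjuvant chemotherapy,
* **t_n** — normal bone outside the tumour (unavailable for some patients),

forms the paired shifts **t_t − t_b** (treatment response) and
**t_b − t_n** (tumour-vs-normal displacement), dichotomises each feature at
a cost-weighted ROC cutoff, and quantifies the prognostic value with
Kaplan–Meier curves, log-rank tests and Cox proportional-hazards models
(full and backward-Wald-eliminated).

Because per-patient spectra of such cohorts are rarely public, the package
ships a synthetic cohort generator that plants the band-position and
survival structure, so every stage is testable end to end against known
ground truth.

## The statistics at the core

**Peak feature.** After rubberband (lower convex hull) baseline correction
and vector normalisation, the biomarker is
`argmax_{ν ∈ [950, 1100]} A(ν)`, per replicate, aggregated by mean and
rounded to 1 cm⁻¹ (grid apex by default; quadratic sub-grid apex available).

**Cutoff selection.** For feature X with binary outcome (progression,
relapse or death), the threshold *t* minimises the expected
misclassification cost

```
cost(t) = c · n₊ · (1 − Se(t)) + n₋ · (1 − Sp(t)),        c = C_FN / C_FP = 2
```

over all attainable thresholds — a prevalence-weighted, cost-tilted Youden
criterion: with c = 1 and prevalence weighting off it reduces to the classic
Youden index J = Se + Sp − 1.  The AUC is computed by trapezoid and proved
against the tie-adjusted rank (Mann–Whitney) formulation.

**Survival.** Kaplan–Meier product-limit curves with log-rank comparisons,
and a Cox partial-likelihood fitter (Newton–Raphson; Efron or Breslow tie
correction) with Wald statistics, 95% CIs `exp(β ± 1.96·SE)`, monotone-
likelihood (separation) flagging, and backward elimination of the largest
Wald p while p > 0.10.

## Worked example

```sh
python examples/full_pipeline.py
```

```
cohort: 27 patients, 222 spectra, 7 without normal bone

cost-weighted cutoffs (FN twice as costly as FP):
  t_b >= 1027 cm^-1            AUC = 0.914  Se = 0.93  Sp = 0.67
  shift_tt_tb < 6 cm^-1        AUC = 0.931  Se = 1.00  Sp = 0.83
  shift_tb_tn >= -7 cm^-1      AUC = 1.000  Se = 1.00  Sp = 1.00

t_b dichotomy log-rank: PFS p = 0.00091072, OS p = 0.00032367
report files written to scratch/example_report/
```

Reading this: a biopsy peak at or above 1027 cm⁻¹, a post-chemotherapy
peak that fails to shift right, or a tumour peak sitting close to the
patient's normal-bone peak each mark the high-risk arm; the AUC is the
probability that a random poor-outcome patient shows the pattern more
strongly than a random good-outcome one, and the log-rank p-values test
whether the two arms' survival curves separate.  Other examples cover
simulation (`simulate_cohort.py`), feature extraction
(`extract_features.py`), cutoff selection (`select_cutoffs.py`) and
survival modelling (`survival_stratification.py`).  A thin CLI wraps the
same library:

```sh
ftirsurv simulate --seed 1 --out cohort/
ftirsurv run --manifest cohort/manifest.csv --clinical cohort/clinical.csv --out report/
```

## Layout

```
src/ftirsurv/
  io.py          spectra (two-column CSV, JCAMP-DX subset), manifests, clinical tables
  preprocess.py  rubberband/polynomial baseline, vector/minmax normalisation,
                 Savitzky–Golay smoothing, band windowing
  features.py    band peak positions, replicate aggregation, shifts,
                 group mean/difference spectra
  stats.py       ROC, AUC, cost-weighted cutoffs, Mann–Whitney, Spearman
  survival.py    Kaplan–Meier, log-rank, Cox (Efron/Breslow), backward Wald
  synthetic.py   cohort generator with planted truth
  pipeline.py    orchestration and report writing
  cli.py         thin command-line interface
```

See `docs/methods.md` for the model, parameter choices and limitations.
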