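# pvcsurv

Premature ventricular contractions (PVCs) seen during a submaximal exercise
test carry prognostic information in asymptomatic adults: the risk of major
adverse cardiovascular events (a composite of myocardial infarction, heart
failure and life-threatening ventricular arrhythmia, "MI/HF/LTVA") and of
all-cause mortality rises with the PVC count during both the exercise and
the recovery phase. Quantifying that association end to end requires an
unusual chain of machinery: beat-level PVC detection from a single-lead ECG,
a rhythm grammar (couplets, triplets, runs, bigeminy, R-on-T candidates,
multifocality), burden categorisation, and category-wise survival modelling
with floated confidence intervals and multiple imputation.

`pvcsurv` implements that whole chain as a tested Python package, paired
with synthetic-data generators so every stage is verifiable without access
to restricted individual-level data:

1. **Synthetic data** (`pvcsurv.synthetic`) — single-lead exercise ECGs
   (15 s rest, 6 min graded exercise, 1 min recovery, 500 Hz) with exact
   ground-truth beat annotations and injectable PVC counts/patterns, and
   cohort tables with a zero-inflated burden distribution (~79.7% / ~90.1%
   zero PVCs in exercise / recovery), planted hazard ratios, and
   administrative censoring.
2. **Preprocessing** (`pvcsurv.preprocess`) — 0.5–45 Hz zero-phase
   bandpass, decimation to 250 Hz, non-overlapping 2048-sample segments
   with exact round-trip reconstruction.
3. **Detector** (`pvcsurv.detector`) — a per-sample three-class 1D CNN
   (normal QRS / PVC QRS / neither) written in numpy, with probability
   smoothing, refractory beat calling and burden-category scoring.
4. **Rhythm** (`pvcsurv.rhythm`) — per-phase counts, burden categories
   (exercise: 0 / 1–5 / 6–10 / 11–20 / >20; recovery: 0 / 1–5 / >5),
   frequent (>10/min), run >2, short-coupling (<400 ms) and multifocality
   (pairwise correlation <0.75) flags, and the composite high-grade flag.
5. **Survival** (`pvcsurv.survival`) — sex-stratified cause-specific Cox
   models (Efron ties) for a categorical exposure against the hazard
   h_s(t | x) = h_{0s}(t) · exp(β_cat + γᵀz); floated absolute-risk 95% CIs
   that give every burden group, including the 0-PVC reference, its own
   interval; MICE with predictive mean matching (m = 5, 10 iterations);
   Rubin pooling with Barnard–Rubin degrees of freedom; Kaplan–Meier
   cumulative incidence and log-rank tests; COPD/CKD-exclusion and
   resting-PVC sensitivity variants.

## Worked example

```python
from pvcsurv.pipeline import train_detector, evaluate_chain
from pvcsurv.synthetic import CohortSpec, generate_cohort
from pvcsurv.survival import AnalysisConfig, run_analysis

net = train_detector(n_recordings=60, seed=11)       # ~1.5 min on one CPU
print(evaluate_chain(net, 30, seed=123_000))          # held-out recordings

cohort = generate_cohort(CohortSpec(n=20_000), seed=202)
out = run_analysis(cohort, AnalysisConfig(exposure="exercise_category",
                                          covariate_set="full", seed=7))
print(out["table"].round(3))
```

prints detection metrics of

```
PVC sensitivity 1.000, PPV 0.989, category accuracy 1.000
```

and the fully adjusted exercise-burden hazard-ratio table

```
category     n    hr  ci_lo  ci_hi  floated_lo  floated_hi     p
       0 15913 1.000    NaN    NaN       0.930       1.075   NaN
     1-5  2964 1.240  1.079  1.425       1.101       1.396 0.002
    6-10   571 1.419  1.094  1.839       1.105       1.821 0.008
   11-20   277 1.810  1.327  2.468       1.340       2.445 0.000
     >20   275 2.221  1.658  2.975       1.675       2.945 0.000
```

i.e. monotonically increasing risk with exercise PVC burden, a proper
floated interval for the reference group, and conventional CIs for the
contrasts. (The point estimates exceed the planted exercise-only hazard
ratios because the generator also plants a correlated recovery-burden
effect, as in real cohorts where burden in the two phases co-occurs.)

The numbered drivers under `analysis/` run the same steps as a narrative:
`01_simulate_data.py`, `02_train_detector.py`, `03_detect_and_summarize.py`,
`04_survival_analysis.py`, `05_sensitivity_analyses.py`. Small output
tables land in `results/`; bulky raw signals land in `scratch/`.

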