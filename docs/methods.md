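# Methods

This note documents the models and procedures implemented in `pvcsurv`,
the defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical conventions a maintainer needs.

## Synthetic exercise ECG

**Protocol.** A recording is 15 s rest + 360 s graded exercise + 60 s
recovery at 500 Hz (217,500 samples). Heart rate follows a deterministic
profile: constant `hr_rest` (default 65 bpm) at rest, a linear ramp to
`hr_peak` (default 110 bpm) completed at 90% of the exercise phase, and a
linear decay by `hr_recovery_drop` (default 25 bpm) over the first half of
recovery. RR intervals get 1.5% multiplicative Gaussian jitter. The
workload tier (35% or 50% of predicted maximum) is carried as metadata
only: the predicted-workload equation is not modelled, and the heart-rate
end points are specified directly.

**Beats.** Normal beats are sums of Gaussians (P, Q, R, S, T; QRS ≈ 92 ms).
Each PVC morphology is a distinct wide biphasic QRS (annotated duration
130–180 ms, ≥120 ms by definition) with no P wave and a discordant T wave;
polarity, widths and lobe spacing are drawn per morphology, so snippets of
the same morphology correlate >0.9 while different morphologies correlate
<0.75 — which is exactly the multifocality trigger downstream.

**Injection.** Requested per-phase PVC counts are decomposed into whole
pattern groups — isolated, couplet (2), triplet (3), run (4), bigeminy
(N V N V N V, i.e. 3 alternating pairs, the minimum we count as bigeminy) —
and placed on non-adjacent slots of the sinus beat grid, at least two
slots from any phase boundary. The first PVC of a group sits one coupling
interval (default 440 ms; 320 ms for the configured R-on-T-candidate
fraction, clamped premature) after the preceding beat; intra-run intervals
are short but above the 200 ms refractory floor; the beat after a group
resumes after a full compensatory pause (RR_pre + RR_post = 2 × local RR).
Sinus beats re-anchor to the original grid so local retiming never
accumulates across phases, which is what makes per-phase counts exact by
construction (and verified at generation time). Infeasible requests fail
with an error naming the phase.

**Noise.** Baseline wander (three sinusoids <0.45 Hz, 0.08 mV total) plus
band-limited Gaussian noise at a configurable SNR (default 20 dB).

**What this does not emulate:** respiration coupling, electrode motion
artefacts, atrial arrhythmia, QT adaptation, or 12-lead geometry. Passing
the detector benchmark therefore shows the pipeline machinery is correct
and trainable, not that the trained weights transfer to clinical ECG.

## Synthetic cohort

One row per participant: age, sex, BMI, lipids, triglycerides, smoking,
diabetes, hypertension (SBP ≥140 or DBP ≥90 or prior diagnosis),
beta-blocker use, QTc, QRS duration, ST-depression flag, per-phase heart
beat counts, heart-rate changes, COPD/CKD/resting-PVC flags. Exercise
burden categories get marginal mass (0.797, 0.147, 0.028, 0.014, 0.014)
and recovery (0.901, 0.084, 0.015) via thresholds on a latent normal; the
two latents are correlated (ρ = 0.7) so high burden co-occurs across
phases, and the latent is mildly loaded on age and male sex
(`confounding`, default 0.25) so unadjusted fits are visibly confounded.

Event times are exponential per sex stratum (female 0.0045, male
0.0065 events/person-year at the covariate reference) scaled by
exp(linear predictor) with planted log hazard ratios — exercise categories
ln(1.2), ln(1.3), ln(1.5), ln(1.8); recovery ln(1.3), ln(1.6); plus modest
clinical-covariate effects. Events draw a type (MI / HF / LTVA / CV death /
non-CV death) from a multinomial; censoring is administrative at 13 years.
Because the baseline is exponential, the proportional-hazards structure is
exact; the Cox fit does not depend on the baseline shape. Missingness is
MCAR at the rates typical for such cohorts (smoking 0.4%, LDL 8.2%,
HDL 13.2%, triglycerides 8.2%, BMI ≈0.01%, QRS 0.9%, QTc 4.6%,
ST-depression ≈0.02%).

Note one deliberate property: with both exposure effects planted and
correlated, a single-exposure fit absorbs part of the partner phase's
effect. Parameter-recovery simulations therefore zero the recovery effects
when checking recovery of the planted exercise coefficients.

## Preprocessing

4th-order Butterworth 0.5–45 Hz applied forward–backward (zero phase, so
R-peak annotations stay aligned); FIR anti-aliased decimation 500→250 Hz;
segmentation into non-overlapping 2048-sample windows with the final
window zero-padded and its `valid_length` carried, so desegmentation is
bit-exact and no tail signal (possibly containing PVCs) is dropped. All
downstream beat coordinates are 0-based indices at 250 Hz.

## Detector

A fully convolutional per-sample classifier over {none, normal QRS, PVC
QRS}: conv(15, 16) → ReLU → conv(15, 16) → ReLU → dropout 0.3 → 1×1
dense(32) → ReLU → linear(3) → softmax, trained with Adam (lr 2e-3) on a
class-weighted cross-entropy (inverse class frequency, since background
dominates). Targets label ±60 ms around normal R peaks and the full
annotated QRS duration for PVCs. The implementation is plain numpy
(im2col convolutions with explicit backprop); everything is seeded, the
output layer is zero-initialised (an untrained net is exactly uniform),
and training is reproducible on a single thread.

Training uses random 512-sample crops of short-protocol recordings
(15/60/30 s phases, burden capped at 25): the network is translation
invariant, crops give many more optimizer steps per CPU-second, and the
benchmark uses longer recordings (15/120/60 s) the network never saw.
Defaults — 60 training recordings, 40 crops each, 10 epochs — train in
about 90 s and were chosen to keep the full benchmark minutes-scale on one
CPU.

Inference rejoins segment outputs into a full-length probability track
(padding stripped), smooths each class channel with a 40 ms moving average
(renormalised), and calls beats as maximal runs where the non-background
probability exceeds 0.5: location is the probability-weighted run centre,
label the class with the larger integrated probability, and calls closer
than 200 ms are merged keeping the higher-confidence one. Beat matching
for evaluation uses greedy one-to-one pairing within ±75 ms.

## Rhythm grammar

Phase assignment uses half-open sample intervals. Burden categories are
boundary-inclusive (exercise 20 → "11–20", 21 → ">20"; recovery 6 → ">5").
Couplet/triplet counts refer to *maximal* PVC runs of exactly 2 / 3 (a
4-run is one run, not two couplets); `run_gt2` is max run > 2. Bigeminy
requires ≥3 contiguous alternating normal–PVC pairs. "Frequent" means
>10 PVCs (strict) in any 60-s window anchored at a PVC — over the 60-s
recovery phase this reduces to the plain count. Coupling intervals are
R-to-R from the preceding beat; the R-on-T *candidate* flag uses
<400 ms (strict) and only counts PVCs preceded by a sinus beat, since
intra-run intervals are short by construction; true R-on-T confirmation is
a visual criterion this package does not claim to automate. Multifocality
is any pairwise correlation <0.75 among R-aligned PVC snippets (undefined,
hence False, with fewer than two PVCs). High-grade = frequent ∨ multifocal
∨ run>2 ∨ R-on-T candidate. Heart-rate change metrics use mean rates from
consecutive-normal RR intervals only (PVC and compensatory intervals
excluded) over the rest phase and the final 15 s of exercise and recovery.

## Survival analysis

Cause-specific, sex-stratified Cox proportional hazards (statsmodels
PHReg, Efron ties): other-cause events are censored at occurrence, and
each sex keeps its own baseline hazard (motivated by a Schoenfeld-residual
test helper that flags sex when modelled as a covariate). The minimal
covariate set is age + heartbeats in the relevant phase; the full set adds
diabetes, hypertension, beta-blocker, smoking, LDL, HDL, triglycerides,
BMI, QRS, QTc, ST-depression and the phase heart-rate change. "Number of
heart beats" uses total beats (PVCs included); the alternative
(normal-only) differs by under 1% in these data. Exposure categories that
are unobserved in a given dataset are dropped from the design rather than
fit as empty columns.

**Floated CIs.** With K burden groups the fit returns K−1 contrasts
against the 0-PVC reference; floated variances v_0 … v_{K−1} re-express
the uncertainty so each group (reference included) has its own interval
with v_i + v_j ≈ Var(β_i − β_j) for every pair. Shared-reference contrast
covariances have the structure Cov(β_i, β_j) ≈ v_0 (i ≠ j),
Var(β_i) ≈ v_0 + v_i; the closed-form fit (v_0 = mean off-diagonal) is
refined by least squares on the relative error of all pairwise contrast
variances, with a floor of 1e-6 × mean diagonal so the independence limit
yields a degenerate-but-defined reference variance. With K = 2 only the
sum v_0 + v_1 is identified; the floor convention closes it, so a binary
exposure's reference group shows an (intentionally) near-zero-width
floated interval.

**Imputation and pooling.** MICE with predictive mean matching (donor
pool k = 5, the conventional size), m = 5 completed datasets, 10
chained-equation iterations per dataset, each dataset an independent
chain; all baseline variables plus follow-up time and event indicator
inform the conditionals. Engine: statsmodels `MICEData`; observed cells
are asserted untouched. Cox fits are pooled with Rubin's rules — mean
coefficients, total variance = within + (1 + 1/m) × between, applied
element-wise to the full coefficient covariance so floated CIs can be
computed after pooling — with Barnard–Rubin degrees of freedom
(complete-data df = events − parameters; the most conservative
per-coefficient df is used for the t reference).

## Benchmark sizes and numerical conventions

The acceptance checks run, on one CPU: rhythm-grammar equivalence against
brute-force oracles on 1,000 random beat sequences; the detector chain
trained on 60 recordings and scored on 300 held-out recordings
(thresholds: category accuracy ≥0.90, beat-level PVC sensitivity and PPV
≥0.95 at ±75 ms); segmentation round-trip on 200 random lengths; CI
coverage of the planted hazard ratios over 200 replicates of n = 4,000
with a raised baseline rate (~12% events, so every category carries
enough events for Wald intervals to be in their asymptotic regime);
MICE-vs-complete-data agreement at n = 6,000 with 10% MCAR; floated-CI
reconstruction on 50 random shared-reference covariances; Rubin
arithmetic on an analytic fixture; and null calibration of log-rank and
Wald p-values over 400 replicates of n = 1,000 with three occupied burden
groups (five groups at that n can leave a group event-free, which is a
separation failure, not a calibration one).

Degenerate-input conventions: empty beat sets summarise to all-zero
counts and all-false flags; an all-background probability track yields an
empty call set; a cohort guaranteed all-censored, an unknown exclusion
flag, a fully missing column, an unknown endpoint and a non-positive-
definite covariance block all raise immediately with named errors.

## Known limitations

The detector is trained and validated on synthetic morphology only; no
claim is made about clinical ECG without retraining. R-on-T and
multifocality are automated triggers, not confirmed diagnoses. The cohort
generator uses a single latent event process with a multinomial type,
so competing risks are stylised (cause-specific analyses remain valid by
construction). Fine–Gray subdistribution modelling, powerline/motion
artefact handling, and supraventricular ectopy are out of scope.
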