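# Methods

## Model

The package computes right-ventricular (RV) total power output (TPO,
J/min) as isovolumic power plus stroke power and couples it to
myocardial oxygen consumption (MVO2, ml/min) at 20.2 J per ml O2, the
theoretical yield of oxidative phosphorylation with mixed substrates.
Glycolytic (anaerobic) power is assumed negligible; the regression
intercept of TPO on MVO2 is the empirical check on that assumption.
Oxygen delivery to the RV free wall is modelled as
`1.34 · OEF · Q_RCA · Sa · Chb` (ml O2/min), i.e. right coronary flow
times arterial O2 content times the extraction fraction; left-coronary
contributions to the RV are neglected.

Two variants of the mechanical side are provided.

* **Original** (`variant="elbeery"`): isovolumic power
  `HR·mRV_EP·(RV_EDV − V0)·1.33e-4`; stroke power as the
  ejection-window time-average of instantaneous hydraulic power,
  `(1/T)∫P_PA·Q_PA dt`, by trapezoidal integration, averaged over the
  first five beats. `V0` (dead volume) defaults to 0 and is exposed for
  sensitivity analyses.
* **Adjusted** (`variant="adjusted"`): isovolumic power
  `HR·(mRV_EP − RV_EDP)·RV_ESV·1.33e-4` — a deliberate lower bound: only
  the residual end-systolic volume is charged, and preload pressure is
  treated as work done upstream. Closed-form stroke power
  `HR·mPAP·SV·1.33e-4 + 0.156·PP`, the second term estimating
  oscillatory power as proportional to pulse pressure. When
  instantaneous flow *is* measured (the animal path), the integrated
  stroke power is used instead of the closed form.

RV efficiency is useful (non-pulsatile) stroke power over TPO. The
useful-power product mPAP·CO is multiplied by the same
1.33e-4 mmHg·ml→J factor so the ratio is dimensionless; internally all
computation is in mmHg / ml / min / J, with converters for L/min and
kPa at I/O boundaries only.

The oscillatory coefficient 0.156 multiplies PP alone (it is not scaled
by HR or SV). The literature method it abbreviates is a per-beat
oscillatory-work estimate, so this is a modelling choice; the
coefficient is a configurable `ModelConstants` field.

## Waveform processing

Beat segmentation uses the smoothed first derivative of RV pressure
(Savitzky–Golay, default 15 ms window, order 3): ejection onset at a
prominent derivative maximum (≥ half the global maximum, candidates
closer than 100 ms merged), end-systole at the following derivative
trough, cycle boundaries onset-to-onset. The detector is invariant to
constant pressure offsets. Ensemble averaging resamples each selected
beat (default five, starting at the first complete beat) onto the
shortest beat's grid by linear interpolation and averages pointwise.
Asynchronously recorded channels are treated as simultaneous; no
alignment is attempted. Mean ejection pressure is the trapezoidal
time-average of RV pressure over [onset, end-systole].

The invented flow profile is `A·SV·exp(−3t)·sin(πt/t_es)` up to
`t_es + 0.02` (the sine's continuation past `t_es` forms the negative
regurgitant lobe), a linear ramp to zero over the next 0.02 s, and zero
through diastole. The decay argument is time in seconds. Calibration
sets A so the full-cycle mean (zero-flow diastole included, since
cardiac output is a per-cycle mean) equals CO, by 1 kHz trapezoidal
quadrature; the profile is linear in A so this is a single division.
When integrating the invented profile against PA pressure, the ejection
window is extended by the 0.04 s regurgitant tail so negative
regurgitant work is captured; measured flow is integrated over
[onset, end-systole] only.

## Synthetic data

The clinical generator draws per-class marginals from truncated normals
with the published PAH group summaries (classes II/III/IV: mPAP
47.4±11.7 / 58.8±13.3 / 65.3±22.9 mmHg; CO 5.6±0.9 / 4.2±1.1 /
3.5±1.4 L/min; EF 0.46±0.133 / 0.31±0.035 / 0.19±0.044; right coronary
flow 47.5±15.5 / 64.6±20.8 / 55.2±12.6 ml/min; OEF 0.60±0.15 /
0.70±0.16 / 0.90±0.08). Default group sizes are the study's 8/4/3.
Truncation bounds are physiologic; the underlying location of each
truncated normal is solved (moment matching) so the truncated mean
equals the published mean — otherwise strongly bounded fields (NYHA-IV
OEF against its ceiling of 1) would generate systematically below
target. SDs are applied on the underlying normal, so sample SDs of
tightly bounded fields run slightly below the published values; means
are exact.

Fields the source tables do not report carry documented assumptions:
HR 78/85/90 ± 10–12 bpm, RV_EDP 8/11/14 ± 3–4 mmHg, Sa
0.94/0.92/0.90, Chb 0.14 g/ml; mRV_EP = mPAP + 3 mmHg; PP = 0.8·mPAP.
Dependent quantities are derived, never drawn (SV = CO/HR,
RV_EDV = SV/EF, RV_ESV = RV_EDV − SV), so every row satisfies the state
invariants exactly; rare extreme RV_EDP draws are clipped to
0.5·mRV_EP. MVO2 is generated from the adjusted model's TPO as
`TPO/20.2·(1+ε)`, ε ~ N(0, cv) with cv = 0.05 by default, plus an
optional oxygen-independent anaerobic offset (default 0); the variant
is configurable for robustness checks.

Waveforms are a raised-cosine RV systolic bump on the diastolic floor
(scaled so the analytic mean over the ground-truth ejection window —
the interval between the derivative extrema of the bump — equals
mRV_EP), a PA beat with raised-cosine upstroke and exponential
diastolic decay whose offset and amplitude are solved in closed form so
the cycle mean is exactly mPAP and the range exactly PP, and PA flow
from the calibrated invented profile (clinical) or a raised-cosine
systolic pulse integrating to SV per beat (animal emulation of a flow
probe). Ground-truth beat timings are returned so detection can be
tested against the generator. These shapes are deliberately simple and
analytically integrable; they do not claim pathological waveform
morphology (no dicrotic notch, no post-systolic contraction), so
passing tests demonstrate numerical correctness of the pipeline, not
morphological realism.

The animal generator follows the banding/hypoxia protocol: a baseline
row, then one row every 40 simulated minutes for 4 h under one of four
conditions (ΔZ0 ∈ {0, 4} mmHg/(L/min) × Sa ∈ {1.00, 0.75}); banding
raises mPAP by ΔZ0 × CO(L/min); OEF is 0.50 in normoxia and 0.60 in
hypoxia. Healthy-sheep baselines (HR 95, mPAP 18 mmHg, CO 5 L/min,
EF 0.45, Chb 0.10 g/ml) carry 3% multiplicative measurement jitter.
MVO2 is coupled to the measured-flow (integrated-stroke) adjusted TPO,
and right coronary flow is back-derived from that demand through the
delivery relation, so supply matches demand as the coupling hypothesis
assumes.

## Statistics

Power–oxygen and efficiency–oxygen relations are simple OLS fits
(statsmodels), TPO or efficiency as response and MVO2 as predictor,
with t-based 95% CIs (n−2 df). Power-fraction summaries report
group-wise mean ± SEM (sd/√n, ddof = 1; SEM undefined for n = 1) of the
isovolumic/useful/pulsatile fractions, NYHA III and IV pooled. The
class comparison is a one-way MANOVA on (efficiency under each variant,
MVO2), Pillai's trace by default (Wilks optional), with Welch post hoc
t-tests Bonferroni-corrected by 3. Exactly identical class means return
statistic 0 and p = 1 by convention (the parametric machinery is
degenerate there); singular within-group covariance or error df below
the number of dependent variables raises a rank-deficiency error with
guidance to drop a variable.

## Numerical and design notes

* Stroke-power integration is trapezoidal on the trace's own grid; at
  1 kHz it agrees with a 10 kHz quadrature to well under 0.1% for the
  synthetic beat family.
* `1.33e-4` J/(mmHg·ml) agrees with the SI-derived 1.33322e-4 to three
  significant figures and is kept at the model's printed precision.
* Ensemble averaging uses linear interpolation; monotone and adequate
  at 250–1000 Hz.
* Known attenuation: because generated MVO2 carries multiplicative
  noise and sits on the predictor side of the regression, the fitted
  slope is attenuated by var(TPO)/(var(TPO)+cv²·E[TPO²]) — a few
  percent below 20.2 under the default cohort (≈19.2–19.9 at n = 200),
  with a correspondingly positive intercept. The noiseless cohort
  recovers slope 20.2, intercept 0, R² = 1 exactly, confirming the
  coupling itself; the attenuated noisy-slope behaviour matches what
  real measured cohorts show. Consequently the noisy slope's 95% CI
  frequently excludes 20.2; this is a property of the
  errors-in-variables design, not an implementation defect.
* Monte-Carlo suites (CI coverage, efficiency-slope significance) use
  n = 200 cohorts in the study's class proportions (107/53/40);
  fixture-style checks use the study-sized 8/4/3 cohort. Problem sizes
  were chosen so the full suite completes in well under a minute of
  compute for the deterministic parts and a few seconds per
  Monte-Carlo study.

## Limitations

Tricuspid-regurgitation stroke work, post-systolic isovolumic
contraction and septal interaction are outside the model. The synthetic
cohorts draw fields independently within class (only marginal summaries
are published), so cross-field correlations of real PAH cohorts are not
reproduced; between-class structure supplies the severity gradient.
Results on synthetic cohorts validate the pipeline's internal
consistency and statistical machinery, not the model's clinical
accuracy.
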