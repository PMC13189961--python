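# Methods

`dsfnet` implements a cost-sensitive early-warning pipeline for
post-stroke neurocritical-care monitoring: a dual-stream neural network that
fuses high-frequency physiological waveforms with structured vital signs,
trained on densely overlapping 15-second windows, thresholded at the
F1-optimal operating point, and explained with Integrated Gradients.
Because the clinical cohort such models are trained on is private bedside
data, the package ships a synthetic bedside-monitor simulator and all
empirical claims made by its tests are claims about recovery of *injected*
signal under controlled conditions.

## Data model

One frame per second carries 587 scalars: a timestamp; 8 vital signs (HR,
PR, SpO2, PI, NIBP systolic/diastolic/mean, RR); 6 per-minute cardiac-event
counters (PVCs, VPBs, pauses, missed beats, couplets, R-on-T); 256 ECG
samples; 256 respiration samples; 60 plethysmogram samples.  Waveform
amplitudes are dimensionless normalised units — monitors do not export
calibrated millivolts consistently, so the simulator does not pretend to.
The cardiac-event counters are rolling trailing-60-s counts (the "/min"
reading most monitors display).

## The simulator

ECG beats are sums of five Gaussians (P, Q, R, S, T) placed on a
phase-continuous beat schedule; beat spacing follows the commanded heart
rate.  A PVC is rendered as a premature (0.35 of a period early), wide,
negatively skewed complex with a discordant T wave followed by a
compensatory pause; an R-on-T event is a narrow ectopic landing on the
previous T wave.  Respiration is a quasi-sinusoid at RR/60 Hz; the pulse
waveform is a cubed-sine systolic upstroke with a dicrotic bump whose
amplitude scales linearly with the perfusion index.  Vital signs wander
around per-patient baselines as AR(1) tracks; PR tracks HR up to noise and
NIBP mean is D + (S − D)/3.

A deterioration episode is injected as a linear precursor ramp of
configurable duration ending at the annotated onset: ectopic rates rise to
~0.35·intensity/s, SpO2 falls by up to 5·intensity %, systolic pressure
drifts up by 12·intensity mmHg, HR variability increases, and the counters
are updated consistently.  `intensity` is a dimensionless gain: 1 is a
subtle episode, 3 (the test default) an overt one.

Cohort generation solves for a common onset time such that, after default
windowing and labelling, the realised window-level negative:positive ratio
matches the configured imbalance target (the clinical regime is ~1:160;
the generator verifies the realised ratio within 25%).  All randomness
derives from one seed via spawned child generators, so cohorts are
byte-reproducible.

What the simulator does **not** emulate: realistic HRV spectra, baseline
wander and electrode artifacts, drug effects, inter-signal physiological
coupling beyond the HR/PR/PI relations above.  A model that recovers the
injected signal here is shown to be *able* to learn such precursors, not
shown to perform at any particular level on real patients.

## Windowing and labels

Windows are L = 15 frames with stride S = 1 (overlap (L−S)/L ≈ 93%).  A
window is anchored at its **last** frame — the moment an alert would fire —
and labelled positive iff that frame's time t satisfies
onset − 1800 s ≤ t < onset.  Frames in a post-onset guard band
[onset, onset + 1800 s) are excluded from both classes so "stable" negatives
are not contaminated by the deterioration itself.  Frame matrices are
stored once per patient as float32 binaries and windows are addressed as
(patient, end-index) views over memory maps, so storage grows with frames,
not with the ~15× larger window count.

Splits are patient-level (8:1:1 by default, floor allocation with the
remainder to train; 30 patients → 24/3/3).  Because desk-scale cohorts are
small, the splitter by default *stratifies*: one episode-bearing and one
episode-free patient are planted in each set before the rest are shuffled
in.  Without this, a 1-or-2-patient validation set is frequently
single-class and AUC/τ* are undefined.  The k-fold protocol draws a fixed
~10% holdout first, partitions the rest into k patient-disjoint folds, and
evaluates every fold's model on the same holdout; the generalisation gap is
mean validation AUC minus mean holdout AUC.

## Architecture

Per frame, the pleth signal is linearly upsampled 60 → 256 and stacked with
ECG and respiration into (3, 256).  Two conv blocks (kernel 7, stride 2,
padding 3, channels 3→16→32, each batch-norm + ReLU + dropout 0.3) reduce
the length 256 → 128 → 64 and flatten to 2048 — the channel plan is the
minimal one satisfying the 2048-d contract given kernel/stride.  The 14
numeric features (timestamp excluded) pass a 14→64→32 MLP with batch norm
and ReLU.  Concatenation yields the 2080-d fused frame vector.  A window's
T = 15 fused vectors are projected to d_model = 128, offset by a learned
T×128 positional table (normal init, sd 0.02), and encoded by a 2-layer
post-norm Transformer (4 heads, feed-forward width 256, dropout 0.1) —
depth/heads are unspecified in the source architecture and chosen small for
CPU-scale training; all are exposed in `ModelConfig`.  The last time-step's
hidden state (causal "last-step pooling") feeds a linear head producing one
logit.

Ablation switches: `use_waveform_branch=False` feeds only the 32-d numeric
embeddings; `use_temporal_fusion=False` classifies from the final frame's
fused vector alone (projection + ReLU + head, no Transformer);
`use_positional_encoding=False` drops the positional table while keeping
the attention stack and last-step pooling unchanged — pooling is never
switched to an attention-pooling head in any variant.

Inputs are z-scored with statistics fitted on the training split only
(per numeric feature; per waveform channel) — the leakage-safe choice.

## Training

The loss is ω-weighted binary cross-entropy,
L = −(1/N) Σ [ω·y·log p + (1−y)·log(1−p)], ω = 160 by default (the
clinical imbalance), computed from logits in softplus form.  Optimisation
is Adam (lr 1e−4, β = 0.9/0.999) with early stopping on validation loss
(default patience 5 in the library; the checkpoint kept is always the
minimum-validation-loss epoch).  GPU-scale settings (batch 4096, ≤50
epochs) remain selectable; the desk defaults used by the pipeline and tests
are batch 128 and ≤5 epochs, sized so a full run fits a single CPU.

The numerical backend is a package-local reverse-mode autodiff engine over
numpy (`dsfnet.nn`): conv1d via im2col, fused batch norm, layer norm,
multi-head self-attention, dropout with inverted scaling, Adam.  Gradients
of every primitive are verified against central differences in float64;
training runs in float32.  Determinism: all weight init, shuffling and
dropout derive from configured seeds; residual nondeterminism is limited to
BLAS reduction order.

## Evaluation

Recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), and AUC in the rank form
(Σ ranks of positives − M(M+1)/2)/(M·N) with ascending midranks for ties,
which equals Mann–Whitney pair counting (ties half).  The decision rule is
score ≥ τ; degenerate ratios return 0 and are logged.  τ* maximises F1 over
(0,1) exactly: F1 is piecewise constant between adjacent distinct scores,
so scanning distinct scores plus midpoints (plus sentinels below/above the
range) attains the global optimum; ties break toward the smallest τ,
favouring recall.  τ* is fitted on validation scores and frozen for test;
recalibration under drift is an explicit re-run of the scan.  Score
diagnostics use 100 fixed bins on [0,1] per class with the overlap
coefficient Σ min(h⁺, h⁻).

## Interpretability

Integrated Gradients along the straight path from baseline x′ to input x,
right-Riemann with m = 50 steps by default (trapezoid selectable),
attributing the post-sigmoid probability (the clinical risk scale; the raw
logit is selectable and is the target used for the linear-model exactness
oracle).  The baseline is the all-zeros input in normalised space, i.e. the
training-split mean in raw units.  The completeness residual
|Σ attr − (F(x) − F(x′))| is recorded in every result, never hidden.
Attributions are reported on the model's input axes; pleth attributions are
mapped back 256 → 60 by splitting each interpolated sample's attribution
between its two source samples with the interpolation weights, which
preserves total mass exactly.  Vital-sign attributions are presented as a
signed 14 × T heatmap (positive = risk-driving).  Attribution is
per-window; no cross-window aggregation is performed.

## Problem sizes used by the tests

The standard recovery benchmark ("easy cohort") is 20 patients × 450 s,
30% episode prevalence, imbalance 1:40, intensity 3, one shared training
run of ≤4 epochs; a 12-patient × 240 s cohort (1:25) backs the paired
ω = 160 vs ω = 1 comparison and the k = 3 + holdout CV check; the 1:160
clinical regime is exercised with 30 patients × 1200 s where only window
counting is needed.  These sizes are the package's chosen desk-scale study
conditions: large enough that the easy cohort is learnable to validation
AUC > 0.95 and the CV gap is stable, small enough to keep a full run on one
CPU core.  With 8:1:1 splits of ~20 patients the validation set holds only
a few hundred windows, so reported AUCs carry meaningful sampling noise —
another reason the tests assert thresholds, not point values.

## Known limitations

- Synthetic-only validation; no claim transfers to real cohorts.
- The simulator's separability is dominated by the numeric stream (SpO2,
  counters); the waveform branch is exercised but not strictly necessary to
  pass the recovery thresholds at intensity 3.
- Single onset time shared across episode patients (chosen by the
  imbalance solver); episode heterogeneity is limited to patient baselines
  and noise.
- Post-norm Transformer at depth 2 only; no learning-rate schedule, mixed
  precision, or multi-device support.
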