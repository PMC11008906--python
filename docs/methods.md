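# Methods

## Study design

The package analyses single-lead resting ECG from cohorts of healthy
subjects labelled with one of 15 ordinal age groups: 18–19, thirteen
consecutive 5-year bins from 20 to 84, and 85–92. Two classifiers predict
the age group from the same recordings through different representations
— record-level engineered features versus raw 3-second waveform crops —
and two attribution procedures then ask *what* each model used. Because
age cohorts of this kind are strongly imbalanced, the headline metric is
the macro-averaged one-vs-rest AUC (insensitive to prevalence and to
probability calibration), accuracy is reported only for comparability,
and uncertainty comes from subject-level bootstrap resampling of the test
set reported as the 2.5 and 97.5 empirical percentiles (a 95 % interval
by the usual convention; the report labels the percentiles themselves to
avoid ambiguity). For comparison with models that operate on broad
categories, 15-group probabilities can be summed onto 4 contiguous
categories; the partition (18–34 / 35–49 / 50–64 / 65–92) is a documented
configuration value since no canonical mapping exists.

## Synthetic cohorts

The generator exists so that every downstream stage has exact ground
truth. A heartbeat is a sum of five Gaussian deflections (P, Q, R, S, T)
with per-group amplitude (mV), width (σ, ms) and centre offset relative
to the R peak. Beat timing follows an NN-interval model
`NN(t) = 60000/HR + RSA·sin(2πf_b t) + drift·sin(2πt/T_d) + frag(t)`,
where respiratory sinus arrhythmia (RSA) is a sinusoid at the breathing
frequency f_b, the slow drift emulates minute-scale autonomic wandering
(default 20 ms over 60 s), and fragmentation adds sign-alternating ±8 ms
perturbations with a per-beat probability — the mechanism that drives the
PAS metric up and, together with shrinking RSA, pNN20 down. R-peak
amplitude is modulated at f_b (default 8 % relative depth) so that
ECG-derived respiration is recoverable. White Gaussian noise (default
0.02 mV) is added last. Records carry hidden annotations (true R times,
analytic fiducials — a Gaussian falls to 10 % of its peak at
centre ± 2.146 σ — and the NN series) that only tests and benchmarks
read.

The default profile injects the age trends the explainability stages are
expected to recover: breathing declines linearly from 16.5 to 8.8
breaths/min, P amplitude rises from 0.10 mV to a 0.26 mV peak at the
55–59 group and falls to 0.08 mV afterwards, RSA shrinks from 45 to
10 ms while fragmentation grows from 0.02 to 0.72, T amplitude declines
from 0.35 to 0.14 mV and mean heart rate climbs from 62 to 73 bpm.
Subject-level jitter (4 % relative on amplitudes, 1.5 bpm on heart rate,
0.2 breaths/min on breathing) is deliberately small against the
between-group steps: the cohort is a *separable-by-construction* test
harness, not a model of population variance. Three derived profiles
support specific experiments: `two_effect_profile` (only breathing and P
amplitude vary — used to test injected-trend recovery),
`p_amplitude_only_profile` (only P amplitude varies; its T amplitude is
fixed at 0.45 mV, well above both P levels, so a translation-tolerant
amplitude detector cannot confuse the P and T bumps and the only
discriminative cue is the P wave), and `flat_age_profile` (identical
groups — the null control).

What the generator does **not** emulate: realistic morphology variation
(notched P waves, QRS axis, ST segments), pathology, baseline wander,
electrode artifacts, or realistic inter-subject overlap. Passing tests
therefore demonstrate that the *pipeline machinery* is correct and that
the explainability stages recover known injected mechanisms; they say
nothing about classification performance on real recordings.

## Preprocessing

Missing samples are dropped and the remainder concatenated (records are
never excluded; a record with more than half its samples missing is
rejected); gap positions are kept so that crops never straddle a gap
wider than one sample. Resampling to 100 Hz uses polyphase FIR
anti-aliased decimation. Crops are non-overlapping consecutive 3-s tiles
from sample zero with the trailing partial tile discarded — a
deterministic policy whose crop counts match exhaustive tiling of the
usable signal. The subject-level 60/20/20 split is stratified per age
group with at least one subject of every group in every partition (groups
with fewer than three subjects make this impossible and raise an error).
Random oversampling duplicates minority-class items uniformly with
replacement up to the majority count and never invents new items.

## Beat detection and delineation

R detection is a Pan–Tompkins-style chain: 2nd-order Butterworth band-pass
5–15 Hz (zero-phase), derivative, squaring, 150 ms moving-window
integration, adaptive dual thresholds with exponentially updated signal
and noise levels, a 200 ms refractory period, and mapping of each
detection to the raw-signal maximum within ±50 ms. Delineation uses
windowed extrema — Q = minimum in (R−80 ms, R), S = minimum in
(R, R+80 ms), P peak = maximum in (R−300, R−100 ms), T peak = extremum in
(R+150 ms, min(R+450 ms, next R − 100 ms)) — with onsets/offsets at the
nearest sample where the wave falls to 10 % of its peak-to-baseline
amplitude; the local baseline is the median of the quiet (R−300, R−220 ms)
window. Windows truncated by record edges, and P/T waves below 0.02 mV,
yield absent fiducials; a final pass enforces strict ordering. These
rules are deterministic and exactly checkable against the Gaussian
generator, which is why they were chosen over wavelet delineation.

NN intervals are successive R-R differences in ms; intervals outside
[300, 2000] ms or deviating more than 20 % from a centred 11-beat running
median are rejected and counted. This range-plus-median rule is this
package's operational definition of "normal-to-normal".

## Features

Time-domain definitions follow the printed formulas exactly: SDNN with
the n−1 denominator, RMSSD, pNNx with strict inequality (`|ΔNN| > x`),
MCVNN = median absolute deviation / median. SDANN1/SDANN5 are the *mean*
of per-window SDNN over consecutive 1-/5-minute windows from t = 0
(trailing partial window discarded, windows needing ≥ 2 intervals) —
i.e. the SDNN index, which is the stated definition here even though the
classical SDANN is the SD of window means. PAS marks maximal runs of
strictly sign-alternating successive differences spanning at least 4 NN
intervals (zero differences break runs) and reports the percentage of
intervals inside such runs — the canonical fragmentation definition.

DFA integrates the mean-centred series and measures RMS fluctuations of
linear-detrended non-overlapping boxes, α₁ over box sizes 4–16 and α₂
over 16–64 (log-spaced), as least-squares slopes in log-log space. At
these small box sizes plain DFA is biased (white noise measures ≈ 0.59
over 4–16); fluctuations are therefore divided by an **exact analytic
finite-size factor** — the expected fluctuation of the linear-detrend
residual operator applied to a cumulative sum of unit white noise,
computed from the trace of the corresponding quadratic form — which makes
white noise scale as n^0.5 exactly. Measured limits: α₁ ≈ 0.50 on i.i.d.
noise and ≈ 1.42 on integrated noise (the Brownian limit retains a small
residual finite-size bias at these scales).

The multifractal summary uses generalized fluctuation moments
F_q(n) = ⟨F_box^q⟩^{1/q} for q ∈ {±1, ±2, ±3} over box sizes 8 to
min(64, N/8), slopes h(q), singularity exponents α(q) = h(q) + q·h′(q),
and reports the mean and the width (max − min) of α(q). Strongly negative
moments over boxes of size 4–16 are dominated by near-zero detrending
residuals (few residual degrees of freedom per box) and make the width
diverge even for monofractal input, so the moderate q-range and larger
minimum box size are essential; with them, monofractal white noise gives
a width of ≈ 0.15 and a mean consistent with α₁. Both summaries are
documented, swappable definitions (module constants).

Frequency-domain powers come from cubic interpolation of the NN series
onto a uniform 4 Hz grid and a Welch periodogram; LF = 0.04–0.15 Hz,
HF = 0.15–0.40 Hz, integrated in ms². ECG-derived respiration
interpolates the R-peak amplitude series to 4 Hz, removes a linear trend,
and takes the breathing rate from the spectral maximum in 0.08–0.5 Hz of
a single-segment Welch spectrum with 8× zero-padding (peak location below
the nominal resolution matters more than variance reduction here); the
breathing-signal summary is the standard deviation of the detrended
respiration waveform.

Short-range features measure wave amplitudes as the 3-sample local mean
at the fiducial minus the local baseline (the local mean suppresses the
positive bias of reading a noisy sample selected as a window maximum),
and intervals PR, QRS, QT, P/T durations in ms; RR and heart rate come
from neighbouring R peaks. Record-level rows average each field over the
beats where it is present; everything missing stays missing and is
median-imputed only inside the tree model, from training rows only.

## Models

**Feature path.** XGBoost multi-class softprob with max_depth = 10,
max_leaves = 10, learning_rate = 0.008 — the configuration found optimal
for this task — with 300 boosting rounds as the package default (enough
rounds at that small learning rate for desk-scale cohorts) and
min_child_weight = 10⁻³: softprob hessians are ≈ p(1−p) per row, so the
library default of 1 silently blocks all splits on cohorts of tens of
records per class. Balanced training applies random oversampling to the
training partition only.

**Raw path.** A 1-D residual convolutional network written directly in
numpy with explicit forward and backward passes, which makes the input
gradient — the saliency substrate — a first-class output. The desk-scale
default is a strided stem (kernel 7, stride 2) plus two basic residual
blocks (kernel 3, width 16) and a global-average-pooled linear head: its
small receptive field (~0.3 s) matches the scale of beat components and
yields well-localized saliency; `block="bottleneck", n_blocks=16,
width=64` instantiates the full 50-convolution bottleneck arrangement.
Training uses AdamW (weight decay 10⁻², a documented default), focal loss
with γ = 2 (γ unstated in the focal-loss citation; 2 is its canonical
value) or cross-entropy, optional inverse-frequency class weights,
batch size 32 and learning rate 3·10⁻³ as desk-scale defaults (many
optimizer steps within few epochs on small cohorts; the full-scale
protocol's 10⁻⁵/10⁻² rates are available through the config), a
plateau schedule dividing the learning rate by 10 after 2 consecutive
non-improving epochs, and early stopping after 3. Validation is monitored
at crop level when supplied. Subject predictions are arithmetic means of
crop probability vectors; argmax ties break toward the younger group.

## Explainability

Tree attributions use TreeSHAP (exact tree-path attributions on the
margin scale, satisfying local accuracy: base value plus contributions
equals the margin within 10⁻³), computed per class. Per-group rankings
sort features by mean |attribution| for that group's class over the
training partition; the direction is the sign of the Spearman correlation
between feature value and attribution. The training partition is used for
all aggregated attribution outputs so both paths explain the same data
the models were fitted on.

Raw-model saliency is the absolute input gradient of the target-class
pre-softmax score (the one attribution method here that passes the
weight-randomization sanity check, which the test suite re-runs: saliency
from a randomized network decorrelates from the trained network's,
mean |r| ≈ 0.05). Crop saliencies are beat-aligned on detected R peaks
over a window from 300 ms before to 500 ms after the R peak — the
physiological window that actually contains the P and T waves; a
30/50 ms variant is exposed in the configuration but cannot span the
waves it is meant to display, so the wide window is the default.
Alignment averages over all usable beats within subject, then groups
average over subjects (each subject counting once); the 8 highest
mean-saliency timesteps per group are marked, ties toward earlier
samples. Segment occupancy assigns each mark to P_onset [P_onset,
P_peak), P_offset [P_peak, P_offset], Q/R/S bands (point fiducials
widened to ±20 ms — point events need nonzero measure), T [T_onset,
T_offset], or TP (outside [P_onset, T_offset], covering both the post-T
gap and the pre-P tail of the previous beat), with the group-mean
fiducials obtained by delineating the aggregated beat itself; marks
without the needed fiducial count as unassigned. Percentages use the
pooled denominator — all marks across all groups (15 × 8 = 120 under the
full design).

## Numerical and degenerate-input conventions

Indices are 0-based with half-open windows. Probabilities must sum to 1
within 10⁻⁶. Focal loss clips p at 10⁻¹² before the log. Flat signals
yield no R peaks (not an error); absent waves yield absent fiducials;
features with insufficient input are NaN, never exceptions. Bootstrap
replicates on which the metric is undefined are redrawn and counted. A
single global seed derives fixed per-stage offsets so stages can be
re-run in isolation; the feature path is bit-reproducible under a fixed
seed and the raw path is deterministic in-process.

## Problem sizes

Desk-scale experiment sizes used by the test suite and the acceptance
script: 15 × 10 subjects with 5-minute records for the feature-path
recovery experiment; 2 × 30 subjects with 2-minute records and 3 training
epochs for the raw-path mechanism recovery; 15 × 8 training / 15 × 6 test
subjects (feature) and 4 × 12 / 4 × 25 (raw) for the null controls;
10,000-beat series with 20 replicates for the DFA limits; 1,000 random
NN series for the formula oracle. These sizes give stable statistics at
interactive runtimes.

## Known limitations

Five-minute synthetic records leave SDANN5 and the multifractal
summaries undefined (they need ≥ 10 minutes and ≥ 500 beats); they are
exercised by direct unit tests instead of the cohort experiments. The
Brownian DFA limit retains a ≈ 0.08 downward finite-size bias over boxes
4–16. The WFDB reader supports the format-16 header+signal layout the
package writes, not the full format zoo. Real-data performance claims are
out of scope: the synthetic cohorts are constructed to be separable, and
the pipeline's AUC values on them measure machinery, not clinical signal.
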