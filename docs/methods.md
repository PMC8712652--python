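# Methods

## Problem and scope

`nirsloc` implements a complete single-subject analysis chain for a
block-design fNIRS sound-localization experiment: a listener faces a
7-loudspeaker arc (-90 to +90 degrees, 30-degree spacing), five active
speakers present 10-s pink-noise bursts at 48 or 58 dB SPL (10 repetitions
per condition, 100 trials), and a 20-channel continuous-wave NIRS montage
records oxy-hemoglobin concentration changes at 13.3 Hz over bilateral
premotor (BA6), supramarginal (BA40), dorsolateral prefrontal (BA9),
superior temporal (BA22) and auditory-association (BA42) cortex, grouped
into 10 regions of interest (ROIs 1-5 left, 6-10 right, mirrored pairs).
The scientific question is whether the direction of a sound source can be
decoded from the evoked oxy-Hb response, per subject, with a linear
classifier.

Because the original recordings are not deposited, the package includes a
first-class synthetic session generator so that every stage of the chain
is verifiable end to end.

## Hemoglobin conversion

The modified Beer-Lambert law relates optical-density change at wavelength
w to chromophore concentration changes:

    dOD_w = (eps_oxy(w) * dC_oxy + eps_deoxy(w) * dC_deoxy) * L

With three wavelengths (780/805/830 nm) and two chromophores the system is
overdetermined; `mbll_convert` solves it per sample by least squares
(pseudoinverse of the extinction matrix).  Continuous-wave instruments do
not resolve the differential pathlength factor, so concentrations carry
units of mM*mm (pathlength-scaled) throughout and the shipped pathlength
(30 mm) and extinction table are editable constants — the instrument
vendor's internal values are not public, and only relative changes enter
the analysis.  Deoxy- and total-hemoglobin are produced by the conversion
but the decoding chain analyses oxy-Hb only.

## Preprocessing

Order of operations on the continuous recording, before any epoching:

1. **Common average reference (CAR).**  The across-channel mean is
   subtracted at every time point.  Any component added identically to all
   channels (global systemic physiology) is removed exactly; this is an
   algebraic identity, tested to numerical precision.
2. **Low-pass** Butterworth, order 4, cutoff 0.2 Hz (removes cardiac
   1-1.5 Hz and most respiratory 0.2-0.5 Hz power).
3. **High-pass** Butterworth, order 4, cutoff 0.03 Hz (baseline drift).

Filters are applied zero-phase (forward-backward, `sosfiltfilt`) by
default: group delay would shift the discriminative 5-8 s post-onset
window, and the composed zero-phase chain attenuates 1.2 Hz by far more
than the 40 dB contract while holding the 0.05-0.15 Hz passband within
1 dB.  A `causal` single-pass mode is provided for strict-literal runs;
whether the original analysis filtered causally is not knowable from the
protocol, and the choice is therefore exposed rather than hidden.

**Epoching.**  10-s windows from stimulus onset; with fs = 13.3 Hz a
window is round(10 x 13.3) = 133 samples.  Sample indices follow one fixed
rule everywhere: index = round(t * fs), half-open windows [start, end).
Epochs are baselined by subtracting the per-channel mean over the second
before onset (`pre_stim_mean`); grand-average curves then start near zero.
A `none` mode skips baselining.  **ROI averaging** replaces the 20
channels by the arithmetic mean of each ROI's 1-4 member channels.

## Feature pool

Evoked responses peak with a variable 3-8 s delay, so each epoch is
covered by 14 overlapping windows (2-s: 2-4...8-10; 3-s: 4-7...7-10; 4-s:
4-8, 5-9, 6-10) and five statistics are computed per unit and window:
mean, sample variance (n-1), moment skewness m3/m2^1.5, excess kurtosis
m4/m2^2-3, and the least-squares slope against time in seconds.
Zero-variance windows define skewness = kurtosis = 0.  The pool is
10 x 14 x 5 = 700 features at ROI granularity (default) or 1400 at channel
granularity; the granularity is a config switch because either level is a
defensible reading of the protocol.  Feature order is deterministic
(unit, then window, then statistic) and is the tie-break order everywhere.

## Feature selection and classification

For each binary contrast the Fisher score of feature k is

    FS_k = (mu_1 - mu_2)^2 / (var_1 + var_2)

with within-class sample variances.  If both variances vanish with
distinct means the feature separates the classes perfectly and receives a
+inf sentinel (ranked first); equal means give FS = 0.

Decoding is leave-one-out cross-validation over the 20 trials of a
contrast: for each held-out trial, standardisation parameters and Fisher
ranking are computed **on the 19 training trials only**, the top-dim
features are selected, and a linear SVM (C = 1 by default; the protocol
specifies no value) predicts the held-out trial.  Accuracy is scanned over
dim = 1..20; the best dim maximises accuracy, smallest dim on ties
(parsimony).  All reported accuracies are therefore multiples of 1/20.
A `global` selection mode (ranking computed once on all trials) is
provided purely as the literal alternative reading; it leaks test
information and a regression test demonstrates the inflation it causes on
label-permuted data.

Two derived analyses reuse this machinery:

* **Interhemispheric pairing** (-90 vs +90 only): each mirrored ROI pair
  is reduced to the member ipsi- or contralateral to the stimulated side,
  giving a 5-unit tensor per side.
* **Per-ROI sound-level decoding**: 48 vs 58 dB at a fixed source, one
  decoder per ROI restricted to that ROI's 70 candidate features.

Group summaries report the mean accuracy as a percentage (2 decimals,
half-up) and the count of subjects at or above the 70% practical margin;
condition comparisons use one-way ANOVA or the Wilcoxon signed-rank test
(identical vectors return p = 1 by convention, since the test statistic is
undefined for all-zero differences).

## Behavioral scoring

Speaker k maps to angle -90 + 30(k-1) degrees.  The RMS localization
error is sqrt(mean(squared angular error)) over the selected trials,
reported to 2 decimals (half-up).  Per-level and pooled errors satisfy
rms_all^2 * n_all = rms_low^2 * n_low + rms_high^2 * n_high up to
reporting precision.  The response matrix counts target x response pairs
(5 active targets x 7 permissible responses).

## Synthetic sessions

`simulate_session` emulates the study conditions: 10-s preparation, then
100 trials of 10-s stimulation / 10-s rest in seeded-random order.  The
evoked response is a canonical double-gamma HRF (peak 6 s, undershoot
16 s, ratio 1/6) convolved with the 10-s stimulus boxcar and normalised to
unit peak, so effect amplitudes are peak oxy-Hb excursions in mM*mm.  An
effect is specified per (ROI, location, level) as (amplitude, latency);
all member channels of an ROI receive the same response.  Note the
boxcar-convolved response is still rising at the end of the 10-s epoch —
the analysis windows see the rise, which is where the discriminative
information lives.

Noise, per channel: cardiac sinusoid (frequency drawn once per session in
1-1.5 Hz, amplitude 0.04), respiratory sinusoid (0.2-0.5 Hz, 0.03), slow
drift (< 0.03 Hz, 0.08), white sensor noise, and a global low-pass-filtered
Gaussian component added identically to all channels (removed exactly by
CAR).  Frequencies are per-session (physiological rhythms are
quasi-stationary), phases per channel.  Trial-to-trial variability is a
multiplicative Gaussian amplitude jitter.

**The lateral-effect preset** encodes the study's phenomenology and was
calibrated once against the reported accuracy ranges, then frozen:

* a bilateral auditory baseline response (ROIs 4, 5, 9, 10) at every
  location and level;
* an extra contralateral STG/supramarginal drive for lateral sources;
* a bilateral dlPFC response for lateral sources only (attention to
  eccentric targets);
* an ipsilateral latency asymmetry: the response to -90 deg peaks earlier
  and to +90 deg later, separating the two lateral sources' waveforms;
* -30/0/+30 deg share one identical pattern (a 30-degree change moves no
  ROI), and 48/58 dB are identical (no sound-level effect), so those
  contrasts decode at chance.

Amplitudes are free parameters of the generator — no effect sizes are
measurable from published group curves — so they were tuned once so that
a 25-subject cohort reproduces the reported regime (lateral contrasts
decoding in the 70-80% band, -90/+90 above -90/0, all +/-30-degree and
level contrasts below the 70% margin) and then committed.  The behavioral
confusion presets mirror the reported error pattern: errors occur only at
+/-90 deg and always land on the adjacent +/-60 deg speaker.

What the generator does **not** emulate: motion artifacts, superficial
(scalp) hemodynamics beyond the single global component, spatially
correlated noise between neighbouring channels, non-stationary
physiological frequencies, and HRF shape variability across subjects.
Passing tests therefore demonstrate the correctness and calibration of the
analysis chain under the stated noise model, not robustness to artifacts
real recordings may contain.

## Statistical design notes

* **Chance-level statistic.**  The per-subject "best accuracy" is a max
  over 20 nested feature-set sizes and is optimistically biased for
  contrasts with no signal: on null sessions it centres near 64%, which is
  exactly the regime of the published +/-30-degree rows (60-68%) — those
  values do not indicate decodable information.  Calibration tests
  therefore check the *dim-averaged* LOOCV accuracy, which is
  chance-centred (measured 47 +/- 2% over 100 null seeds) and is inflated
  by selection leakage, making it the right leakage detector.  The same
  dim-averaged statistic rises monotonically with the generator's effect
  amplitude; the best-dim statistic is validated by effect recovery
  (~100% at high SNR, cohort-level 70-80% bands) rather than by
  monotonicity, because its selection bias flattens the curve between
  zero and weak effects.
* **Determinism.**  All randomness flows from a single integer seed per
  session (`numpy.random.default_rng`); identical configs are
  bit-identical, and cohort runs write a config hash + seed list to their
  manifest.
* **Degenerate inputs.**  Single-channel CAR, single-class contrasts,
  sub-3-sample windows, empty conditions, and invalid confusion tables
  raise `ValidationError` with the offending item named.

## Problem sizes used in tests

Unit and property tests run on single sessions or small random matrices.
The cohort-level acceptance checks use 25 simulated subjects (the study's
cohort size), 100 null seeds for chance calibration, and a 5-point
amplitude grid at 10 seeds per point for effect-amplitude monotonicity.

## Known limitations

* The two anomalous printed montage coordinates (channel 6 at MNI x = -6;
  channel 17 nearly duplicating channel 18) are shipped as published and
  flagged in `probe.py`; coordinates are metadata only and do not affect
  any computation.
* SNIRF support covers processed concentration series plus stimulus
  markers (the subset this chain needs), not raw-intensity acquisitions.
* Multiclass (5-way) decoding, deoxy-Hb-based analyses and motion-artifact
  correction are out of scope by design.
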