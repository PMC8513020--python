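# Methods

This note documents the signal model behind the synthetic cohorts, the
segmentation and feature conventions, the evaluation protocol, and the
design decisions taken where the problem left room for choice.

## Synthetic walking-bout model

Each cohort emulates a treadmill fatigue-inducement protocol: every
participant completes `bouts_per_participant` = 5 bouts of
`bout_duration` = 120 s walking — a non-fatigued baseline (bout 0)
followed by four rounds of progressively harder circuit exercise. The
**fatigue stage** equals the bout index (0–4) and scales every configured
effect linearly; the class label comes from the bout's Borg CR10 reading
via the 0–2 / 3–5 / 6–8 / 9–10 banding. The default Borg schedule
(0, 2, 4, 7, 9) maps the five stages to classes Low, Low, Moderate, High,
Very High, which makes Low the largest class and reproduces the mild
class imbalance typical of such protocols (≈ 43 / 20 / 19 / 18 % at the
default geometry). Note the effect ladder is therefore a *stage* ladder:
two bouts sharing the class Low still differ physiologically, as they
would in practice.

### Gait timing

Participant baseline cycle times are drawn N(1.10, 0.08) s, clipped to a
physiological 0.8–1.5 s. Within a bout, cycle durations get i.i.d.
Gaussian jitter with a 3 % coefficient of variation (clipped at ±3 SD);
under fatigue the nominal duration is multiplied by
(1 + `effect_cycle_time` · stage), +5 %/stage by default, so bout 4 walks
~20 % slower than bout 0. Bouts open mid-cycle (a partial lead-in stride)
so the first ground-truth heel strike is preceded by a toe-off and
mid-swing peak, as in a recording that starts while the subject is already
walking; past the final heel strike the gait phase is frozen a quarter
cycle into stance so the tail carries no phantom events.

### Foot sagittal angular velocity

The per-cycle template (gait-phase units, phase 0 = heel strike) is:
stance near zero; a positive half-sine swing lobe from phase 0.45 to 1.0
peaking at 5 rad/s; Gaussian notches of −2.0 rad/s at phase 0.47 (toe-off,
σ = 0.05 cycle) and −3.5 rad/s at phase 1.0 (heel strike, σ = 0.04 cycle).
This preserves the canonical toe-off → mid-swing → heel-strike morphology
with the heel strike as the *second* of the two minima of each cycle, and
— unlike a sum of narrow pulses, whose harmonics are nearly flat — puts
the dominant spectral line at the stride frequency (fundamental-to-second
-harmonic ratio ≈ 1.5), as real foot gyro traces do. The notch widths are
a compromise: wide enough to survive the 6 Hz low-pass with little
attenuation, narrow enough that the swing lobe's slope does not bias the
filtered trough location (the residual bias is ≈ 1 sample at 128 Hz).

### Other channels

* **Foot accelerometer**: gravity on the vertical axis plus a push-off
  bump per cycle and a decaying 15 Hz oscillation at each heel strike
  (the impact shock wave); both amplitudes scale with
  (1 + `effect_foot_accel` · stage). The sign of the effect is
  configurable because fatigue has two opposing reported signatures —
  reduced shock attenuation raises impact amplitude while slower walking
  lowers peak acceleration — and the generator does not adjudicate
  between them.
* **L5-S1 IMU**: smooth sinusoids at step (2/cycle) and stride frequency
  with amplitudes scaled by (1 + `effect_torso` · stage).
* **EMG envelopes** are generated directly as rectified-envelope signals
  (a positive baseline plus one Gaussian activation burst per cycle at a
  muscle-specific phase), not as raw interference EMG, because the
  pipeline only consumes envelope RMS. Per-muscle amplitudes scale with
  (1 + `effect_emg_rms` · stage), −10 %/stage by default.
* **Heart rate** is a stage-dependent plateau (85 + 12·stage bpm) with an
  on-bout exponential rise; it feeds the safety-stop rule only, never the
  feature set. The **lactate surrogate** is a strictly non-decreasing
  per-bout scalar (unit increments plus a small positive random step),
  carried as an auxiliary label column; no quantitative lactate kinetics
  are modelled.

Additive Gaussian noise (defaults: 0.05 m/s² accel, 0.05 rad/s gyro,
0.005 mV EMG, 1 bpm HR) is applied per sample. Determinism: the master
seed spawns per-participant and per-bout child seeds, so identical
(config, seed) give bit-identical cohorts regardless of generation order.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: musculoskeletal dynamics, treadmill-speed
drift, within-bout fatigue accumulation (effects are constant within a
bout), sensor drift/misalignment, EMG crosstalk, missing data, and
morphological variation of the gyro waveform between individuals (only
timing and amplitude vary). Real-data performance must be established on
real recordings; the synthetic cohorts validate the *machinery* —
segmentation correctness, feature definitions, normalization algebra,
evaluation plumbing — not clinical accuracy.

## Preprocessing choices

* **Filter**: order-2 Butterworth low-pass, zero-phase (`sosfiltfilt`), so
  event timing is not lag-shifted; forward–backward application squares
  the magnitude response, hence gain 0.5 (not 1/√2) at the cutoff. The
  cutoff defaults to 6 Hz for IMU channels — gait energy sits below
  ~5 Hz — and is configurable; EMG envelopes and heart rate are not
  filtered.
* **Heel-strike detection**: mid-swing maxima (prominent peaks above 30 %
  of the signal maximum, separated by at least half the running median
  stride) anchor the strides. Stride windows are delimited at *midpoints
  between* consecutive mid-swing peaks — so each window contains, in
  order, toe-off trough, mid-swing peak, heel-strike trough, and the
  second sub-threshold minimum is the heel strike. (Delimiting exactly at
  the peaks would make the heel strike the first minimum; the midpoint
  convention is what makes the "second minimum" rule correct.)
* **Threshold scan**: 25 candidates spanning 10–60 % of the signal's
  negative range; a candidate is viable only if its event count reaches
  90 % of the best count across the scan (a threshold that misses strides
  outright can have a deceptively low interval CV); among viable
  candidates the minimum-CV one wins. Because thresholds are relative to
  the signal range, detection is invariant to uniform scaling.
* **Refractory rule**: events closer than 0.5 × the median stride are
  suppressed (at most one event per stride window can fire, so this is a
  second line of defence).
* **Outlier cycles**: windows deviating more than ±50 % from the bout
  median duration are discarded and logged. Indices are 0-based and
  windows half-open [start, end).
* **Cleaning**: samples outside per-modality physical bounds (±16 g,
  ±35 rad/s, 25–250 bpm, envelope −0.5–10 mV) are replaced by linear
  interpolation and counted in a structured log.

## Feature conventions

Primitive definitions are fixed so tests can be exact: population
variance/std; energy = mean of squared samples (rate-independent);
entropy = Shannon entropy (natural log) of a 16-bin histogram of the
window, with 0·log 0 := 0 and windows whose range is below float
resolution treated as constant (entropy 0); kurtosis = Fisher excess with
biased moments, defined 0 for zero-variance windows; maxfreq = frequency
of the largest FFT magnitude excluding DC; stdfreq = standard deviation
of the DC-excluded normalized power spectral distribution; RMS = root
mean square of envelope samples. Tri-axial IMU channels are collapsed to
the Euclidean magnitude before statistics (one value per statistic per
sensor/modality); EMG windows cover the same time interval on the 512 Hz
clock. The published feature-name spellings are kept verbatim (including
"curtosis", "Kurtosis" and "tibilisAnterior"), and index 9 is the foot
*accelerometer* stdfreq — the foot gyro family has nine statistics, with
no stdfreq.

Baseline normalization divides every feature by the participant's
reference value — the mean over the first ten bout-0 cycles — which
removes between-subject scale: the normalized baseline mean is exactly 1,
re-normalization is the identity, and a per-participant channel gain
cancels for scale-linear features. A zero reference raises an error
naming the feature rather than propagating infinities.

## Evaluation protocol

Holdout splits are stratified by default (stabilizing the two minority
classes; configurable off); 10-fold CV averages fold metrics and sums
confusion matrices. Both macro and pooled (micro) averaging are computed;
macro is the headline because with imbalance pooled metrics collapse to
accuracy (for single-label multiclass, micro precision = micro recall =
accuracy — asserted identically in the tests). Zero-denominator classes
yield metric 0 with a warning. Feature reduction selects top-k columns
*in original index order*, so k = 43 reproduces the full model exactly at
a fixed seed. Splitting is row-wise (not grouped by participant) to match
the simple random-assignment protocol; with real data this leaks
participant identity across the split, and a grouped split should be
preferred for generalization claims. The master seed fans out to
partitioning and model initialization; reports record it.

## Problem sizes

The test suite and acceptance script use three cohort geometries, chosen
to exercise each property at an appropriate scale: the full default
24 × 5 × 120 s cohort (~12 000 heel strikes) for segmentation recovery;
a 12 × 5 × 60 s cohort (~2 800 cycles, the scale of a real treadmill
study dataset) for classification, reduction and ablation; and twenty
6 × 5 × 30 s cohorts for the null-effect calibration, where all effect
sizes are zeroed and random-forest accuracy must stay within the 95 %
binomial interval of the class-prior baseline.

## Known limitations

* Under the default effect ladder the synthetic classes are strongly
  separated and most classifiers saturate at F1 ≈ 1; the ladder is a
  correctness harness, not a difficulty benchmark.
* Borg readings are deterministic per bout (no inter-participant rating
  noise), so label noise robustness is untested.
* The four-class banding assumes integer CR10 readings; half-point
  ratings would need a convention the package does not define.
* `stdfreq`/`maxfreq` depend on window length through FFT bin width;
  cycles of different durations are therefore not strictly comparable in
  those two features (mitigated by baseline normalization).
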