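# Methods

## The estimation problem

A reflective PPG sensor measures blood-volume changes in the microvascular
bed.  The pulsatile (AC) waveform morphology co-varies with arterial
pressure, but only relatively: absolute pressure is not identifiable from
the optical signal alone.  The device model implemented here therefore
(1) extracts waveform features per 15-s window, (2) maps features to
pressure with a Gaussian-process regressor, and (3) anchors the result to a
single cuff reading taken at enrolment.  Validation follows the cuff-monitor
standard: alternating same-arm reference/test readings, pooled and
per-subject difference statistics, and cumulative-percentage grading.

## Synthetic signal model

The generator is a phantom, not a hemodynamic simulation.  One beat is the
sum of

* a **systolic lobe**: Gaussian with center `t_sys` and width
  `0.40 · t_sys`, so the upstroke begins immediately at the beat onset and
  the onset is a sharp waveform minimum that foot detection can localise;
* a **diastolic lobe**: a smaller Gaussian (reflected wave) after a delay;
* a **late-diastolic run-off**: `0.12 · exp(−t/0.22 s)`, giving the beat its
  quasi-sawtooth decay.  The fixed time constant keeps the run-off area
  essentially independent of beat length, so heart rate does not leak into
  the area features.

Beats are tiled at the heart period and ride on a DC baseline (constant
tissue offset ≈ 10× the AC amplitude plus a respiration sinusoid at the
subject's respiratory rate, amplitude 0.5× AC).  For beats shorter than
0.8 s the morphology is compressed proportionally.

### BP → morphology map

| parameter | value at (120, 80) mmHg | dependence |
|---|---|---|
| systolic time `t_sys` | 0.17 s | −0.8 ms per mmHg SBP |
| systolic width | 0.40 · t_sys | decreases with SBP |
| diastolic/systolic amplitude ratio | 0.25 | × e^(0.03·ΔDBP), strictly increasing |
| diastolic delay | 0.26 s | +0.5 ms per mmHg DBP |
| diastolic width | 0.070 s | +0.5 ms per mmHg DBP |

The map is deterministic and injective on the supported range (SBP 60–200,
DBP 40–120 mmHg): SBP is recoverable from systolic timing/width, DBP from
the diastolic amplitude ratio.  The documented monotonicities (systolic time
falls with SBP; diastolic-to-systolic area ratio rises with DBP) are tested.
The quantitative slopes are a modelling assumption chosen to make recovery
tests meaningful — no claim is made that a real artery obeys them.

### Quality tiers

Human-rater quality levels are operationalised as white-noise SNR relative
to the AC rms: excellent 30 dB, good 15 dB, fair 5 dB; the fair tier adds
Poisson-timed baseline steps (≈0.1/s, 0.5–2× AC amplitude) emulating
micromotion.  A synthetic-only `noiseless` tier (SNR ∞) serves as the oracle
in tests.  Skin phototype enters as an AC amplitude scale (tier II 1.0,
tier III 0.85).

## Signal conditioning

DC is a zero-phase 4th-order Butterworth low-pass at 0.5 Hz; AC is defined
as the residual, so AC + DC reconstructs the input exactly.  A 4th-order
filter (rather than 2nd) is used because the shallower roll-off let the
cardiac fundamental leak into the DC estimate, which showed up as a
heart-rate confound worth ≈14 mmHg-equivalent in the area-ratio features;
at 4th order the leak is negligible while ≥99% of respiration still lands
in DC.

Feet are detected as prominent minima (≥5% of signal range) preceding
upstrokes whose smoothed slope exceeds 40% of the 95th-percentile positive
slope, refined by an argmin on the raw trace plus a forward walk down any
near-flat diastolic tail.  Beats outside [60/180, 60/40] s are discarded;
a trailing partial beat never forms a pulse.  The first foot of a recording
sits in the DC-filter warm-up transient and is localised less precisely —
tests therefore check interior feet (±3 samples of the generator's onset
log).

The systolic peak is the post-foot global maximum; the diastolic peak is the
most prominent later local maximum with prominence ≥5% of pulse amplitude.
Pulse SNR is estimated as smoothed-waveform power (10 Hz zero-phase
low-pass) over high-frequency residual power.  Grading: excellent = both
peaks and SNR ≥ 12 dB; good = systolic peak with SNR ≥ 6 dB; fair
otherwise.  The thresholds are an operational surrogate for human raters
and are configurable.

## Features

Per-pulse quantities are computed after subtracting the foot-to-end chord
(linear drift removal — subtracting only the foot value leaves a
beat-length-dependent negative tail that contaminates the diastolic area).
The systolic region runs foot → systolic peak, the diastolic region
systolic peak → beat end (the dicrotic notch is not used as the split
because it is undetectable in fair pulses; the peak split keeps the
area-partition invariant exact).  Areas are trapezoidal; the window value of
each feature is the **median** across the window's pulses (robust to
residual artifact beats); the peak-to-peak interval is the mean of
successive systolic-peak spacings.  Windows are non-overlapping, aligned to
the record start, `floor(duration/15)` per record; a window needs ≥2 usable
pulses.

Eight features are the classical pulse-contour set (areas over total and
over amplitude, maximal amplitude over time, systolic/diastolic times, mean
peak-to-peak interval).  The ninth and tenth — pulse amplitude and width at
half amplitude — are standard additions chosen because they are independent
of the named eight; the half-amplitude width is computed with linear
interpolation at the crossings and turns out to be the cleanest systolic
carrier in the phantom (its continuous value is immune to the 1/256-s
quantisation that limits the systolic-time feature).

## Regression

Covariance k(x, x′) = S² exp(−d/ℓ), d the Euclidean distance between
feature rows standardised by training-set column mean/SD (the features mix
seconds, ratios and amplitudes; the constants are stored in the model).
Per-target models (one SBP, one DBP); prior mean = training-response mean;
jitter 10⁻⁸·S² on the kernel diagonal; prediction via Cholesky solves, with
the noise variance included in the predictive SD so that far from training
data the posterior reverts to (mean, √(S² + noise²)).

Initialisation: the kernel-scale search interval is [0.001, 1]×XMaxRange
(largest per-feature range) and S starts from the pooled standard deviation
of all matrix entries, √(Σ|Xᵢ−μ|²/(N−1)).  The pooled (axis-free) reading of
μ is used, and the root is taken so the quantity is a standard deviation as
named.  With `fix_kernel` the kernel scale and signal SD are held exactly at
the supplied values — the shipped pretrained configuration uses 11.9 and 9.6
— and only the noise SD is estimated, a one-dimensional
marginal-likelihood search (the model records which hyperparameters the
optimiser touched, and tests assert fine-tuning searches the noise only).
Fine-tuning re-estimates the noise rather than freezing it; with a frozen
kernel this is the only quantity the new data can inform.

## Calibration

The anchor is an additive per-target offset: cuff reading minus model
prediction at the calibration features.  This is the minimal mechanism
consistent with the premise that PPG features estimate only BP changes; the
estimate at the calibration operating point equals the cuff reading exactly,
and shifting all training responses by a constant provably cancels out of
calibrated estimates.  One calibration record is retained (most recent
wins).  A physiologically impossible estimate (SBP ≤ DBP) is flagged, never
silently corrected.  The session workflow is an eight-state deterministic
machine (default → ready → measured → transferred → calibrating →
awaiting-ack → calibrated, plus an aborted sink); out-of-order events abort
with a diagnostic and a duplicate acknowledgement is idempotent.

## Simulated study conditions

The pipeline's defaults define the study: 30 subjects, SBP ~ N(111, 12²)
and DBP ~ N(67, 10²) mmHg clipped to a ≥25 mmHg pulse pressure (matching a
typical validation cohort's weekly statistics), resting heart rates 55–90
bpm, respiration 12–18 breaths/min, skin tiers II/III at 53/47%.  Training
databases draw 100 (pretrain) and 30 (fine-tune) profiles from a slightly
wider distribution, one 31-s recording (two windows) each — profile
diversity matters more than windows per profile, because each profile
contributes fresh nuisance covariates for the regressor to learn to ignore.
Test-device acquisitions are 16-s excellent-quality recordings (the device
asks the user to re-measure when signal quality is poor, so the estimator
operates on accepted signals); reference observers read the slot truth with
2 mmHg SD noise; true BP jitters 1.5 mmHg between slots and drifts 2 mmHg
SD week to week.  A single `SeedSequence` tree derives every random stream,
so a run is reproducible from one integer.

These sizes keep the complete study (training, 480 device acquisitions,
pairing, reports) around a few seconds while leaving ~90 pairs per week for
stable statistics.

## What passing tests do and do not show

The synthetic generator guarantees that BP information is present in the
waveform by construction, with stationary morphology, white noise, and a
single artifact type.  Passing the recovery and ISO-criteria tests therefore
demonstrates that the *pipeline* — segmentation, features, GP,
calibration, statistics — is implemented correctly and is internally
consistent, not that the method achieves any particular accuracy on human
subjects.  Real PPG adds pulse-shape variability, motion artifact classes,
sensor-contact drift, and physiological confounds (arrhythmia, vasomotion)
that the phantom deliberately omits.

## Numerical choices and degenerate inputs

* Indices are 0-based; beat intervals are foot-inclusive, next-foot-exclusive.
* AC/DC reconstruction is exact by definition (residual decomposition).
* Records shorter than 2 s are rejected (filter warm-up); empty beat lists
  are a valid result, an empty feature matrix is an error.
* ISO threshold comparisons are inclusive at the boundary; criterion-2
  bounds are the fixed 6.89/6.84 mmHg values, not recomputed from the
  standard's population formula.
* BHS grading requires all three cumulative percentages to meet a grade's
  thresholds (classic whole-row rule).
* Criterion 2 is undefined for a single-subject cohort; the weekly report
  records it as NaN and fails the flag rather than raising.
* CSV writers use 17-significant-digit formatting and readers use
  round-trip float parsing, so file round-trips are bit-exact.

## Known limitations

* The BP→morphology slopes are assumptions; absolute accuracy numbers from
  the simulation characterise the pipeline under those assumptions only.
* Quality grading is algorithmic; no attempt is made to model human-rater
  disagreement.
* The GP is dense (O(N³) fit); training sets beyond a few thousand windows
  would need approximations that are out of scope.
* Foot detection assumes a pronounced onset; waveforms with very flat feet
  (severe vasoconstriction) would degrade systolic-time features first.
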