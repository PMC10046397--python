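# ppgbp — cuffless blood-pressure estimation from upper-arm PPG

`ppgbp` implements the full signal-to-statistics chain of an upper-arm,
cuffless photoplethysmographic (PPG) blood-pressure monitor, for researchers
and engineers who want to study or reproduce this class of device without
hardware or clinical data:

1. **Synthetic PPG** (`ppgbp.synth`) — 256 Hz reflective-PPG traces built
   from a two-Gaussian beat phantom with a deterministic, injective map from
   ground-truth (SBP, DBP) to beat morphology, a respiration/tissue DC
   baseline, and three noise tiers (excellent 30 dB, good 15 dB, fair 5 dB).
2. **Signal conditioning** (`ppgbp.signal`) — zero-phase AC/DC decomposition,
   foot-to-foot beat segmentation, systolic/diastolic peak detection, and
   fair/good/excellent pulse-quality grading.
3. **Features** (`ppgbp.features`) — the 10-dimensional waveform feature
   vector per 15-s window: systolic/diastolic areas over total area and over
   pulse amplitude, maximal amplitude over time (upstroke-slope proxy),
   systolic and diastolic times, mean peak-to-peak interval, pulse amplitude,
   and pulse width at half amplitude.
4. **Regression** (`ppgbp.gpr`) — Gaussian-process regression with the
   exponential kernel k(x, x′) = S² exp(−‖x − x′‖/ℓ).  The kernel scale ℓ is
   searched in [0.001, 1]×XMaxRange, where XMaxRange = maxⱼ(max Xⱼ − min Xⱼ),
   and the signal standard deviation S is initialised from the pooled spread
   of the feature matrix, S = √(Σᵢ|Xᵢ − μ|²/(N−1)) with μ the mean over all
   entries.  *Fine-tuning* re-fits on new data with ℓ and S frozen at the
   shipped pretrained constants (ℓ = 11.9, S = 9.6), re-estimating only the
   noise level by marginal-likelihood maximisation.
5. **Calibration** (`ppgbp.calibration`) — PPG features track only *changes*
   in BP, so a one-time cuff reading anchors the regressor with an additive
   per-target offset; an eight-state session machine models the device's
   auto-calibration workflow.
6. **Protocol & validation** (`ppgbp.protocol`, `ppgbp.validation`) — the
   ISO 81060-2 same-arm sequential schedule (slots BP1–BP8, calibration in
   week 1 only, ≥60 s between readings), observer-averaged test/reference
   pairing, ISO criteria 1 (|mean| ≤ 5, SD ≤ 8.0 mmHg) and 2 (per-subject SD
   ≤ 6.89/6.84 mmHg for SBP/DBP), BHS cumulative-percentage grading,
   Bland–Altman limits of agreement, and Pearson correlation.
7. **Pipeline** (`ppgbp.pipeline`) — a fully seeded five-week validation
   study on a synthetic cohort: pretrain → fine-tune → week-1 calibration →
   uncalibrated weekly follow-ups → pairing → weekly reports.

## Worked example

```sh
python examples/06_full_validation_study.py
```

runs the complete simulated study (30 subjects, 5 weeks, seed 1) and prints:

```
450 comparison pairs over 5 weeks

 week target  n_pairs  pct_le5  pct_le10  pct_le15  mean_diff  sd_diff  per_subject_sd bhs_grade  iso1_pass  iso2_pass  pearson_r
    1    SBP       90    82.22     98.89    100.00      -0.12     3.80            3.26         A       True       True       0.95
    1    DBP       90    83.33     97.78    100.00       0.21     3.93            2.48         A       True       True       0.89
    ...
    5    SBP       90    72.22     98.89    100.00      -0.86     4.56            4.08         A       True       True       0.93
    5    DBP       90    80.00     95.56    100.00       0.30     4.39            3.30         A       True       True       0.82
```

Each row is one week × pressure target over the 90 weekly test-vs-reference
pairs: the cumulative percentages of absolute differences within 5/10/15
mmHg (the BHS columns), the pooled mean ± SD of the differences (criterion
1), the SD of per-subject mean differences (criterion 2), the resulting BHS
grade and ISO pass flags, and the test/reference Pearson correlation.  On
this controlled synthetic cohort the estimator stays within both ISO bounds
through four uncalibrated follow-up weeks — the property the one-time
calibration design is meant to deliver.

The other `examples/` scripts exercise one capability each (synthesis,
segmentation/grading, feature extraction + GP training, calibration,
protocol pairing).  A thin CLI mirrors the pipeline stages:

```sh
ppgbp synth --sbp 120 --dbp 80 --duration 60 --seed 1 --out rec.csv
ppgbp segment --in rec.csv --out pulses.json
ppgbp extract --in rec.csv --out features.csv
ppgbp train --features features.csv --target SBP --out model.json
ppgbp run --seed 1 --out study/
```

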