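"""Run the complete simulated one-time-calibration validation study.

Thirty synthetic subjects, a week-1 cuff calibration, and four uncalibrated
weekly follow-ups; prints the weekly ISO 81060-2 / BHS summary table the
validation module assembles (the library-level equivalent of
`ppgbp run --out <dir>` on the command line).
"""

from ppgbp import RunConfig
from ppgbp.pipeline import run_pipeline
from ppgbp.validation import report_table

result = run_pipeline(RunConfig(seed=1))
print(f"{len(result.pairs)} comparison pairs over 5 weeks\n")
print(report_table(result.reports).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# iso1_pass: pooled mean/SD of test-reference differences within +/-5 / 8 mmHg.
# iso2_pass: SD of per-subject mean differences within 6.89 (SBP) / 6.84 (DBP).
# BHS grade A requires 60/85/95% of |differences| within 5/10/15 mmHg.
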