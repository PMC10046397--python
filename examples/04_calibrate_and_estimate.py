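"""Anchor the regressor to a cuff reading, then estimate absolute BP.

PPG features only track BP changes, so a one-time cuff calibration supplies
the absolute level: the estimate at the calibration features equals the cuff
reading exactly, and later estimates carry the same per-target offset.
"""

import numpy as np

from ppgbp import KernelParams, calibrate, estimate_bp, fit
from ppgbp.features import FeatureVector
from ppgbp.pipeline import make_training_data

root = np.random.SeedSequence(4)
ss_train, ss_subject = root.spawn(2)
train = make_training_data(100, ss_train)
init = KernelParams(11.9, 9.6, 1.0)
sbp_model = fit(train, train.sbp, init=init, fix_kernel=True, target="SBP")
dbp_model = fit(train, train.dbp, init=init, fix_kernel=True, target="DBP")

subject = make_training_data(1, ss_subject)  # two 15-s windows of one subject
cal_fv, later_fv = FeatureVector(*subject.X[0]), FeatureVector(*subject.X[1])
cuff = (128.0, 84.0)

est = calibrate(sbp_model, dbp_model, cuff, cal_fv)
at_cal = estimate_bp(est, cal_fv)
later = estimate_bp(est, later_fv)
print(f"cuff reading            : {cuff[0]:.1f}/{cuff[1]:.1f} mmHg")
print(f"offsets (SBP, DBP)      : {est.offsets[0]:+.2f}, {est.offsets[1]:+.2f} mmHg")
print(f"estimate at calibration : {at_cal.sbp:.1f}/{at_cal.dbp:.1f} mmHg (anchors exactly)")
print(f"estimate a window later : {later.sbp:.1f}/{later.dbp:.1f} ± {later.sbp_std:.1f}/{later.dbp_std:.1f} mmHg")
# The second estimate differs from the cuff only through genuine waveform
# change plus measurement noise; its posterior SD quantifies GP uncertainty.
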