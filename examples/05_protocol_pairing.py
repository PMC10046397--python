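"""The same-arm sequential schedule and test/reference pairing rules.

Week 1 runs BP1..BP8 (BP1/BP2 = calibration pair); follow-up weeks run
BP3..BP8.  The average of the two blinded observers at BP3/BP5/BP7 is paired
with the following test reading, three pairs per subject-week.
"""

from ppgbp import BPReading, build_pairs, schedule

for week in (1, 2):
    slots = ", ".join(f"{s.label}({s.device[:3]}{'*' if s.calibration else ''})" for s in schedule(week))
    print(f"week {week}: {slots}")
print("(* = calibration slot, excluded from pairing)\n")

readings = []
for k, slot in enumerate(schedule(1)):
    if slot.device == "reference":
        readings += [
            BPReading("S001", 1, slot.label, "reference", obs, 120.0 + j, 80.0 + j, time=60.0 * k)
            for j, obs in enumerate(("obs1", "obs2"))
        ]
    else:
        readings.append(BPReading("S001", 1, slot.label, "test", "obs1", 118.0, 79.0, time=60.0 * k))

for p in build_pairs(readings):
    print(
        f"{p.reference_slot}->{p.reference_slot[:2]}{int(p.reference_slot[2]) + 1}: "
        f"reference {p.reference_sbp:.1f}/{p.reference_dbp:.1f} (observer mean), "
        f"test {p.test_sbp:.1f}/{p.test_dbp:.1f} mmHg"
    )
# One complete subject-week always yields exactly 3 pairs; 30 subjects -> 90.
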