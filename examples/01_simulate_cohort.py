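"""Simulate a small cohort of chair-BCG sessions with ground-truth BP.

Builds three rest-session subjects and one recovery subject, and prints the
epoch-level reference blood pressures the cuff would have recorded.  In a
recovery session the subject has just exercised to 80 % of the age-predicted
maximum heart rate, so SBP starts elevated and decays toward rest.
"""

from bcgbp import default_config, sample_cohort, simulate_session

cohort = sample_cohort(3, "rest", seed=42)
for i, cfg in enumerate(cohort):
    rec, refs = simulate_session(cfg)
    print(
        f"subject {i}: age {cfg.subject_age:4.1f} y, HR {cfg.resting_hr:4.1f} bpm, "
        f"rest SBP/DBP {cfg.resting_sbp:.1f}/{cfg.resting_dbp:.1f} mmHg, "
        f"{rec.n_samples} samples x 2 channels, {len(refs)} epochs"
    )

print("\nrecovery subject (age 35, delta SBP 35 mmHg, tau 120 s):")
rec, refs = simulate_session(default_config("recovery", subject_age=35.0, seed=7))
for r in refs:
    print(f"  epoch at {r.epoch_start_s:5.1f} s: SBP {r.sbp:6.1f}  DBP {r.dbp:5.1f} mmHg")
print("epoch-mean SBP decays exponentially back toward the resting value.")
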