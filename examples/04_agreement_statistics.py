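"""Agreement statistics: ME/SD, Bland-Altman limits, AAMI verdicts.

Uses synthetic estimate/reference pairs to show how the evaluator reports
device agreement, including the verdict text that names the violated
criterion when a model fails the SD bound.
"""

import numpy as np

from bcgbp import aami_check, bland_altman_table, error_summary

rng = np.random.default_rng(0)
reference = rng.uniform(95, 145, 40)

print("well-calibrated estimator (bias +1, spread 4 mmHg):")
est = reference + rng.normal(1.0, 4.0, 40)
s = error_summary(est, reference, target="sbp", session="rest")
print(f"  n={s.n}  ME {s.me:+.2f}  SD {s.sd:.2f}  "
      f"LoA [{s.ba_loa_low:+.2f}, {s.ba_loa_high:+.2f}] mmHg  "
      f"AAMI {'pass' if s.aami_pass else 'fail'}")

print("noisy estimator (spread 10 mmHg) fails on SD:")
est_bad = reference + rng.normal(0.0, 10.0, 40)
s2 = error_summary(est_bad, reference, target="sbp", session="recovery")
passed, reason = aami_check(s2.me, s2.sd)
print(f"  ME {s2.me:+.2f}  SD {s2.sd:.2f}  -> {reason}")

table, summary = bland_altman_table(est, reference)
inside = ((table["diff_mmhg"] >= summary["loa_low_mmhg"])
          & (table["diff_mmhg"] <= summary["loa_high_mmhg"])).mean()
print(f"Bland-Altman: bias {summary['bias_mmhg']:+.2f} mmHg, "
      f"{inside:.0%} of pairs inside the 1.96 SD limits of agreement")
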