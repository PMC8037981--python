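"""Train the CNN regressor on a small simulated cohort and evaluate it.

A compact version of the full study replica: 12 rest subjects are
simulated and run to phase epochs, split 8:2, and an SBP model is trained
with 10-fold cross-validation (moderate budget; the example runs in about
two minutes on one CPU).  The held-out mean error (ME) and error SD are then
judged against the device-agreement bounds |ME| < 5 mmHg, SD < 8 mmHg.
"""

import numpy as np

from bcgbp import (
    ArchitectureSpec,
    TrainSettings,
    error_summary,
    make_cv_folds,
    predict_bp,
    sample_cohort,
    split_train_test,
    train_model,
)
from bcgbp.workflow import subject_epochs

epochs = []
for i, cfg in enumerate(sample_cohort(12, "rest", seed=1)):
    epochs.extend(subject_epochs(cfg, f"s{i:02d}"))
print(f"{len(epochs)} ten-second phase epochs from 12 subjects")

plan = make_cv_folds(split_train_test(epochs, ratio=0.8, seed=2), k=10)
settings = TrainSettings(target="sbp", batch_size=16, max_epochs=18,
                         early_stop_patience=6, seed=3)
model = train_model(epochs, plan, ArchitectureSpec(), settings)
print("fold validation MSE:", ["%.0f" % v for v in model.fold_history])
print(f"selected fold: {model.selected_fold}")

test_eps = [epochs[i] for i in plan.test]
preds = predict_bp(model, test_eps)
refs = np.array([e.sbp for e in test_eps])
s = error_summary(preds, refs, target="sbp", session="rest")
print(f"held-out ME {s.me:+.2f} mmHg, SD {s.sd:.2f} mmHg on n={s.n} epochs")
print("AAMI verdict:", "pass" if s.aami_pass else "fail",
      "(|ME| < 5 and SD < 8 required; the small cohort and budget give a",
      "weaker fit than the full 30-subject replica)")
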