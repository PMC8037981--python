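"""Agreement statistics between estimated and reference blood pressure.

Errors are estimated minus reference, in mmHg.  The summary reports the
mean error (ME), the sample (n−1) standard deviation of the errors (SD),
Bland–Altman bias with 1.96·SD limits of agreement, and a pass/fail verdict
against the ANSI/AAMI/ISO 2013 device-agreement bounds: |ME| < 5 mmHg and
SD < 8 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ErrorSummary", "error_summary", "aami_check", "bland_altman_table", "bland_altman_plot"]

AAMI_ME_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0
LOA_FACTOR = 1.96


@dataclass(frozen=True)
class ErrorSummary:
    """Agreement summary for one (target, session) evaluation."""

    n: int
    me: float
    sd: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    aami_pass: bool
    target: str
    session: str

    def to_row(self) -> dict:
        return {
            "session": self.session,
            "target": self.target,
            "n": self.n,
            "me_mmhg": self.me,
            "sd_mmhg": self.sd,
            "ba_bias_mmhg": self.ba_bias,
            "ba_loa_low_mmhg": self.ba_loa_low,
            "ba_loa_high_mmhg": self.ba_loa_high,
            "aami_pass": self.aami_pass,
        }


def _differences(estimates: np.ndarray, references: np.ndarray) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must have equal length")
    if est.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    return est - ref


def error_summary(
    estimates: np.ndarray,
    references: np.ndarray,
    target: str = "sbp",
    session: str = "rest",
) -> ErrorSummary:
    """ME, SD, Bland–Altman limits and the AAMI verdict for one evaluation."""
    diff = _differences(estimates, references)
    me = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    passed, _ = aami_check(me, sd)
    return ErrorSummary(
        n=diff.shape[0],
        me=me,
        sd=sd,
        ba_bias=me,
        ba_loa_low=me - LOA_FACTOR * sd,
        ba_loa_high=me + LOA_FACTOR * sd,
        aami_pass=passed,
        target=target,
        session=session,
    )


def aami_check(me: float, sd: float) -> tuple[bool, str]:
    """Verdict against the AAMI bounds; on failure names the violated criterion.

    The mean-error bound is applied to |ME|, the protocol's intent for a
    bias criterion.
    """
    if not (np.isfinite(me) and np.isfinite(sd)):
        raise ValueError("me and sd must be finite")
    failures = []
    if not abs(me) < AAMI_ME_LIMIT:
        failures.append(f"ME: |{me:.3g}| >= {AAMI_ME_LIMIT} mmHg")
    if not sd < AAMI_SD_LIMIT:
        failures.append(f"SD: {sd:.3g} >= {AAMI_SD_LIMIT} mmHg")
    if failures:
        return False, "fail on " + " and ".join(failures)
    return True, "pass"


def bland_altman_table(
    estimates: np.ndarray, references: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Per-pair (mean, difference) rows plus the bias/LoA summary."""
    diff = _differences(estimates, references)
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    table = pd.DataFrame({"mean_mmhg": (est + ref) / 2.0, "diff_mmhg": diff})
    sd = float(np.std(diff, ddof=1))
    bias = float(np.mean(diff))
    summary = {
        "bias_mmhg": bias,
        "loa_low_mmhg": bias - LOA_FACTOR * sd,
        "loa_high_mmhg": bias + LOA_FACTOR * sd,
    }
    return table, summary


def bland_altman_plot(
    estimates: np.ndarray,
    references: np.ndarray,
    path: str | Path,
    title: str = "Bland-Altman",
) -> None:
    """Render the agreement plot (difference vs mean with bias and LoA lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table, summary = bland_altman_table(estimates, references)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["mean_mmhg"], table["diff_mmhg"], s=12, alpha=0.7)
    ax.axhline(summary["bias_mmhg"], color="k", lw=1)
    for key in ("loa_low_mmhg", "loa_high_mmhg"):
        ax.axhline(summary[key], color="r", ls="--", lw=1)
    ax.set_xlabel("mean of estimate and reference (mmHg)")
    ax.set_ylabel("estimate - reference (mmHg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
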