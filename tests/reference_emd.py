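"""Independent reference EMD used only as a test oracle.

A deliberately separate, textbook implementation of one round of empirical
mode decomposition: extrema from ``scipy.signal.argrelmax``/``argrelmin``
(no plateau handling), envelopes as not-a-knot cubic splines anchored at the
signal endpoints (no mirror extension), and a fixed number of sifting
passes (no Cauchy stop).  It shares no code with the package's
implementation; on signals whose components are well separated in frequency
both must converge to the same first IMF.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelmax, argrelmin


def reference_imf1(x: np.ndarray, n_sifts: int = 12) -> np.ndarray:
    """First intrinsic mode function by plain fixed-iteration sifting."""
    h = np.asarray(x, dtype=float).copy()
    grid = np.arange(h.shape[0], dtype=float)
    for _ in range(n_sifts):
        maxi = argrelmax(h)[0]
        mini = argrelmin(h)[0]
        if len(maxi) < 2 or len(mini) < 2:
            break
        up_x = np.concatenate([[0], maxi, [len(h) - 1]])
        up_y = np.concatenate([[h[0]], h[maxi], [h[-1]]])
        lo_x = np.concatenate([[0], mini, [len(h) - 1]])
        lo_y = np.concatenate([[h[0]], h[mini], [h[-1]]])
        mean = (CubicSpline(up_x, up_y)(grid) + CubicSpline(lo_x, lo_y)(grid)) / 2.0
        h = h - mean
    return h
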