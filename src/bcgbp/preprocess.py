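"""Cardiac-band isolation of BCG channels with a Butterworth band-pass.

The pipeline's only preprocessing step: a third-order Butterworth band-pass
(0.5–6 Hz by default) applied identically to both channels.  By default the
filter runs forward–backward (zero phase) so the relative phase between the
two channels — the carrier of the blood-pressure information — is untouched
by group delay; note that zero-phase application squares the magnitude
response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthbcg import RawRecording

__all__ = ["FilterSpec", "bandpass_filter", "butter_bandpass_gain"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: order and corner frequencies for a given rate."""

    fs: float
    order: int = 3
    f_lo: float = 0.5
    f_hi: float = 6.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.f_hi >= self.fs / 2:
            raise ValueError("f_hi must be below the Nyquist frequency")

    @property
    def settle_len(self) -> int:
        """Samples needed for the slowest pass-band component to settle."""
        return int(round(self.fs / self.f_lo))

    def sos(self) -> np.ndarray:
        return sps.butter(
            self.order, [self.f_lo, self.f_hi], btype="bandpass", fs=self.fs, output="sos"
        )


def _filter_channel(x: np.ndarray, spec: FilterSpec, zero_phase: bool) -> np.ndarray:
    pad = 3 * spec.settle_len
    xp = np.pad(x, pad, mode="reflect")
    sos = spec.sos()
    if zero_phase:
        y = sps.sosfiltfilt(sos, xp, padtype=None)
    else:
        y = sps.sosfilt(sos, xp)
    return np.asarray(y[pad : pad + x.shape[0]])


def bandpass_filter(
    record: RawRecording, spec: FilterSpec | None = None, zero_phase: bool = True
) -> RawRecording:
    """Band-pass both channels of a recording.

    Edges are handled by reflect-padding three settling lengths before
    filtering and trimming afterwards, so output length equals input length.

    Raises ``ValueError`` if the spec does not match the recording's rate or
    the recording is shorter than three settling lengths.
    """
    if spec is None:
        spec = FilterSpec(fs=record.fs)
    if spec.fs != record.fs:
        raise ValueError("FilterSpec.fs does not match the recording")
    if record.n_samples <= 3 * spec.settle_len:
        raise ValueError(
            f"record too short to filter: need > {3 * spec.settle_len} samples, "
            f"got {record.n_samples}"
        )
    return replace(
        record,
        ch_back=_filter_channel(record.ch_back, spec, zero_phase),
        ch_seat=_filter_channel(record.ch_seat, spec, zero_phase),
    )


def butter_bandpass_gain(
    f_hz: np.ndarray | float, spec: FilterSpec, zero_phase: bool = True
) -> np.ndarray | float:
    """Closed-form magnitude response of the digital Butterworth band-pass.

    Uses the bilinear-transform frequency mapping of the analog prototype:
    with v = tan(pi f / fs), the prototype frequency is
    Omega(f) = (v^2 - v_lo * v_hi) / (v * (v_hi - v_lo)) and
    |H| = (1 + Omega^(2*order))^(-1/2); forward–backward application squares
    this.  Evaluated without touching the filter coefficients, so it serves
    as an independent check of the implemented filter.
    """
    f = np.asarray(f_hz, dtype=float)
    v = np.tan(np.pi * f / spec.fs)
    v_lo = np.tan(np.pi * spec.f_lo / spec.fs)
    v_hi = np.tan(np.pi * spec.f_hi / spec.fs)
    omega = (v**2 - v_lo * v_hi) / (v * (v_hi - v_lo))
    mag = 1.0 / np.sqrt(1.0 + omega ** (2 * spec.order))
    if zero_phase:
        mag = mag**2
    return mag if mag.ndim else float(mag)
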