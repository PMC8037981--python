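"""Empirical mode decomposition and Hilbert instantaneous phase.

EMD splits a signal into intrinsic mode functions (IMFs) by iteratively
subtracting the mean of the cubic-spline envelopes through its extrema
("sifting"); IMF(1) is the highest-frequency component and, for a band-passed
BCG, carries the heartbeat oscillation.  The instantaneous phase of IMF(1) —
the four-quadrant angle of its analytic signal — is the quantity fed to the
CNN regressor downstream: the premise is that the phase relation between the
two BCG channels encodes the beat transit delay and hence blood pressure.

Decomposition stops when the running residue is monotone-like (fewer than
two interior extrema).  Per-IMF sifting stops on the classic Cauchy
criterion: SD = sum((h_prev - h)^2) / sum(h_prev^2) < 0.2, capped at 100
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

__all__ = [
    "CannotSiftError",
    "SiftSettings",
    "IMFSet",
    "PhaseSeries",
    "find_extrema",
    "spline_envelopes",
    "envelope_mean",
    "sift",
    "emd_decompose",
    "hilbert_phase",
    "instantaneous_frequency",
]


class CannotSiftError(ValueError):
    """Raised when a signal has too few extrema to build spline envelopes."""


@dataclass(frozen=True)
class SiftSettings:
    """Sifting controls; the defaults are the classic Huang settings."""

    sd_threshold: float = 0.2
    max_sift_iters: int = 100
    max_imfs: int = 10
    spline: str = "cubic"
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.spline != "cubic" or self.boundary != "mirror":
            raise ValueError("only cubic splines with mirror boundaries are supported")


@dataclass
class IMFSet:
    """Ordered IMFs (highest frequency first) plus the final residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residue; equals the source signal."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class PhaseSeries:
    """Wrapped instantaneous phase, one value in (-pi, pi] per sample."""

    phase: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)

    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phase)

    def __len__(self) -> int:
        return self.phase.shape[0]


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior maxima and minima indices, with plateau runs collapsed.

    A flat run of equal samples bounded by opposite slopes contributes its
    midpoint index as a single extremum.  Monotone input returns empty sets.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    d = np.sign(np.diff(x))
    nz = np.flatnonzero(d)
    maxima: list[int] = []
    minima: list[int] = []
    for j in range(len(nz) - 1):
        s0, s1 = d[nz[j]], d[nz[j + 1]]
        if s0 == s1:
            continue
        # extremum spans samples nz[j]+1 .. nz[j+1]; plateau midpoint
        idx = (nz[j] + 1 + nz[j + 1]) // 2
        if s0 > 0:
            maxima.append(idx)
        else:
            minima.append(idx)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirrored_knots(
    idx: np.ndarray, val: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by mirroring the two nearest about each end."""
    k = min(2, len(idx))
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    xi = np.concatenate([left_i, idx, right_i]).astype(float)
    vi = np.concatenate([left_v, val, right_v])
    # mirroring can duplicate a knot when an extremum sits on a boundary
    xi, keep = np.unique(xi, return_index=True)
    return xi, vi[keep]


def spline_envelopes(
    signal: np.ndarray, settings: SiftSettings = SiftSettings()
) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower natural-cubic-spline envelopes through the extrema.

    Raises :class:`CannotSiftError` when there are fewer than two maxima or
    two minima, the condition that terminates the decomposition.
    """
    x = np.asarray(signal, dtype=float)
    n = x.shape[0]
    maxima, minima = find_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise CannotSiftError(
            f"need >= 2 maxima and >= 2 minima to sift, got {len(maxima)}/{len(minima)}"
        )
    grid = np.arange(n, dtype=float)
    envelopes = []
    for idx in (maxima, minima):
        xi, vi = _mirrored_knots(idx, x[idx], n)
        envelopes.append(CubicSpline(xi, vi, bc_type="natural")(grid))
    return envelopes[0], envelopes[1]


def envelope_mean(
    signal: np.ndarray, settings: SiftSettings = SiftSettings()
) -> np.ndarray:
    """Pointwise mean of the upper and lower spline envelopes."""
    upper, lower = spline_envelopes(signal, settings)
    return (upper + lower) / 2.0


def sift(signal: np.ndarray, settings: SiftSettings = SiftSettings()) -> np.ndarray:
    """Extract one IMF by repeated envelope-mean subtraction.

    Iterates h <- h - m(h) until the Cauchy SD between successive iterates
    drops below ``sd_threshold`` or ``max_sift_iters`` is reached.  If the
    first envelope cannot be built the :class:`CannotSiftError` propagates;
    if a later iterate loses its extrema, the current iterate is returned.
    """
    h = np.asarray(signal, dtype=float).copy()
    m = envelope_mean(h, settings)  # may raise CannotSiftError
    for _ in range(settings.max_sift_iters):
        h_new = h - m
        denom = float(np.sum(h**2))
        sd = float(np.sum(m**2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < settings.sd_threshold:
            break
        try:
            m = envelope_mean(h, settings)
        except CannotSiftError:
            break
    return h


def emd_decompose(
    signal: np.ndarray, settings: SiftSettings = SiftSettings()
) -> IMFSet:
    """Full decomposition: sift IMFs off the residue until it is monotone-like.

    Completeness (sum of IMFs + residue == input) is algebraically exact up
    to floating-point roundoff because each IMF is subtracted from the
    running residue.  Degenerate input (monotone, too short to oscillate)
    yields zero IMFs with residue equal to the input.
    """
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < settings.max_imfs:
        maxima, minima = find_extrema(residue)
        if len(maxima) + len(minima) < 2:
            break  # residue is monotone-like: stop
        try:
            imf = sift(residue, settings)
        except CannotSiftError:
            break
        if not np.any(imf):
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue)


def hilbert_phase(imf: np.ndarray, fs: float) -> PhaseSeries:
    """Wrapped instantaneous phase of a component via the analytic signal.

    The analytic signal is built in the frequency domain over the full
    record (no windowing), and the phase is its four-quadrant angle in
    (-pi, pi].  Constant (zero-energy) input is rejected.
    """
    x = np.asarray(imf, dtype=float)
    if x.shape[0] < 2 or np.ptp(x) == 0:
        raise ValueError("instantaneous phase requires a non-constant signal")
    analytic = hilbert(x)
    phase = np.angle(analytic)
    # np.angle maps the negative real axis to +pi, so the range is (-pi, pi]
    return PhaseSeries(phase=phase, fs=fs)


def instantaneous_frequency(phase: PhaseSeries) -> np.ndarray:
    """Per-sample frequency (Hz) from the unwrapped phase derivative.

    Finite differences give one fewer sample than the input.
    """
    if len(phase) < 2:
        raise ValueError("need at least 2 phase samples")
    return np.diff(phase.unwrapped()) * phase.fs / (2.0 * np.pi)
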