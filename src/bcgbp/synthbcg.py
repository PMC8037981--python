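"""Synthetic two-channel chair-BCG generator with paired ground-truth blood pressure.

The study data this package targets — seat/backrest ballistocardiograms with
cuff-reference SBP/DBP — are not publicly deposited, so every downstream
stage (filtering, EMD, phase extraction, CNN regression, agreement
statistics) is exercised on recordings produced here.  The generator is a
*statistical* emulation, not a cardiovascular forward model: each heartbeat
contributes a Gaussian-windowed oscillatory wavelet to both channels, and
blood pressure is encoded solely in the inter-channel beat transit delay
(higher SBP -> shorter delay, the usual pulse-transit-time direction).

Two session types are supported, mirroring the experimental protocol of the
method this package implements:

* ``rest`` — constant heart rate and BP; five contiguous 10-s epochs by
  default.
* ``recovery`` — the subject has just exercised to 80 % of the age-predicted
  maximum heart rate (220 − age); HR and BP start elevated and decay
  exponentially toward rest; ten 10-s epochs by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "SimConfig",
    "RawRecording",
    "BPReference",
    "beat_times",
    "bcg_wavelet",
    "simulate_session",
    "default_config",
    "sample_cohort",
]

EPOCH_S = 10.0
#: population reference SBP (mmHg) used by the cohort sampler to couple a
#: subject's baseline transit delay to their resting pressure
POP_REF_SBP = 125.0

# analysis band of the downstream band-pass filter; the beat wavelet must
# keep essentially all its energy inside it
BAND_LO_HZ = 0.5
BAND_HI_HZ = 6.0

WAVELET_CENTER_HZ = 2.5
WAVELET_WIDTH_S = 0.15
RESP_BASELINE_AMP = 0.3
RESP_AM_FRAC = 0.03
IBI_JITTER_FRAC = 0.02
MOTION_BURST_S = 0.5
MOTION_BURST_AMP = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session for one subject.

    Units: ages in years, heart rates in beats/min, pressures in mmHg,
    durations in seconds, ``fs`` in Hz, transit quantities in ms (slope in
    ms per mmHg of SBP elevation above rest).
    """

    subject_age: float = 35.0
    resting_hr: float = 70.0
    resting_sbp: float = 112.0
    resting_dbp: float = 72.0
    session: str = "rest"
    duration_s: float = 50.0
    fs: float = 100.0
    recovery_hr_peak_frac: float = 0.8
    recovery_tau_s: float = 120.0
    delta_sbp: float = 0.0
    delta_dbp: float | None = None
    transit_base_ms: float = 30.0
    transit_slope_ms_per_mmhg: float = -0.5
    resp_freq_hz: float = 0.25
    noise_sd: float = 0.05
    motion_burst_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session not in ("rest", "recovery"):
            raise ValueError(f"unknown session {self.session!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 < self.recovery_hr_peak_frac <= 1:
            raise ValueError("recovery_hr_peak_frac must be in (0, 1]")
        if not self.resting_sbp > self.resting_dbp > 0:
            raise ValueError("need resting_sbp > resting_dbp > 0")
        if self.transit_base_ms <= 0:
            raise ValueError("transit_base_ms must be positive")
        if self.resting_hr <= 0:
            raise ValueError("resting_hr must be positive")

    @property
    def delta_dbp_effective(self) -> float:
        """DBP elevation at recovery start; defaults to a third of the SBP one."""
        return self.delta_sbp / 3.0 if self.delta_dbp is None else self.delta_dbp

    @property
    def max_hr(self) -> float:
        """Age-predicted maximum heart rate, the 220 − age rule."""
        return 220.0 - self.subject_age

    def hr_trajectory(self) -> Callable[[np.ndarray], np.ndarray]:
        """Heart rate (beats/min) as a function of session time (s)."""
        if self.session == "rest":
            hr0 = self.resting_hr
            return lambda t: np.full_like(np.asarray(t, dtype=float), hr0)
        peak = self.recovery_hr_peak_frac * self.max_hr
        rise = peak - self.resting_hr
        return lambda t: self.resting_hr + rise * np.exp(
            -np.asarray(t, dtype=float) / self.recovery_tau_s
        )

    def sbp_trajectory(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.session == "rest":
            return lambda t: np.full_like(np.asarray(t, dtype=float), self.resting_sbp)
        return lambda t: self.resting_sbp + self.delta_sbp * np.exp(
            -np.asarray(t, dtype=float) / self.recovery_tau_s
        )

    def dbp_trajectory(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.session == "rest":
            return lambda t: np.full_like(np.asarray(t, dtype=float), self.resting_dbp)
        d = self.delta_dbp_effective
        return lambda t: self.resting_dbp + d * np.exp(
            -np.asarray(t, dtype=float) / self.recovery_tau_s
        )

    def transit_delay_s(self, sbp: np.ndarray) -> np.ndarray:
        """Inter-channel beat delay (s) for a given SBP (mmHg)."""
        ms = self.transit_base_ms + self.transit_slope_ms_per_mmhg * (
            np.asarray(sbp, dtype=float) - self.resting_sbp
        )
        return ms / 1000.0


@dataclass
class RawRecording:
    """Two simultaneously sampled BCG channels (backrest and seat)."""

    ch_back: np.ndarray
    ch_seat: np.ndarray
    fs: float
    session: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ch_back = np.asarray(self.ch_back, dtype=float)
        self.ch_seat = np.asarray(self.ch_seat, dtype=float)
        if self.ch_back.shape != self.ch_seat.shape:
            raise ValueError("channels must have the same length")

    @property
    def n_samples(self) -> int:
        return self.ch_back.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class BPReference:
    """Cuff-style reference measurement attached to one 10-s epoch."""

    epoch_start_s: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp:
            raise ValueError("sbp must exceed dbp")


def beat_times(
    hr_trajectory: Callable[[np.ndarray], np.ndarray],
    duration_s: float,
    seed: int | np.random.Generator = 0,
    jitter_frac: float = 0.0,
) -> np.ndarray:
    """Place beat onsets for a time-varying heart rate.

    Integrate-to-threshold placement: the cumulative beat count
    ``\\int hr(t)/60 dt`` is tracked and a beat fires each time it crosses the
    next threshold; thresholds are 1 beat apart plus optional Gaussian jitter
    (``jitter_frac`` of one inter-beat interval).  The first beat is at t = 0.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1e-3
    grid = np.arange(0.0, duration_s + dt, dt)
    rate = np.asarray(hr_trajectory(grid), dtype=float) / 60.0
    if np.any(rate <= 0):
        raise ValueError("heart rate must stay positive over the session")
    cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * np.diff(grid))])
    n_expect = int(np.ceil(cum[-1])) + 10
    incr = 1.0 + jitter_frac * rng.standard_normal(n_expect)
    incr = np.clip(incr, 0.5, 1.5)  # keep intervals physiological
    levels = np.concatenate([[0.0], np.cumsum(incr)])
    levels = levels[levels <= cum[-1]]
    times = np.interp(levels, cum, grid)
    return times[times < duration_s]


def _wavelet_eval(t: np.ndarray, center_freq_hz: float, width_s: float) -> np.ndarray:
    """Continuous-time beat wavelet: Gaussian-windowed cosine, unit peak at t=0."""
    t = np.asarray(t, dtype=float)
    return np.exp(-(t**2) / (2.0 * width_s**2)) * np.cos(2.0 * np.pi * center_freq_hz * t)


def bcg_wavelet(
    fs: float,
    center_freq_hz: float = WAVELET_CENTER_HZ,
    width_s: float = WAVELET_WIDTH_S,
) -> np.ndarray:
    """Sampled beat wavelet template (the simulator's I-J-K complex stand-in).

    A Gaussian-windowed cosine whose spectrum sits inside the 0.5–6 Hz
    analysis band.  Support is truncated at ±4 Gaussian widths; peak
    amplitude is 1 at the centre sample.
    """
    if not BAND_LO_HZ <= center_freq_hz <= BAND_HI_HZ:
        raise ValueError(
            f"center_freq_hz must lie in the {BAND_LO_HZ}-{BAND_HI_HZ} Hz analysis band"
        )
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    half = int(np.ceil(4.0 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    return _wavelet_eval(t, center_freq_hz, width_s)


def _motion_bursts(
    n: int, fs: float, rate_per_min: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-timed high-amplitude artifact bursts (0.5 s, Hann-windowed noise)."""
    out = np.zeros(n)
    lam = rate_per_min / 60.0 * duration_s
    n_bursts = rng.poisson(lam)
    burst_len = int(round(MOTION_BURST_S * fs))
    window = np.hanning(burst_len)
    for _ in range(n_bursts):
        start = int(rng.uniform(0, max(n - burst_len, 1)))
        out[start : start + burst_len] += (
            MOTION_BURST_AMP * window * rng.standard_normal(burst_len)
        )
    return out


def simulate_session(config: SimConfig) -> tuple[RawRecording, list[BPReference]]:
    """Simulate one session: two-channel BCG plus per-epoch BP references.

    The seat channel repeats the backrest beat train with each beat shifted
    by the transit delay at that beat's SBP (sub-sample shifts are exact:
    wavelets are evaluated in continuous time).  Each 10-s epoch's reference
    SBP/DBP is the window mean of the underlying trajectory.  Identical
    config (including seed) gives bit-identical output.
    """
    n_epochs = int(config.duration_s // EPOCH_S)
    if n_epochs < 1:
        raise ValueError("duration_s must cover at least one 10-s epoch")
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    ss = np.random.SeedSequence(config.seed)
    rng_beats, rng_noise_back, rng_noise_seat, rng_motion = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    sbp_f = config.sbp_trajectory()
    dbp_f = config.dbp_trajectory()
    beats = beat_times(
        config.hr_trajectory(), config.duration_s, rng_beats, jitter_frac=IBI_JITTER_FRAC
    )
    delays = config.transit_delay_s(sbp_f(beats))
    if np.any(delays <= 0):
        raise ValueError(
            "transit delay would become non-positive over the simulated BP range; "
            "adjust transit_base_ms / transit_slope_ms_per_mmhg / delta_sbp"
        )
    amps = 1.0 + RESP_AM_FRAC * np.sin(2.0 * np.pi * config.resp_freq_hz * beats)

    ch_back = np.zeros(n)
    ch_seat = np.zeros(n)
    half_support = 4.0 * WAVELET_WIDTH_S
    for tb, delay, amp in zip(beats, delays, amps):
        for chan, center in ((ch_back, tb), (ch_seat, tb + delay)):
            i0 = max(int(np.floor((center - half_support) * config.fs)), 0)
            i1 = min(int(np.ceil((center + half_support) * config.fs)) + 1, n)
            if i1 > i0:
                chan[i0:i1] += amp * _wavelet_eval(
                    t[i0:i1] - center, WAVELET_CENTER_HZ, WAVELET_WIDTH_S
                )

    baseline = RESP_BASELINE_AMP * np.sin(2.0 * np.pi * config.resp_freq_hz * t)
    ch_back += baseline
    ch_seat += baseline
    if config.noise_sd > 0:
        ch_back += config.noise_sd * rng_noise_back.standard_normal(n)
        ch_seat += config.noise_sd * rng_noise_seat.standard_normal(n)
    if config.motion_burst_rate > 0:
        ch_back += _motion_bursts(n, config.fs, config.motion_burst_rate, config.duration_s, rng_motion)
        ch_seat += _motion_bursts(n, config.fs, config.motion_burst_rate, config.duration_s, rng_motion)

    refs = []
    for k in range(n_epochs):
        i0 = int(round(k * EPOCH_S * config.fs))
        i1 = int(round((k + 1) * EPOCH_S * config.fs))
        window = t[i0:i1]
        refs.append(
            BPReference(
                epoch_start_s=k * EPOCH_S,
                sbp=float(np.mean(sbp_f(window))),
                dbp=float(np.mean(dbp_f(window))),
            )
        )
    rec = RawRecording(ch_back=ch_back, ch_seat=ch_seat, fs=config.fs, session=config.session)
    return rec, refs


def default_config(session: str, **overrides) -> SimConfig:
    """Session defaults: 5 epochs at rest, 10 in recovery with elevated BP/HR
    decaying over tau = 120 s and motion bursts at 2/min."""
    base: dict = {"session": session}
    if session == "recovery":
        base.update(duration_s=100.0, delta_sbp=35.0, motion_burst_rate=2.0)
    else:
        base.update(duration_s=50.0)
    base.update(overrides)
    return SimConfig(**base)


def sample_cohort(
    n_subjects: int, session: str, seed: int = 0, **overrides
) -> list[SimConfig]:
    """Draw a cohort of per-subject session configs.

    Subject covariates are sampled once per subject: age U(20, 60) years,
    resting HR N(70, 8) bpm, resting SBP N(112, 10) mmHg clipped to
    [95, 140], resting DBP 28 + 0.4*SBP + N(0, 3) mmHg (population
    SBP-DBP correlation about 0.8).  The baseline transit delay is coupled
    to resting SBP through the same slope that governs within-session
    dynamics (base = 30 + slope*(SBP - 125 mmHg)), so the inter-channel
    delay carries blood-pressure information across subjects as well as
    within a recovery session.  Recovery elevation delta_sbp ~ N(35, 8)
    clipped to [20, 45] mmHg.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    configs = []
    for i in range(n_subjects):
        age = float(rng.uniform(20, 60))
        hr = float(np.clip(rng.normal(70, 8), 50, 95))
        sbp = float(np.clip(rng.normal(112, 10), 95, 140))
        dbp = float(np.clip(28 + 0.4 * sbp + rng.normal(0, 3), 55, sbp - 20))
        delta = float(np.clip(rng.normal(35, 8), 20, 45))
        slope = overrides.get("transit_slope_ms_per_mmhg", -0.5)
        subject_seed = int(rng.integers(0, 2**31 - 1))
        kw = dict(overrides)
        kw.setdefault("subject_age", age)
        kw.setdefault("resting_hr", hr)
        kw.setdefault("resting_sbp", sbp)
        kw.setdefault("resting_dbp", dbp)
        kw.setdefault("transit_base_ms", 30.0 + slope * (kw["resting_sbp"] - POP_REF_SBP))
        kw["seed"] = subject_seed  # per-subject stream derived from the cohort seed
        if session == "recovery":
            kw.setdefault("delta_sbp", delta)
        configs.append(default_config(session, **kw))
    return configs
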