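import numpy as np
import pytest

from bcgbp import default_config, simulate_session
from bcgbp.workflow import recording_to_phase


@pytest.fixture(scope="session")
def rest_pipeline():
    """One clean rest subject run through filter + EMD + phase; reused by
    several modules to keep the suite fast."""
    cfg = default_config("rest", seed=11)
    rec, refs = simulate_session(cfg)
    back, seat = recording_to_phase(rec)
    return cfg, rec, refs, back, seat


def two_tone(f_slow=1.0, f_fast=5.0, fs=100.0, n=1000, amp_slow=1.0, amp_fast=1.0,
             phase_slow=0.0, phase_fast=0.0):
    """Two well-separated sinusoids; EMD should peel the fast one off first."""
    t = np.arange(n) / fs
    slow = amp_slow * np.sin(2 * np.pi * f_slow * t + phase_slow)
    fast = amp_fast * np.sin(2 * np.pi * f_fast * t + phase_fast)
    return t, slow, fast, slow + fast


def band_limited_noise(rng, n=1000, fs=100.0, f_lo=0.5, f_hi=10.0, n_tones=12):
    """Random sum of sinusoids inside a band — a smooth oscillatory test signal."""
    t = np.arange(n) / fs
    freqs = rng.uniform(f_lo, f_hi, n_tones)
    amps = rng.uniform(0.2, 1.0, n_tones)
    phases = rng.uniform(0, 2 * np.pi, n_tones)
    return np.sum(
        amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0
    )
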