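"""Run one recording through the signal chain: band-pass, EMD, Hilbert phase.

The 0.5-6 Hz zero-phase Butterworth isolates the cardiac band, empirical
mode decomposition peels off the highest-frequency intrinsic mode function
(IMF 1 = the heartbeat oscillation), and the Hilbert transform turns IMF(1)
into a wrapped instantaneous phase.  The phase difference between the two
channels reflects the beat transit delay, the carrier of BP information.
"""

import numpy as np

from bcgbp import (
    FilterSpec,
    bandpass_filter,
    default_config,
    emd_decompose,
    hilbert_phase,
    instantaneous_frequency,
    simulate_session,
)

rec, refs = simulate_session(default_config("rest", seed=3))
filtered = bandpass_filter(rec, FilterSpec(fs=rec.fs))

imfs_back = emd_decompose(filtered.ch_back)
print(f"back channel: {imfs_back.n} IMFs + residue")
recon_err = np.max(np.abs(imfs_back.reconstruct() - filtered.ch_back))
print(f"reconstruction error (sum of IMFs + residue vs input): {recon_err:.2e}")

phase_back = hilbert_phase(imfs_back.imfs[0], rec.fs)
phase_seat = hilbert_phase(emd_decompose(filtered.ch_seat).imfs[0], rec.fs)
freq = instantaneous_frequency(phase_back)
print(f"IMF(1) median instantaneous frequency: {np.median(freq):.2f} Hz "
      "(inside the 0.5-6 Hz analysis band)")

dphi = np.angle(np.exp(1j * (phase_back.phase - phase_seat.phase)))
print(f"circular-mean inter-channel phase difference: {np.angle(np.mean(np.exp(1j*dphi))):.3f} rad")
print("this phase offset encodes the configured 30 ms transit delay at 100 Hz.")
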