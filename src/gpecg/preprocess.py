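"""Baseline-wander removal.

The denoising model assumes its input is free of baseline wander and
powerline interference, so the standard front end is a 5–80 Hz passband
built from two zero-phase first-order forward-backward lowpass stages:
the 5 Hz lowpass output is the baseline estimate and is *subtracted*
(realizing the highpass), then an 80 Hz lowpass removes high-frequency
content.  Forward-backward application doubles the effective order and
cancels the phase response, so the ECG's landmarks are not delayed.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .records import EcgRecord

__all__ = ["remove_baseline", "notch_powerline"]


def _zero_phase_lowpass(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    b, a = signal.butter(1, fc, btype="low", fs=fs)
    # reflect-pad roughly one filter time constant at each end: zero-phase
    # filtering is edge-sensitive and the default pad is too short at low fc
    padlen = min(x.size - 1, max(3 * int(fs / fc), 12))
    return signal.filtfilt(b, a, x, padlen=padlen)


def remove_baseline(
    record: EcgRecord, fc_low: float = 5.0, fc_high: float = 80.0
) -> EcgRecord:
    """Remove baseline wander, leaving an ``fc_low``–``fc_high`` Hz passband.

    Per lead: subtract the zero-phase first-order lowpass at ``fc_low``
    (the baseline estimate), then apply the zero-phase first-order lowpass
    at ``fc_high``.  Output has the same length as the input and no group
    delay.

    Raises
    ------
    ValueError
        If the cutoffs are not ordered or reach the Nyquist frequency.
    """
    nyq = record.fs / 2
    if not (0 < fc_low < fc_high < nyq):
        raise ValueError(
            f"need 0 < fc_low < fc_high < fs/2, got ({fc_low}, {fc_high}) at fs={record.fs}"
        )
    out = np.empty_like(record.samples)
    for i, x in enumerate(record.samples):
        detrended = x - _zero_phase_lowpass(x, fc_low, record.fs)
        out[i] = _zero_phase_lowpass(detrended, fc_high, record.fs)
    return record.copy_with(out)


def notch_powerline(record: EcgRecord, freq: float = 50.0, q: float = 30.0) -> EcgRecord:
    """Optional zero-phase notch at the powerline frequency (50 or 60 Hz)."""
    if not (0 < freq < record.fs / 2):
        raise ValueError(f"notch frequency {freq} outside (0, fs/2)")
    b, a = signal.iirnotch(freq, q, fs=record.fs)
    out = np.array([signal.filtfilt(b, a, x) for x in record.samples])
    return record.copy_with(out)
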