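"""Zero-phase Butterworth filtering of raw channels.

sEMG is conventionally band-passed 20–450 Hz before envelope/energy
analysis; acceleration and plantar-pressure channels are low-passed at
20 Hz.  Filters are applied forward-backward (``filtfilt``) so detected
segment boundaries are not phase-shifted.
"""

from __future__ import annotations

from scipy import signal as sps

from .signal_io import SignalRecord

__all__ = ["bandpass_filter", "lowpass_filter", "DEFAULT_EMG_BAND", "DEFAULT_ACC_LOWPASS", "DEFAULT_FILTER_ORDER"]

DEFAULT_EMG_BAND = (20.0, 450.0)
DEFAULT_ACC_LOWPASS = 20.0
DEFAULT_FILTER_ORDER = 4


def _check_length(record: SignalRecord, sos) -> None:
    # filtfilt default pad length for sos is 3 * (n_sections * 2 + 1)
    padlen = 3 * (sos.shape[0] * 2 + 1)
    if record.n_samples <= padlen:
        raise ValueError(
            f"record of {record.n_samples} samples is shorter than the filter "
            f"warm-up length ({padlen + 1} samples required)"
        )


def bandpass_filter(
    record: SignalRecord,
    low_hz: float = DEFAULT_EMG_BAND[0],
    high_hz: float = DEFAULT_EMG_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> SignalRecord:
    """Band-pass every channel with a zero-phase Butterworth filter.

    Returns a new record with identical shape, sampling rate, channel
    names and label.
    """
    nyq = record.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high corner {high_hz} Hz must be below the Nyquist rate {nyq} Hz"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=record.fs, output="sos")
    _check_length(record, sos)
    filtered = sps.sosfiltfilt(sos, record.samples, axis=0)
    return SignalRecord(filtered, record.fs, list(record.channel_names), record.label)


def lowpass_filter(
    record: SignalRecord,
    cutoff_hz: float = DEFAULT_ACC_LOWPASS,
    order: int = DEFAULT_FILTER_ORDER,
) -> SignalRecord:
    """Low-pass every channel with a zero-phase Butterworth filter."""
    nyq = record.fs / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq}) Hz"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=record.fs, output="sos")
    _check_length(record, sos)
    filtered = sps.sosfiltfilt(sos, record.samples, axis=0)
    return SignalRecord(filtered, record.fs, list(record.channel_names), record.label)
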