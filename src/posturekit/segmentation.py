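"""Active-segment detection for sEMG by moving-average energy thresholding.

The detection statistic is the squared signal (instantaneous energy)
smoothed by a forward moving-average window of fixed length N.  A motion
onset is declared at the first index where the averaged energy reaches the
threshold T and stays at or above it for a full window of N samples; an
offset is declared symmetrically on a sustained sub-threshold run.  T is a
fixed fraction (2% by default) of the maximum of the averaged-energy
sequence, which makes detection invariant to overall amplitude scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import ActiveSegment, SignalRecord

__all__ = [
    "EnergySequence",
    "SegmenterConfig",
    "instantaneous_energy",
    "moving_average_energy",
    "compute_threshold",
    "detect_active_segments",
    "segment_record",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN = 128
DEFAULT_THRESHOLD_FRACTION = 0.02


@dataclass
class EnergySequence:
    """Nonnegative energy values (squared amplitudes), possibly averaged.

    ``window_len`` records the moving-average window N once smoothing has
    been applied; it stays None for a raw instantaneous-energy sequence.
    """

    values: np.ndarray
    fs: float
    window_len: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("energy sequence must be nonempty")
        if np.any(self.values < 0):
            raise ValueError("energy values must be nonnegative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SegmenterConfig:
    """Tunables of the energy-threshold segmenter.

    window_len
        Moving-average window N in samples.
    threshold_fraction
        Threshold T as a proportion of the maximum averaged energy.
    min_segment_len
        Detected segments shorter than this many samples are discarded.
    merge_gap
        Adjacent segments separated by fewer than this many samples are
        merged into one.
    """

    window_len: int = DEFAULT_WINDOW_LEN
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    min_segment_len: int = field(default=None)  # type: ignore[assignment]
    merge_gap: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.min_segment_len is None:
            self.min_segment_len = self.window_len
        if self.merge_gap is None:
            self.merge_gap = self.window_len // 2
        if self.min_segment_len < 1:
            raise ValueError("min_segment_len must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def instantaneous_energy(x: np.ndarray, fs: float = 1.0) -> EnergySequence:
    """Square a single-channel signal sample-wise."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot compute energy of an empty signal")
    return EnergySequence(x**2, fs)


def moving_average_energy(energy: EnergySequence, n: int) -> EnergySequence:
    """Average energy over a causal-forward window of length ``n``.

    output[i] = mean(E[i : i + n]); the result has len(E) - n + 1 values,
    each anchored at the window's left edge (output index i corresponds to
    raw index i).
    """
    if n < 1:
        raise ValueError("window length must be >= 1")
    if n > len(energy):
        raise ValueError(
            f"window length {n} exceeds sequence length {len(energy)}"
        )
    kernel = np.full(n, 1.0 / n)
    averaged = np.convolve(energy.values, kernel, mode="valid")
    # rounding in the convolution can leave tiny negatives on zero stretches
    np.clip(averaged, 0.0, None, out=averaged)
    return EnergySequence(averaged, energy.fs, window_len=n)


def compute_threshold(ema: EnergySequence, fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    """Threshold T = fraction x max of the averaged-energy sequence."""
    if not (0 < fraction < 1):
        raise ValueError("threshold fraction must lie in (0, 1)")
    peak = float(np.max(ema.values))
    if peak == 0.0:
        warnings.warn(
            "averaged energy is identically zero; threshold is 0 and no "
            "burst can be detected",
            stacklevel=2,
        )
        return 0.0
    return fraction * peak


def _runs(mask: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean mask as (value, start, length) triples."""
    out: list[tuple[bool, int, int]] = []
    start = 0
    for i in range(1, mask.size + 1):
        if i == mask.size or mask[i] != mask[start]:
            out.append((bool(mask[start]), start, i - start))
            start = i
    return out


def detect_active_segments(
    ema: EnergySequence,
    threshold: float,
    cfg: SegmenterConfig,
    n_samples: int | None = None,
) -> list[ActiveSegment]:
    """Declare motion segments from sustained threshold crossings.

    A start is the first index t where the averaged energy is >= T and the
    whole window of ``cfg.window_len`` samples from t onward stays >= T; an
    end requires a sustained sub-threshold run of the same length.  A burst
    still open at the end of the record is closed at the final sample and
    logged.  Indices are reported in raw-signal coordinates (the averaging
    window is anchored at its left edge) and clipped to ``n_samples`` when
    the parent record's length is given.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = cfg.window_len
    values = ema.values
    if threshold == 0.0 and not np.any(values > 0):
        return []  # identically-zero energy: no burst (despite the >= tie rule)
    supra = values >= threshold  # tie EMA == T counts as supra-threshold
    segments: list[tuple[int, int]] = []
    open_start: int | None = None
    for value, start, length in _runs(supra):
        if open_start is None and value and length >= n:
            open_start = start
        elif open_start is not None and not value and length >= n:
            segments.append((open_start, start))
            open_start = None
    unterminated = open_start is not None
    if unterminated:
        segments.append((open_start, values.size))
        logger.info(
            "burst starting at sample %d unterminated at record end; "
            "closed at the final sample",
            open_start,
        )

    # merge near-adjacent segments, then drop the too-short ones
    merged: list[list[int]] = []
    for start, end in segments:
        if merged and start - merged[-1][1] < cfg.merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    limit = n_samples if n_samples is not None else values.size + n - 1
    if unterminated and merged:
        merged[-1][1] = limit  # close the open burst at the record's final sample
    out: list[ActiveSegment] = []
    for start, end in merged:
        end = min(end, limit)
        if end - start >= cfg.min_segment_len:
            out.append(ActiveSegment(start, end))
    return out


def segment_record(
    record: SignalRecord,
    cfg: SegmenterConfig | None = None,
    channel: str | None = None,
) -> list[ActiveSegment]:
    """Energy -> moving average -> threshold -> segments, on one channel.

    ``channel`` defaults to the record's first channel.
    """
    cfg = cfg or SegmenterConfig()
    name = channel if channel is not None else record.channel_names[0]
    x = record.channel(name)
    energy = instantaneous_energy(x, record.fs)
    ema = moving_average_energy(energy, cfg.window_len)
    threshold = compute_threshold(ema, cfg.threshold_fraction)
    segs = detect_active_segments(ema, threshold, cfg, n_samples=record.n_samples)
    return [ActiveSegment(s.start, s.end, channel_scope=name) for s in segs]
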