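"""Core record types and plain-text I/O for multichannel signals and feature tables.

The on-disk signal dialect is a comma-delimited body preceded by a
``#``-prefixed ``key=value`` header carrying the sampling rate (``fs``),
channel names (``channels``) and an optional class ``label``.  Values are
written with full ``repr`` precision so a write/read round-trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SignalRecord",
    "ActiveSegment",
    "LabeledDataset",
    "read_signal",
    "write_signal",
    "read_dataset",
    "write_dataset",
]


class FormatError(ValueError):
    """Raised when a signal or feature file violates the expected dialect."""


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal amplitudes.  sEMG channels are in mV-equivalent arbitrary
        units, acceleration in g, plantar pressure in N-equivalent units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per column.
    label : str, optional
        Class label of the trial (gesture or gait mode), if known.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_samples x n_channels] array")
        n_samples, n_channels = self.samples.shape
        if n_samples < 1 or n_channels < 1:
            raise ValueError("record needs at least 1 sample and 1 channel")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if len(set(self.channel_names)) != n_channels:
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.samples[:, idx]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ActiveSegment:
    """Half-open sample interval [start, end) marking one detected motion burst.

    Indices are 0-based raw-signal sample coordinates of the parent record.
    """

    start: int
    end: int
    channel_scope: str = "all"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self, record: SignalRecord) -> np.ndarray:
        """Extract the segment's samples (all channels) from its parent record."""
        if self.end > record.n_samples:
            raise ValueError(
                f"segment end {self.end} exceeds record length {record.n_samples}"
            )
        return record.samples[self.start : self.end]


@dataclass
class LabeledDataset:
    """Feature matrix with per-row class labels and stable feature names."""

    features: np.ndarray
    labels: list[str]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = [str(l) for l in self.labels]
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        self.feature_names = list(self.feature_names)
        if self.features.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.features.shape[0]} rows but {len(self.labels)} labels"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.features.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_obs(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> list[str]:
        """Sorted unique class labels."""
        return sorted(set(self.labels))

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows)
        return LabeledDataset(
            self.features[rows],
            [self.labels[i] for i in np.atleast_1d(rows)],
            self.feature_names,
        )


# ---------------------------------------------------------------------------
# signal files


def write_signal(record: SignalRecord, path) -> None:
    """Write a SignalRecord in the '#'-header CSV dialect, losslessly."""
    if not isinstance(record, SignalRecord):
        raise TypeError("write_signal expects a SignalRecord")
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        fh.write(f"# channels={','.join(record.channel_names)}\n")
        if record.label is not None:
            fh.write(f"# label={record.label}\n")
        for row in record.samples:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_signal(path) -> SignalRecord:
    """Read a '#'-header CSV signal file written by :func:`write_signal`."""
    fs: float | None = None
    channels: list[str] | None = None
    label: str | None = None
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise FormatError(
                        f"{path}:{lineno}: header line without key=value: {line!r}"
                    )
                key, _, value = body.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "fs":
                    try:
                        fs = float(value)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric fs {value!r}"
                        ) from None
                elif key == "channels":
                    channels = [c.strip() for c in value.split(",")]
                elif key == "label":
                    label = value
                else:
                    raise FormatError(
                        f"{path}:{lineno}: unknown header key {key!r}"
                    )
                continue
            cells = line.split(",")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row has {len(cells)} columns, "
                    f"expected {width}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell in row {line!r}"
                ) from None
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=' header line")
    if channels is None:
        raise FormatError(f"{path}: missing '# channels=' header line")
    if fs <= 0:
        raise ValueError(f"{path}: fs must be positive, got {fs}")
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    return SignalRecord(np.array(rows, dtype=float), fs, channels, label)


# ---------------------------------------------------------------------------
# feature tables


def write_dataset(ds: LabeledDataset, path) -> None:
    """Write a LabeledDataset as plain CSV with a leading "label" column."""
    frame = pd.DataFrame(ds.features, columns=ds.feature_names)
    frame.insert(0, "label", ds.labels)
    frame.to_csv(path, index=False, float_format=None)


def read_dataset(path) -> LabeledDataset:
    """Read a feature table written by :func:`write_dataset`."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: unreadable feature table: {exc}") from exc
    if "label" not in frame.columns:
        raise FormatError(f"{path}: missing required 'label' column")
    labels = frame["label"].astype(str).tolist()
    feats = frame.drop(columns=["label"])
    values = feats.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric feature cell present")
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite feature value present")
    return LabeledDataset(values.astype(float), labels, list(feats.columns))
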