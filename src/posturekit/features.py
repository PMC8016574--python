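"""Feature bank for the sEMG and gait branches.

sEMG branch (per channel, per active segment):
    standard deviation of the amplitude (population divisor N), plus the
    largest singular value of a Hankel trajectory matrix built from each
    subband of a level-3..5 discrete wavelet transform (level+1 subbands:
    a_L, d_L, ..., d_1).

Gait branch (per sliding window):
    per-axis acceleration mean / SD / variance (population divisor),
    the 8 terminal-node energies of a db1 three-level wavelet-packet
    decomposition of each acceleration axis, and the mean forefoot-minus-
    heel plantar-pressure difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.linalg import hankel

from .signal_io import ActiveSegment, SignalRecord

__all__ = [
    "WaveletConfig",
    "FeatureVector",
    "standard_deviation",
    "dwt_subbands",
    "subband_singular_values",
    "emg_feature_vector",
    "wavelet_packet_energy",
    "acc_time_features",
    "pressure_diff_mean",
    "gait_feature_vector",
    "mean_absolute_value",
    "variance",
]

GAIT_FUSION_MODES = ("fusion", "acc_only", "pressure_only")


@dataclass
class WaveletConfig:
    """Wavelet-analysis settings shared by both feature branches.

    basis_emg
        Mother wavelet for the sEMG DWT (db4 default, the common sEMG
        choice).
    level_emg
        DWT depth, 3–5; depth L yields L+1 subbands.
    basis_gait / level_gait
        Wavelet-packet basis and depth for acceleration windows; db1 at
        level 3 gives the 8-node energy spectrum.
    svd_embed_rows
        Row count of the Hankel trajectory matrix embedded from each
        subband before SVD.
    """

    basis_emg: str = "db4"
    level_emg: int = 3
    basis_gait: str = "db1"
    level_gait: int = 3
    svd_embed_rows: int = 10

    def __post_init__(self) -> None:
        if not 3 <= self.level_emg <= 5:
            raise ValueError("level_emg must be in {3, 4, 5}")
        if self.level_gait < 1:
            raise ValueError("level_gait must be >= 1")
        if self.svd_embed_rows < 2:
            raise ValueError("svd_embed_rows must be >= 2")


@dataclass
class FeatureVector:
    """Ordered numeric features with stable names; one classifier input row."""

    values: np.ndarray
    names: list[str]
    source: str  # "emg" | "gait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.names = list(self.names)
        if self.values.size != len(self.names):
            raise ValueError("feature values and names must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")
        if self.source not in ("emg", "gait"):
            raise ValueError("source must be 'emg' or 'gait'")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# scalar time-domain statistics (population divisor N throughout)


def standard_deviation(x: np.ndarray) -> float:
    """Population standard deviation sqrt((1/N) * sum((x_i - mean)^2))."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("standard deviation needs at least 2 samples")
    return float(np.std(x, ddof=0))


def variance(x: np.ndarray) -> float:
    """Population variance (1/N) * sum((x_i - mean)^2)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("variance needs at least 2 samples")
    return float(np.var(x, ddof=0))


def mean_absolute_value(x: np.ndarray) -> float:
    """Mean of |x_i|; optional extra mirroring classic sEMG time features."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("mean absolute value needs at least 1 sample")
    return float(np.mean(np.abs(x)))


# ---------------------------------------------------------------------------
# sEMG branch: DWT subbands + trajectory-matrix singular values


def _pad_pow2(x: np.ndarray, level: int) -> np.ndarray:
    """Zero-pad so every decomposition stage halves the length evenly."""
    block = 2**level
    remainder = x.size % block
    if remainder == 0:
        return x
    return np.concatenate([x, np.zeros(block - remainder)])


def dwt_subbands(x: np.ndarray, basis: str = "db4", level: int = 3) -> list[np.ndarray]:
    """Level-L discrete wavelet transform returning L+1 coefficient vectors.

    Order is [a_L, d_L, ..., d_1] (approximation first, then details from
    coarse to fine), as :func:`pywt.wavedec` delivers them.
    """
    x = np.asarray(x, dtype=float).ravel()
    minimum = 2**level
    if x.size < minimum:
        raise ValueError(
            f"segment of {x.size} samples is too short for a level-{level} "
            f"DWT (minimum {minimum})"
        )
    # zero-pad to a multiple of 2^level: the periodized transform is then
    # orthonormal, so total coefficient energy equals signal energy for
    # orthogonal bases (padding adds no energy)
    coeffs = pywt.wavedec(_pad_pow2(x, level), basis, mode="periodization", level=level)
    assert len(coeffs) == level + 1
    return [np.asarray(c, dtype=float) for c in coeffs]


def _trajectory_matrix(s: np.ndarray, rows: int) -> np.ndarray:
    """Hankel embedding: row r is s[r : r + n - rows + 1]."""
    cols = s.size - rows + 1
    return hankel(s[:rows], s[rows - 1 :])[:, :cols]


def subband_singular_values(
    subbands: list[np.ndarray], embed_rows: int = 10
) -> np.ndarray:
    """Largest singular value of each subband's trajectory matrix.

    Each 1-D coefficient vector is embedded as a Hankel matrix with
    ``embed_rows`` rows; the dominant singular value summarises the
    subband's energy/structure.  With ``embed_rows == 1`` this reduces to
    the Euclidean norm of the subband.
    """
    if embed_rows < 1:
        raise ValueError("embed_rows must be >= 1")
    out = np.empty(len(subbands))
    for i, sub in enumerate(subbands):
        s = np.asarray(sub, dtype=float).ravel()
        if s.size < embed_rows:
            raise ValueError(
                f"subband {i} has {s.size} coefficients, fewer than "
                f"embed_rows={embed_rows}"
            )
        a = _trajectory_matrix(s, embed_rows)
        out[i] = np.linalg.svd(a, compute_uv=False)[0]
    return out


_SUBBAND_TAGS = {
    level: [f"a{level}"] + [f"d{k}" for k in range(level, 0, -1)] for level in (3, 4, 5)
}


def emg_feature_vector(
    record: SignalRecord,
    seg: ActiveSegment,
    cfg: WaveletConfig | None = None,
) -> FeatureVector:
    """[SD, sigma_aL, sigma_dL, ..., sigma_d1] per channel, concatenated."""
    cfg = cfg or WaveletConfig()
    window = seg.slice(record)
    values: list[float] = []
    names: list[str] = []
    tags = _SUBBAND_TAGS[cfg.level_emg]
    for ch, name in enumerate(record.channel_names):
        x = window[:, ch]
        subbands = dwt_subbands(x, cfg.basis_emg, cfg.level_emg)
        sigmas = subband_singular_values(subbands, cfg.svd_embed_rows)
        values.append(standard_deviation(x))
        names.append(f"{name}.sd")
        values.extend(sigmas)
        names.extend(f"{name}.svd.{tag}" for tag in tags)
    return FeatureVector(np.array(values), names, source="emg")


# ---------------------------------------------------------------------------
# gait branch: wavelet-packet energies + time stats + pressure difference


def wavelet_packet_energy(
    x: np.ndarray, basis: str = "db1", level: int = 3
) -> np.ndarray:
    """Energies of the 2^level terminal wavelet-packet nodes.

    E(j) = sum of squared coefficients of node j; nodes are returned in
    natural frequency order, so level 3 yields the 8-element energy
    spectrum from the lowest to the highest subspace.
    """
    x = np.asarray(x, dtype=float).ravel()
    minimum = 2**level
    if x.size < minimum:
        raise ValueError(
            f"window of {x.size} samples is too short for a level-{level} "
            f"wavelet-packet decomposition (minimum {minimum})"
        )
    wp = pywt.WaveletPacket(_pad_pow2(x, level), basis, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    return np.array([float(np.sum(node.data**2)) for node in nodes])


def acc_time_features(window: np.ndarray) -> np.ndarray:
    """Per-axis [mean, SD, variance] of a 3-axis acceleration window (9 values)."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[1] != 3:
        raise ValueError(f"expected a 3-channel acceleration window, got {window.shape[1]} channels")
    if window.shape[0] < 2:
        raise ValueError("window must contain at least 2 samples")
    out = []
    for axis in range(3):
        x = window[:, axis]
        sd = np.std(x, ddof=0)
        out.extend([np.mean(x), sd, sd * sd])
    return np.array(out)


def pressure_diff_mean(forefoot: np.ndarray, heel: np.ndarray) -> float:
    """Mean forefoot-minus-heel pressure; positive when forefoot loading dominates."""
    forefoot = np.asarray(forefoot, dtype=float).ravel()
    heel = np.asarray(heel, dtype=float).ravel()
    if forefoot.size != heel.size:
        raise ValueError(
            f"forefoot ({forefoot.size}) and heel ({heel.size}) windows differ in length"
        )
    if forefoot.size < 1:
        raise ValueError("pressure windows must be nonempty")
    return float(np.mean(forefoot - heel))


_ACC_AXES = ("x", "y", "z")


def gait_feature_vector(
    acc_window: np.ndarray,
    pressure_window: np.ndarray,
    cfg: WaveletConfig | None = None,
    mode: str = "fusion",
) -> FeatureVector:
    """Gait features for one time-aligned window.

    fusion: 9 time-domain + 3x2^level packet energies + 1 pressure
    difference (34 with level 3); acc_only drops the pressure feature;
    pressure_only keeps only the pressure-difference mean.  The fusion
    vector is exactly the concatenation of acc_only and pressure_only.
    """
    cfg = cfg or WaveletConfig()
    if mode not in GAIT_FUSION_MODES:
        raise ValueError(f"mode must be one of {GAIT_FUSION_MODES}, got {mode!r}")
    values: list[float] = []
    names: list[str] = []
    if mode in ("fusion", "acc_only"):
        acc_window = np.atleast_2d(np.asarray(acc_window, dtype=float))
        stats = acc_time_features(acc_window)
        for i, axis in enumerate(_ACC_AXES):
            values.extend(stats[3 * i : 3 * i + 3])
            names.extend([f"acc_{axis}.mean", f"acc_{axis}.sd", f"acc_{axis}.var"])
        for i, axis in enumerate(_ACC_AXES):
            energies = wavelet_packet_energy(
                acc_window[:, i], cfg.basis_gait, cfg.level_gait
            )
            values.extend(energies)
            names.extend(
                f"acc_{axis}.wpe{j}" for j in range(energies.size)
            )
    if mode in ("fusion", "pressure_only"):
        pressure_window = np.atleast_2d(np.asarray(pressure_window, dtype=float))
        if pressure_window.shape[1] != 2:
            raise ValueError("pressure window must have 2 channels (forefoot, heel)")
        values.append(
            pressure_diff_mean(pressure_window[:, 0], pressure_window[:, 1])
        )
        names.append("pressure.diff_mean")
    return FeatureVector(np.array(values), names, source="gait")
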