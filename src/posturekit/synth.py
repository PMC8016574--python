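"""Synthetic sEMG gesture trials and five-mode gait trials with ground truth.

No recordings ship with this package, so end-to-end behaviour is exercised
on generated data whose class structure mirrors the wearable set-up the
toolkit targets:

* sEMG gestures (left_turn / stop / right_turn, two forearm channels):
  band-limited Gaussian noise amplitude-modulated by a smooth burst
  envelope at a random onset.  Per-gesture, per-channel envelope scales
  reproduce the qualitative ordering seen on the biceps channel in real
  steering gestures — left turn strongest, right turn intermediate, stop
  near rest.  This is the standard amplitude-modulated-noise surrogate for
  surface EMG; no motor-unit-level structure is simulated.

* gait modes (walking / waiting / upstairs / downstairs / falling; three
  acceleration axes in g plus forefoot and heel pressure): periodic modes
  are sinusoid-plus-harmonic accelerations at a mode-specific step
  frequency with anti-phase forefoot/heel pressure alternation whose duty
  is shifted forefoot-ward for upstairs and heel-ward for downstairs;
  waiting is a near-static noise floor with slightly heel-biased standing
  pressure; falling is a single high-amplitude transient after which both
  pressure channels drop to zero.  Upstairs and downstairs deliberately
  share similar acceleration dynamics, so their separation must come from
  the pressure channel — the mechanism behind the fusion-beats-single-
  modality comparison.

Every trial is reproducible from (config seed, trial seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import WaveletConfig, emg_feature_vector, gait_feature_vector
from .preprocess import bandpass_filter, lowpass_filter
from .segmentation import SegmenterConfig, segment_record
from .signal_io import ActiveSegment, LabeledDataset, SignalRecord

__all__ = [
    "EmgSynthConfig",
    "GaitSynthConfig",
    "gen_emg_trial",
    "gen_gait_trial",
    "gen_emg_dataset",
    "gen_gait_dataset",
    "gait_windows",
    "GESTURES",
    "GAIT_MODES",
]

GESTURES = ("left_turn", "stop", "right_turn")
GAIT_MODES = ("walking", "waiting", "upstairs", "downstairs", "falling")
EMG_CHANNELS = ("biceps", "extensor")


@dataclass
class EmgSynthConfig:
    """Generator settings for sEMG gesture trials.

    ``burst_amplitude`` maps gesture -> per-channel envelope scale
    (biceps, extensor), in baseline-noise units.  ``contrast`` is a
    separability dial: 1.0 keeps the full class structure, 0.0 collapses
    every gesture onto the geometric-mean amplitude (classes identical).
    """

    fs: float = 1000.0
    gestures: tuple[str, ...] = GESTURES
    burst_amplitude: dict = field(
        default_factory=lambda: {
            "left_turn": (100.0, 85.0),
            "stop": (5.0, 5.0),
            "right_turn": (30.0, 43.0),
        }
    )
    burst_duration: float = 1.0
    trial_duration: float = 3.0
    baseline_noise_sd: float = 0.5
    n_trials_per_gesture: int = 30
    contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.gestures:
            if g not in self.burst_amplitude:
                raise ValueError(f"no burst amplitude configured for gesture {g!r}")
            if any(a <= 0 for a in self.burst_amplitude[g]):
                raise ValueError("burst amplitudes must be positive")
        if not (0 <= self.contrast <= 1):
            raise ValueError("contrast must lie in [0, 1]")
        if self.baseline_noise_sd <= 0:
            raise ValueError("baseline_noise_sd must be positive")

    def effective_amplitude(self, gesture: str, channel_idx: int) -> float:
        """Amplitude after the contrast dial: ref * (amp/ref)^contrast."""
        amps = np.array([self.burst_amplitude[g][channel_idx] for g in self.gestures])
        ref = float(np.exp(np.mean(np.log(amps))))
        amp = self.burst_amplitude[gesture][channel_idx]
        return ref * (amp / ref) ** self.contrast


@dataclass
class GaitSynthConfig:
    """Generator settings for five-mode gait trials.

    ``acc_amplitude`` is per mode per axis (x, y, z) in g;
    ``pressure_duty`` maps mode -> (forefoot weight, heel weight) of the
    anti-phase loading alternation — equal weights give a near-zero mean
    forefoot-minus-heel difference, a forefoot-heavy pair a positive one.
    """

    fs: float = 100.0
    modes: tuple[str, ...] = GAIT_MODES
    step_frequency: dict = field(
        default_factory=lambda: {
            "walking": 2.0,
            "waiting": 0.0,
            "upstairs": 1.6,
            "downstairs": 1.6,  # same cadence: stairs differ in intensity
            # and, decisively, in the forefoot/heel loading pattern
            "falling": 0.0,
        }
    )
    # upstairs/downstairs share the same axis mix and differ only in overall
    # intensity; with per-trial scale jitter their acceleration signatures
    # overlap, so their reliable separation must come from the pressure duty
    acc_amplitude: dict = field(
        default_factory=lambda: {
            "walking": (0.25, 0.15, 0.50),
            "waiting": (0.0, 0.0, 0.0),
            "upstairs": (0.16, 0.20, 0.30),
            "downstairs": (0.205, 0.256, 0.384),
            "falling": (0.0, 0.0, 0.0),
        }
    )
    pressure_duty: dict = field(
        default_factory=lambda: {
            "walking": (1.0, 1.0),
            "waiting": (0.5, 0.5),  # balanced static stance
            "upstairs": (1.4, 0.6),
            "downstairs": (0.6, 1.4),
            "falling": (0.5, 0.5),  # stance until the fall
        }
    )
    pressure_load: float = 10.0
    fall_amplitude: float = 3.0
    amp_jitter_sigma: float = 0.15  # lognormal sigma of per-trial intensity
    step_freq_jitter_sd: float = 0.05  # Hz, per-trial cadence variability
    fall_event_duration: float = 0.5  # s, impact span a "falling" window must cover
    weight_shift_sd: float = 0.011  # stationary sd of stance weight shift (fraction of load)
    weight_shift_tau: float = 2.0  # s, correlation time of the postural sway
    noise_sd: float = 0.008  # g, accelerometer noise floor
    pressure_noise_sd: float = 1.0  # membrane sensors are noisy: ~10% of load
    trial_duration: float = 10.0
    window_duration: float = 2.0
    window_overlap: float = 0.5
    n_trials_per_mode: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.modes:
            for table in (self.step_frequency, self.acc_amplitude, self.pressure_duty):
                if m not in table:
                    raise ValueError(f"mode {m!r} missing from generator tables")
        if not (0 <= self.window_overlap < 1):
            raise ValueError("window_overlap must lie in [0, 1)")
        if self.window_duration > self.trial_duration:
            raise ValueError("window_duration exceeds trial_duration")


# ---------------------------------------------------------------------------
# sEMG trials


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the sEMG band."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / np.std(x, ddof=0)


def gen_emg_trial(
    gesture: str, cfg: EmgSynthConfig, trial_seed: int
) -> tuple[SignalRecord, list[ActiveSegment]]:
    """One two-channel sEMG trial plus its ground-truth burst interval."""
    if gesture not in cfg.gestures:
        raise ValueError(f"unknown gesture {gesture!r}; expected one of {cfg.gestures}")
    margin = 0.2
    if cfg.burst_duration + 2 * margin > cfg.trial_duration:
        raise ValueError(
            f"burst of {cfg.burst_duration} s does not fit a "
            f"{cfg.trial_duration} s trial with {margin} s margins"
        )
    gesture_idx = cfg.gestures.index(gesture)
    rng = np.random.default_rng([cfg.seed, gesture_idx, trial_seed])
    n = int(round(cfg.trial_duration * cfg.fs))
    burst_len = int(round(cfg.burst_duration * cfg.fs))
    onset = int(rng.uniform(margin, cfg.trial_duration - cfg.burst_duration - margin) * cfg.fs)
    envelope = np.zeros(n)
    envelope[onset : onset + burst_len] = sps.windows.tukey(burst_len, alpha=0.25)
    channels = np.empty((n, len(EMG_CHANNELS)))
    for ch in range(len(EMG_CHANNELS)):
        carrier = _bandlimited_noise(rng, n, cfg.fs)
        amp = cfg.effective_amplitude(gesture, ch)
        channels[:, ch] = carrier * (cfg.baseline_noise_sd + amp * envelope)
    record = SignalRecord(channels, cfg.fs, list(EMG_CHANNELS), label=gesture)
    truth = [ActiveSegment(onset, onset + burst_len)]
    return record, truth


# ---------------------------------------------------------------------------
# gait trials


def _weight_shift(rng: np.random.Generator, t: np.ndarray, cfg: GaitSynthConfig) -> np.ndarray:
    """Slow forefoot/heel weight redistribution during quiet standing.

    Modeled as a stationary Ornstein–Uhlenbeck (AR(1)) process with
    correlation time ``weight_shift_tau`` and stationary sd
    ``weight_shift_sd``, the usual first-order model of postural sway.
    """
    n = t.size
    dt = float(t[1] - t[0]) if n > 1 else 1.0
    rho = np.exp(-dt / cfg.weight_shift_tau)
    innov_sd = cfg.weight_shift_sd * np.sqrt(1.0 - rho * rho)
    shift = np.empty(n)
    shift[0] = rng.normal(0.0, cfg.weight_shift_sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        shift[i] = rho * shift[i - 1] + eps[i - 1]
    return shift


def gen_gait_trial(mode: str, cfg: GaitSynthConfig, trial_seed: int) -> SignalRecord:
    """One labeled gait trial: 3 acceleration axes + forefoot/heel pressure."""
    if mode not in cfg.modes:
        raise ValueError(f"unknown gait mode {mode!r}; expected one of {cfg.modes}")
    mode_idx = cfg.modes.index(mode)
    rng = np.random.default_rng([cfg.seed, 100 + mode_idx, trial_seed])
    n = int(round(cfg.trial_duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    acc = rng.normal(0.0, cfg.noise_sd, size=(n, 3))
    fore = np.empty(n)
    heel = np.empty(n)
    w_fore, w_heel = cfg.pressure_duty[mode]
    load = cfg.pressure_load
    step_f = cfg.step_frequency[mode]

    if step_f > 0:  # periodic locomotion
        phase = rng.uniform(0, 2 * np.pi)
        scale = rng.lognormal(0.0, cfg.amp_jitter_sigma)  # trial intensity
        step_f = max(0.2, step_f + rng.normal(0.0, cfg.step_freq_jitter_sd))
        for ax, amp in enumerate(cfg.acc_amplitude[mode]):
            amp = amp * scale
            ax_phase = phase + ax * 2 * np.pi / 3
            acc[:, ax] += amp * np.sin(2 * np.pi * step_f * t + ax_phase)
            acc[:, ax] += 0.3 * amp * np.sin(2 * np.pi * 2 * step_f * t + 2 * ax_phase)
        load = load * scale
        gait_cycle = np.sin(2 * np.pi * step_f * t + phase)
        fore[:] = load * w_fore * np.clip(gait_cycle, 0.0, None)
        heel[:] = load * w_heel * np.clip(-gait_cycle, 0.0, None)
    elif mode == "falling":
        # quiet stance, then one decaying-oscillation impact; pressure
        # drops to zero once the subject is down
        t_fall = rng.uniform(0.5, 0.7) * cfg.trial_duration
        onset = int(t_fall * cfg.fs)
        tau = 0.15  # s, impact decay constant
        rel = t - t_fall
        pulse = np.where(
            rel >= 0,
            cfg.fall_amplitude * np.exp(-rel / tau) * np.sin(2 * np.pi * 5.0 * rel),
            0.0,
        )
        for ax, share in enumerate((0.6, 0.5, 1.0)):
            acc[:, ax] += share * pulse
        standing = np.arange(n) < onset
        shift = _weight_shift(rng, t, cfg)
        fore[:] = np.where(standing, load * (w_fore + shift), 0.0)
        heel[:] = np.where(standing, load * (w_heel - shift), 0.0)
    else:  # waiting: static stance with slow postural sway
        sway_phase = rng.uniform(0, 2 * np.pi)
        sway = 0.01 * np.sin(2 * np.pi * 0.3 * t + sway_phase)
        acc[:, 0] += sway
        shift = _weight_shift(rng, t, cfg)
        fore[:] = load * (w_fore + shift)
        heel[:] = load * (w_heel - shift)

    fore = np.clip(fore + rng.normal(0.0, cfg.pressure_noise_sd, n), 0.0, None)
    heel = np.clip(heel + rng.normal(0.0, cfg.pressure_noise_sd, n), 0.0, None)
    samples = np.column_stack([acc, fore, heel])
    names = ["acc_x", "acc_y", "acc_z", "p_forefoot", "p_heel"]
    return SignalRecord(samples, cfg.fs, names, label=mode)


def gait_windows(record: SignalRecord, cfg: GaitSynthConfig) -> list[tuple[int, int]]:
    """Fixed-length sliding-window intervals [start, end) over a gait trial."""
    win = int(round(cfg.window_duration * record.fs))
    hop = max(1, int(round(win * (1.0 - cfg.window_overlap))))
    return [(s, s + win) for s in range(0, record.n_samples - win + 1, hop)]


def _fall_onset(record: SignalRecord, cfg: GaitSynthConfig) -> int:
    """Locate the fall from the pressure channels going slack."""
    total = record.channel("p_forefoot") + record.channel("p_heel")
    slack = total < 0.25 * cfg.pressure_load
    idx = np.flatnonzero(slack)
    return int(idx[0]) if idx.size else record.n_samples


# ---------------------------------------------------------------------------
# dataset builders


def gen_emg_dataset(
    cfg: EmgSynthConfig,
    seg_cfg: SegmenterConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    trial_indices: dict[str, list[int]] | None = None,
) -> LabeledDataset:
    """Generate, filter, segment and featurize sEMG trials.

    One feature row per detected active segment (detection runs on the
    biceps channel, the most discriminative one).  ``trial_indices`` maps
    gesture -> trial seeds, defaulting to range(n_trials_per_gesture) for
    every gesture; disjoint index sets give trial-level-disjoint datasets.
    """
    seg_cfg = seg_cfg or SegmenterConfig()
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    rows: list[np.ndarray] = []
    labels: list[str] = []
    names: list[str] | None = None
    missed = 0
    for gesture in cfg.gestures:
        indices = (
            trial_indices[gesture]
            if trial_indices is not None
            else range(cfg.n_trials_per_gesture)
        )
        for trial_seed in indices:
            raw, _ = gen_emg_trial(gesture, cfg, trial_seed)
            filtered = bandpass_filter(raw)
            segments = segment_record(filtered, seg_cfg, channel="biceps")
            if not segments:
                missed += 1
                continue
            for seg in segments:
                fv = emg_feature_vector(filtered, seg, wavelet_cfg)
                rows.append(fv.values)
                labels.append(gesture)
                names = fv.names
    if missed:
        warnings.warn(f"{missed} trial(s) produced no detected segment", stacklevel=2)
    if not rows:
        raise ValueError("no active segments detected in any trial")
    return LabeledDataset(np.array(rows), labels, names or [])


def gen_gait_dataset(
    cfg: GaitSynthConfig,
    mode: str = "fusion",
    wavelet_cfg: WaveletConfig | None = None,
    trial_indices: dict[str, list[int]] | None = None,
) -> LabeledDataset:
    """Generate, filter, window and featurize gait trials.

    One feature row per sliding window.  Falling trials only contribute
    windows that overlap the impact event (onset to onset +
    ``fall_event_duration``): pre-fall stance and post-impact lying-still
    windows would mislabel "standing"/"lying" data as "falling".
    """
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    rows: list[np.ndarray] = []
    labels: list[str] = []
    names: list[str] | None = None
    for gait_mode in cfg.modes:
        indices = (
            trial_indices[gait_mode]
            if trial_indices is not None
            else range(cfg.n_trials_per_mode)
        )
        for trial_seed in indices:
            raw = gen_gait_trial(gait_mode, cfg, trial_seed)
            filtered = lowpass_filter(raw)
            event = None
            if gait_mode == "falling":
                onset = _fall_onset(raw, cfg)
                event = (onset, onset + int(cfg.fall_event_duration * cfg.fs))
            for start, end in gait_windows(filtered, cfg):
                if event is not None:
                    overlap = min(end, event[1]) - max(start, event[0])
                    if overlap < (event[1] - event[0]) / 2:
                        continue  # window misses most of the impact
                window = filtered.samples[start:end]
                fv = gait_feature_vector(window[:, :3], window[:, 3:], wavelet_cfg, mode)
                rows.append(fv.values)
                labels.append(gait_mode)
                names = fv.names
    return LabeledDataset(np.array(rows), labels, names or [])
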