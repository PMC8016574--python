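"""End-to-end experiments: gesture identification and gait-mode fusion.

Both experiments share the same skeleton: generate labeled synthetic
trials, split them 70/30 at the *trial* level (every segment or window of
a trial stays on one side, so no within-trial leakage inflates the test
accuracy), extract features, tune (C, gamma) by genetic search on the
training split, and report held-out per-class and overall accuracy with a
confusion matrix.  Everything is reproducible from the configs' seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .features import GAIT_FUSION_MODES, WaveletConfig
from .gasvm import GAConfig, ga_optimize, predict, train_svm
from .segmentation import SegmenterConfig
from .signal_io import LabeledDataset
from .synth import EmgSynthConfig, GaitSynthConfig, gen_emg_dataset, gen_gait_dataset

__all__ = [
    "EvaluationReport",
    "run_emg_experiment",
    "run_gait_experiment",
    "DEFAULT_TRAIN_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_TRAIN_FRACTION = 0.7


@dataclass
class EvaluationReport:
    """Held-out evaluation of one experiment setting."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: dict[str, dict[str, int]]  # true label -> predicted label -> count
    n_obs: int
    best_params: dict[str, float]
    best_cv_fitness: float
    config: dict
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _split_trials(
    n_trials: int, class_names: tuple[str, ...], train_fraction: float, seed: int
) -> tuple[dict[str, list[int]], dict[str, list[int]]]:
    """Per-class random trial split; returns (train, test) index maps."""
    rng = np.random.default_rng([seed, 7])
    train: dict[str, list[int]] = {}
    test: dict[str, list[int]] = {}
    n_train = int(round(train_fraction * n_trials))
    if not (0 < n_train < n_trials):
        raise ValueError(
            f"train fraction {train_fraction} leaves an empty split for "
            f"{n_trials} trials"
        )
    for name in class_names:
        perm = rng.permutation(n_trials)
        train[name] = sorted(int(i) for i in perm[:n_train])
        test[name] = sorted(int(i) for i in perm[n_train:])
    return train, test


def _evaluate(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    ga_cfg: GAConfig,
    config_snapshot: dict,
    seed: int,
) -> EvaluationReport:
    result = ga_optimize(train_ds, ga_cfg)
    logger.info(
        "GA best C=%.4g gamma=%.4g cv fitness=%.4f (%d evaluations)",
        result.best_params.C,
        result.best_params.gamma,
        result.best_fitness,
        result.evaluations,
    )
    model = train_svm(train_ds, result.best_params)
    predicted = predict(model, test_ds.features)
    truth = np.array(test_ds.labels)
    classes = sorted(set(test_ds.labels) | set(train_ds.labels))
    confusion = {t: {p: 0 for p in classes} for t in classes}
    for t, p in zip(truth, predicted):
        confusion[t][p] += 1
    per_class = {
        c: (float(np.mean(predicted[truth == c] == c)) if np.any(truth == c) else float("nan"))
        for c in classes
    }
    overall = float(np.mean(predicted == truth))
    logger.info("held-out accuracy %.4f on %d observations", overall, truth.size)
    return EvaluationReport(
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        confusion=confusion,
        n_obs=int(truth.size),
        best_params={"C": result.best_params.C, "gamma": result.best_params.gamma},
        best_cv_fitness=result.best_fitness,
        config=config_snapshot,
        seed=seed,
    )


def run_emg_experiment(
    synth_cfg: EmgSynthConfig | None = None,
    seg_cfg: SegmenterConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    ga_cfg: GAConfig | None = None,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> EvaluationReport:
    """Three-gesture sEMG identification on synthetic trials.

    generate -> band-pass -> energy-threshold segmentation -> SD +
    wavelet-subband singular values -> GA-tuned RBF-SVM, evaluated on a
    trial-level held-out split.
    """
    synth_cfg = synth_cfg or EmgSynthConfig()
    seg_cfg = seg_cfg or SegmenterConfig()
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    ga_cfg = ga_cfg or GAConfig(seed=synth_cfg.seed)
    train_idx, test_idx = _split_trials(
        synth_cfg.n_trials_per_gesture, synth_cfg.gestures, train_fraction, synth_cfg.seed
    )
    train_ds = gen_emg_dataset(synth_cfg, seg_cfg, wavelet_cfg, train_idx)
    test_ds = gen_emg_dataset(synth_cfg, seg_cfg, wavelet_cfg, test_idx)
    for gesture in synth_cfg.gestures:
        if gesture not in train_ds.labels or gesture not in test_ds.labels:
            raise RuntimeError(f"no segments detected for gesture {gesture!r}")
    logger.info(
        "emg experiment: %d train rows, %d test rows", train_ds.n_obs, test_ds.n_obs
    )
    snapshot = {
        "task": "emg",
        "synth": asdict(synth_cfg),
        "segmenter": asdict(seg_cfg),
        "wavelet": asdict(wavelet_cfg),
        "ga": asdict(ga_cfg),
        "train_fraction": train_fraction,
    }
    return _evaluate(train_ds, test_ds, ga_cfg, snapshot, synth_cfg.seed)


def run_gait_experiment(
    synth_cfg: GaitSynthConfig | None = None,
    wavelet_cfg: WaveletConfig | None = None,
    ga_cfg: GAConfig | None = None,
    modes: tuple[str, ...] = GAIT_FUSION_MODES,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
) -> dict[str, EvaluationReport]:
    """Five-mode gait identification, once per fusion setting.

    All settings (fusion / acc_only / pressure_only) run on the *same*
    generated trials and the same trial split, so the comparison isolates
    the feature set.
    """
    synth_cfg = synth_cfg or GaitSynthConfig()
    wavelet_cfg = wavelet_cfg or WaveletConfig()
    ga_cfg = ga_cfg or GAConfig(seed=synth_cfg.seed)
    train_idx, test_idx = _split_trials(
        synth_cfg.n_trials_per_mode, synth_cfg.modes, train_fraction, synth_cfg.seed
    )
    reports: dict[str, EvaluationReport] = {}
    for setting in modes:
        train_ds = gen_gait_dataset(synth_cfg, setting, wavelet_cfg, train_idx)
        test_ds = gen_gait_dataset(synth_cfg, setting, wavelet_cfg, test_idx)
        logger.info(
            "gait experiment [%s]: %d train rows, %d test rows",
            setting,
            train_ds.n_obs,
            test_ds.n_obs,
        )
        snapshot = {
            "task": "gait",
            "setting": setting,
            "synth": asdict(synth_cfg),
            "wavelet": asdict(wavelet_cfg),
            "ga": asdict(ga_cfg),
            "train_fraction": train_fraction,
        }
        reports[setting] = _evaluate(train_ds, test_ds, ga_cfg, snapshot, synth_cfg.seed)
    return reports
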