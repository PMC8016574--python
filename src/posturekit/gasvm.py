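"""RBF-kernel soft-margin SVM with genetic-algorithm hyperparameter search.

The classifier is the standard soft-margin dual

    min_a  1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j) - sum_i a_i
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C,

with the RBF kernel K(x_i, x) = exp(-gamma * ||x_i - x||^2), and the
decision function f(x) = sgn(sum_i a_i y_i K(x_i, x) + b).  Multiclass
problems are handled one-vs-one with majority voting.  The inner binary
quadratic program is delegated to scikit-learn's SVC (a replaceable
solver); the one-vs-one scheme, dual-feasibility checks, prediction
voting, cross-validated fitness and the genetic search are implemented
here.

The genetic algorithm evolves real-valued chromosomes (log2 C, log2 gamma)
with tournament selection, blend crossover, Gaussian mutation, and a
generation gap of 0.95 — the complementary 5% elite survives unchanged,
which makes the best cross-validated fitness non-decreasing across
generations.  One individual of the initial population is always the
conventional default (C=1, gamma=1/n_features), so the search can never
finish below that baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .signal_io import LabeledDataset

__all__ = [
    "SVMParams",
    "SVMModel",
    "GAConfig",
    "GAResult",
    "rbf_kernel",
    "train_svm",
    "predict",
    "cv_fitness",
    "ga_optimize",
    "save_model",
    "load_model",
]

DUAL_TOL = 1e-6


@dataclass(frozen=True)
class SVMParams:
    """Soft-margin penalty C and RBF width gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("penalty factor C must be > 0")
        if self.gamma <= 0:
            raise ValueError("RBF parameter gamma must be > 0")


@dataclass
class _BinaryMachine:
    """One trained class-pair subproblem (classes in lexicographic order).

    ``dual_coefs`` holds the signed products a_i * y_i with y = -1 for
    ``neg_label`` and +1 for ``pos_label``; ``bias`` is the intercept b.
    A positive decision value votes for ``pos_label``.
    """

    neg_label: str
    pos_label: str
    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    bias: float

    def decision(self, x: np.ndarray, gamma: float) -> np.ndarray:
        d2 = np.sum(
            (x[:, None, :] - self.support_vectors[None, :, :]) ** 2, axis=2
        )
        return np.exp(-gamma * d2) @ self.dual_coefs + self.bias


@dataclass
class SVMModel:
    """Trained one-vs-one multiclass RBF-SVM with its fitted feature scaler."""

    machines: list[_BinaryMachine]
    classes: list[str]
    params: SVMParams
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.scaler_mean.size

    def check_dual_feasibility(self, tol: float = DUAL_TOL) -> None:
        """Verify the box constraint |a_i y_i| <= C and sum a_i y_i = 0 per pair."""
        for m in self.machines:
            if np.any(np.abs(m.dual_coefs) > self.params.C * (1 + tol) + tol):
                raise AssertionError(
                    f"box constraint violated for pair ({m.neg_label}, {m.pos_label})"
                )
            balance = float(np.sum(m.dual_coefs))
            if abs(balance) > tol * max(1.0, self.params.C):
                raise AssertionError(
                    f"equality constraint sum(a_i y_i)={balance:g} for pair "
                    f"({m.neg_label}, {m.pos_label})"
                )


def rbf_kernel(xi: np.ndarray, x: np.ndarray, gamma: float) -> float:
    """K(x_i, x) = exp(-gamma * ||x_i - x||^2); symmetric, in (0, 1]."""
    xi = np.asarray(xi, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if xi.size != x.size:
        raise ValueError(f"vector lengths differ: {xi.size} vs {x.size}")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return float(np.exp(-gamma * np.sum((xi - x) ** 2)))


def _fit_scaler(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = features.mean(axis=0)
    scale = features.std(axis=0, ddof=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return mean, scale


def train_svm(ds: LabeledDataset, params: SVMParams) -> SVMModel:
    """Fit a one-vs-one RBF-SVM on z-scored features.

    The z-score standardization is fitted on ``ds`` and stored with the
    model; each class pair gets its own binary soft-margin machine trained
    on that pair's samples only.
    """
    classes = ds.classes
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if not np.all(np.isfinite(ds.features)):
        raise ValueError("training features contain non-finite values")
    mean, scale = _fit_scaler(ds.features)
    scaled = (ds.features - mean) / scale
    labels = np.array(ds.labels)
    machines: list[_BinaryMachine] = []
    for i, neg in enumerate(classes):
        for pos in classes[i + 1 :]:
            mask = (labels == neg) | (labels == pos)
            x_pair = scaled[mask]
            y_pair = np.where(labels[mask] == pos, 1.0, -1.0)
            svc = SVC(kernel="rbf", C=params.C, gamma=params.gamma)
            svc.fit(x_pair, y_pair)
            machines.append(
                _BinaryMachine(
                    neg_label=neg,
                    pos_label=pos,
                    support_vectors=svc.support_vectors_.copy(),
                    dual_coefs=svc.dual_coef_[0].copy(),
                    bias=float(svc.intercept_[0]),
                )
            )
    model = SVMModel(machines, classes, params, mean, scale, list(ds.feature_names))
    model.check_dual_feasibility()
    return model


def decision_values(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Pairwise decision values, shape (n_obs, n_class_pairs)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match the "
            f"model's training dimension {model.n_features}"
        )
    scaled = (features - model.scaler_mean) / model.scaler_scale
    return np.column_stack(
        [m.decision(scaled, model.params.gamma) for m in model.machines]
    )


def predict(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """One-vs-one majority vote over pairwise sign decisions.

    Ties are broken by the largest aggregate signed margin in favour of a
    class, then lexicographically.  Accepts one vector or a matrix; always
    returns an array of labels.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    dec = decision_values(model, features)
    n_obs = features.shape[0]
    classes = model.classes
    votes = np.zeros((n_obs, len(classes)))
    margins = np.zeros((n_obs, len(classes)))
    index = {c: k for k, c in enumerate(classes)}
    for j, m in enumerate(model.machines):
        pos_wins = dec[:, j] > 0
        votes[pos_wins, index[m.pos_label]] += 1
        votes[~pos_wins, index[m.neg_label]] += 1
        margins[:, index[m.pos_label]] += dec[:, j]
        margins[:, index[m.neg_label]] -= dec[:, j]
    out = np.empty(n_obs, dtype=object)
    for r in range(n_obs):
        best = np.flatnonzero(votes[r] == votes[r].max())
        if best.size > 1:
            top = best[margins[r, best] == margins[r, best].max()]
            best = top  # residual ties fall through to lexicographic order
        out[r] = classes[int(best[0])]
    return out.astype(str)


def accuracy(model: SVMModel, ds: LabeledDataset) -> float:
    """Fraction of correctly predicted rows."""
    return float(np.mean(predict(model, ds.features) == np.array(ds.labels)))


def cv_fitness(
    ds: LabeledDataset, params: SVMParams, folds: int = 5, seed: int = 0
) -> float:
    """Mean held-out accuracy of stratified k-fold cross-validation.

    The feature scaler is refitted inside each training fold (it travels
    with train_svm), so no information leaks from the held-out fold.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    labels = np.array(ds.labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than "
            f"{folds} folds"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in splitter.split(ds.features, labels):
        model = train_svm(ds.subset(train_idx), params)
        scores.append(accuracy(model, ds.subset(test_idx)))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# genetic search over (log2 C, log2 gamma)


@dataclass
class GAConfig:
    """Genetic-algorithm settings for the (C, gamma) search.

    Defaults follow the conventional GA parameterization for SVM tuning:
    population 50, 50 generations, generation gap 0.95 (5% elitism),
    crossover probability 0.8, mutation probability 0.1, fitness scored by
    5-fold cross-validated accuracy.  Search ranges are log2-scaled:
    C in [2^-5, 2^15], gamma in [2^-15, 2^3].
    """

    pop_size: int = 50
    max_gen: int = 50
    generation_gap: float = 0.95
    p_crossover: float = 0.8
    p_mutation: float = 0.1
    C_range: tuple[float, float] = (-5.0, 15.0)
    gamma_range: tuple[float, float] = (-15.0, 3.0)
    cv_folds: int = 5
    seed: int = 0
    tournament_size: int = 3
    blend_alpha: float = 0.5
    mutation_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_gen < 1:
            raise ValueError("max_gen must be >= 1")
        if not (0 < self.generation_gap <= 1):
            raise ValueError("generation_gap must lie in (0, 1]")
        for name, rng in ("C_range", self.C_range), ("gamma_range", self.gamma_range):
            if rng[0] >= rng[1]:
                raise ValueError(f"{name} must be a nonempty (low, high) interval")


@dataclass
class GAResult:
    """Outcome of one genetic search."""

    best_params: SVMParams
    best_fitness: float
    history: list[dict]  # per generation: {"best": float, "mean": float}
    evaluations: int
    fold_seed: int | None = None  # CV fold assignment used for every fitness call


def _clip(chrom: np.ndarray, cfg: GAConfig) -> np.ndarray:
    chrom[0] = min(max(chrom[0], cfg.C_range[0]), cfg.C_range[1])
    chrom[1] = min(max(chrom[1], cfg.gamma_range[0]), cfg.gamma_range[1])
    return chrom


def ga_optimize(
    ds: LabeledDataset | None,
    cfg: GAConfig,
    fitness_fn=None,
) -> GAResult:
    """Evolve (log2 C, log2 gamma) to maximize cross-validated accuracy.

    ``fitness_fn(params: SVMParams) -> float`` may replace the CV fitness
    (e.g. for landscape studies); by default fitness is
    ``cv_fitness(ds, params, cfg.cv_folds, fold_seed)`` with one fold
    assignment fixed for the whole run so candidate fitnesses are
    comparable.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    if fitness_fn is None:
        if ds is None:
            raise ValueError("ga_optimize needs a dataset or an explicit fitness_fn")

        def fitness_fn(params: SVMParams) -> float:
            return cv_fitness(ds, params, cfg.cv_folds, fold_seed)

    n_elite = max(1, cfg.pop_size - int(round(cfg.generation_gap * cfg.pop_size)))

    def chrom_params(chrom: np.ndarray) -> SVMParams:
        return SVMParams(C=2.0 ** chrom[0], gamma=2.0 ** chrom[1])

    # initial population: uniform over the log2 box, with one individual
    # pinned to the conventional default C=1, gamma=1/n_features
    pop = np.column_stack(
        [
            rng.uniform(*cfg.C_range, size=cfg.pop_size),
            rng.uniform(*cfg.gamma_range, size=cfg.pop_size),
        ]
    )
    if ds is not None:
        baseline = np.array([0.0, math.log2(1.0 / ds.n_features)])
        pop[0] = _clip(baseline, cfg)
    evaluations = 0

    def evaluate(population: np.ndarray) -> np.ndarray:
        nonlocal evaluations
        fits = np.empty(population.shape[0])
        for i, chrom in enumerate(population):
            fits[i] = fitness_fn(chrom_params(chrom))
        evaluations += population.shape[0]
        return fits

    fits = evaluate(pop)
    history: list[dict] = []
    for _ in range(cfg.max_gen):
        order = np.argsort(-fits, kind="stable")
        elite = pop[order[:n_elite]].copy()
        elite_fits = fits[order[:n_elite]].copy()
        children = []
        while len(children) < cfg.pop_size - n_elite:
            parents = []
            for _ in range(2):  # tournament selection
                idx = rng.integers(0, cfg.pop_size, size=cfg.tournament_size)
                parents.append(pop[idx[np.argmax(fits[idx])]].copy())
            p1, p2 = parents
            if rng.random() < cfg.p_crossover:  # BLX-alpha blend
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                span = hi - lo
                c1 = rng.uniform(lo - cfg.blend_alpha * span, hi + cfg.blend_alpha * span)
                c2 = rng.uniform(lo - cfg.blend_alpha * span, hi + cfg.blend_alpha * span)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(children) >= cfg.pop_size - n_elite:
                    break
                mutate = rng.random(2) < cfg.p_mutation
                child = child + mutate * rng.normal(0.0, cfg.mutation_sigma, size=2)
                children.append(_clip(child, cfg))
        children = np.array(children)
        child_fits = evaluate(children)
        pop = np.vstack([elite, children])
        fits = np.concatenate([elite_fits, child_fits])
        history.append(
            {"best": float(np.max(fits)), "mean": float(np.mean(fits))}
        )
    best_idx = int(np.argmax(fits))
    return GAResult(
        best_params=chrom_params(pop[best_idx]),
        best_fitness=float(fits[best_idx]),
        history=history,
        evaluations=evaluations,
        fold_seed=fold_seed,
    )


# ---------------------------------------------------------------------------
# model serialization (self-contained JSON)


def save_model(model: SVMModel, path) -> None:
    """Serialize a trained model (scaler, support vectors, coefficients)."""
    payload = {
        "params": {"C": model.params.C, "gamma": model.params.gamma},
        "classes": model.classes,
        "feature_names": model.feature_names,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "machines": [
            {
                "neg_label": m.neg_label,
                "pos_label": m.pos_label,
                "support_vectors": m.support_vectors.tolist(),
                "dual_coefs": m.dual_coefs.tolist(),
                "bias": m.bias,
            }
            for m in model.machines
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SVMModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    machines = [
        _BinaryMachine(
            neg_label=m["neg_label"],
            pos_label=m["pos_label"],
            support_vectors=np.array(m["support_vectors"], dtype=float),
            dual_coefs=np.array(m["dual_coefs"], dtype=float),
            bias=float(m["bias"]),
        )
        for m in payload["machines"]
    ]
    return SVMModel(
        machines=machines,
        classes=list(payload["classes"]),
        params=SVMParams(**payload["params"]),
        scaler_mean=np.array(payload["scaler_mean"], dtype=float),
        scaler_scale=np.array(payload["scaler_scale"], dtype=float),
        feature_names=list(payload["feature_names"]),
    )
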