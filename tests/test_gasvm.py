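import numpy as np
import pytest

from posturekit import (
    GAConfig,
    LabeledDataset,
    SVMParams,
    cv_fitness,
    ga_optimize,
    load_model,
    predict,
    rbf_kernel,
    save_model,
    train_svm,
)
from posturekit.gasvm import DUAL_TOL, accuracy


def make_blobs(rng, centers, n_per_class, spread=0.3, labels=None):
    """Well-separated Gaussian blobs as a LabeledDataset."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    labels = labels or [chr(ord("A") + i) for i in range(len(centers))]
    feats, labs = [], []
    for c, lab in zip(centers, labels):
        feats.append(c + spread * rng.standard_normal((n_per_class, centers.shape[1])))
        labs.extend([lab] * n_per_class)
    return LabeledDataset(np.vstack(feats), labs)


def brute_force_dual(x, y, C, gamma):
    """Independent solve of the soft-margin dual as a generic NLP.

    Minimizes 1/2 a^T Q a - sum(a) with Q = y y^T K under 0 <= a <= C and
    a . y = 0 via SLSQP; shares no code with the trained path.
    """
    from scipy.optimize import minimize

    n = len(y)
    d2 = np.sum((x[:, None] - x[None, :]) ** 2, axis=2)
    k = np.exp(-gamma * d2)
    q = np.outer(y, y) * k

    def objective(a):
        return 0.5 * a @ q @ a - a.sum()

    def gradient(a):
        return q @ a - 1.0

    res = minimize(
        objective,
        np.full(n, C / 2),
        jac=gradient,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    # bias from margin vectors (0 < a < C)
    free = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if not np.any(free):
        free = a > 1e-6 * C
    b = np.mean(y[free] - (a * y) @ k[:, free])
    return a, b

    # decision: f(z) = sum_i a_i y_i K(x_i, z) + b


def brute_force_decision(x, y, a, b, gamma, z):
    k = np.exp(-gamma * np.sum((x - z) ** 2, axis=1))
    return float((a * y) @ k + b)


class TestRbfKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.standard_normal(8)
        assert rbf_kernel(x, x, 0.7) == 1.0

    def test_decay_with_distance(self):
        x = np.zeros(2)
        assert rbf_kernel(x, np.full(2, 100.0), 1.0) < 1e-300 or rbf_kernel(
            x, np.full(2, 100.0), 1.0
        ) == pytest.approx(0.0, abs=1e-100)

    def test_forced_arithmetic(self):
        assert rbf_kernel(np.array([0.0]), np.array([1.0]), 1.0) == pytest.approx(
            np.exp(-1.0)
        )

    def test_symmetry_and_range(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        k = rbf_kernel(a, b, 0.3)
        assert k == rbf_kernel(b, a, 0.3)
        assert 0 < k <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.ones(3), np.ones(4), 1.0)


class TestTrainSvm:
    def test_minimal_two_point_problem(self):
        ds = LabeledDataset(np.array([[0.0], [1.0]]), ["A", "B"])
        model = train_svm(ds, SVMParams(C=1e3, gamma=1.0))
        assert list(predict(model, ds.features)) == ["A", "B"]

    def test_separable_blobs_perfect_training_accuracy(self, rng):
        ds = make_blobs(rng, [[0, 0], [10, 10]], 20)
        model = train_svm(ds, SVMParams(C=10.0, gamma=1.0))
        assert accuracy(model, ds) == 1.0

    def test_dual_feasibility(self, rng):
        ds = make_blobs(rng, [[0, 0], [3, 0], [0, 3]], 15, spread=1.0)
        for C in (0.1, 1.0, 100.0):
            model = train_svm(ds, SVMParams(C=C, gamma=0.5))
            model.check_dual_feasibility(DUAL_TOL)  # raises on violation
            for m in model.machines:
                assert np.all(np.abs(m.dual_coefs) <= C * (1 + 1e-6) + 1e-6)
                assert abs(np.sum(m.dual_coefs)) <= 1e-6 * max(1.0, C)

    def test_duplicated_dataset_same_predictions(self, rng):
        ds = make_blobs(rng, [[0, 0], [4, 4]], 10)
        doubled = LabeledDataset(
            np.vstack([ds.features, ds.features]), ds.labels + ds.labels
        )
        probe = rng.uniform(-1, 5, (30, 2))
        m1 = train_svm(ds, SVMParams(C=5.0, gamma=0.7))
        m2 = train_svm(doubled, SVMParams(C=5.0, gamma=0.7))
        assert list(predict(m1, probe)) == list(predict(m2, probe))

    def test_single_class_rejected(self, rng):
        ds = LabeledDataset(rng.standard_normal((10, 2)), ["A"] * 10)
        with pytest.raises(ValueError):
            train_svm(ds, SVMParams(C=1.0, gamma=1.0))


class TestPredict:
    def test_three_class_separable_blobs(self, rng):
        ds = make_blobs(rng, [[0, 0], [8, 0], [0, 8]], 15)
        model = train_svm(ds, SVMParams(C=10.0, gamma=0.5))
        assert accuracy(model, ds) == 1.0

    def test_order_permutation_invariance(self, rng):
        ds = make_blobs(rng, [[0, 0], [6, 0], [0, 6]], 12)
        perm = rng.permutation(ds.n_obs)
        shuffled = ds.subset(perm)
        probe = rng.uniform(-2, 8, (40, 2))
        p1 = predict(train_svm(ds, SVMParams(C=3.0, gamma=0.4)), probe)
        p2 = predict(train_svm(shuffled, SVMParams(C=3.0, gamma=0.4)), probe)
        assert list(p1) == list(p2)

    def test_dimension_mismatch_rejected(self, rng):
        ds = make_blobs(rng, [[0, 0], [5, 5]], 10)
        model = train_svm(ds, SVMParams(C=1.0, gamma=1.0))
        with pytest.raises(ValueError):
            predict(model, np.ones((1, 3)))

    def test_agrees_with_brute_force_dual_on_small_instances(self, rng):
        """Decision f(x) = sgn(sum a_i y_i K(x_i, x) + b) from an
        independently solved dual matches the trained machine."""
        for trial in range(5):
            n = 8 + 2 * trial  # n <= 16
            x = rng.standard_normal((n, 1))
            y = np.where(x[:, 0] + 0.3 * rng.standard_normal(n) > 0, 1.0, -1.0)
            if len(np.unique(y)) < 2:
                continue
            C, gamma = 2.0, 0.8
            ds = LabeledDataset(x, ["P" if v > 0 else "N" for v in y])
            model = train_svm(ds, SVMParams(C=C, gamma=gamma))
            # brute-force reference on the standardized features
            xs = (x - model.scaler_mean) / model.scaler_scale
            a, b = brute_force_dual(xs, y, C, gamma)
            probes = np.linspace(xs.min() - 1, xs.max() + 1, 21)[:, None]
            raw_probes = probes * model.scaler_scale + model.scaler_mean
            got = predict(model, raw_probes)
            for z, lab in zip(probes, got):
                ref = brute_force_decision(xs, y, a, b, gamma, z)
                if abs(ref) > 1e-3:  # skip knife-edge points
                    assert lab == ("P" if ref > 0 else "N")


class TestCvFitness:
    def test_separable_blobs_fitness_one(self, rng):
        ds = make_blobs(rng, [[0, 0], [10, 10]], 20)
        assert cv_fitness(ds, SVMParams(C=10.0, gamma=0.5), 5, 0) == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        n = 200
        feats = rng.standard_normal((n, 4))
        labels = ["A"] * (n // 2) + ["B"] * (n // 2)
        labels = [labels[i] for i in rng.permutation(n)]
        fit = cv_fitness(
            LabeledDataset(feats, labels), SVMParams(C=1.0, gamma=0.25), 5, 3
        )
        assert 0.4 <= fit <= 0.6  # binomial 95% band around 1/2 at n=200

    def test_deterministic_given_seed(self, rng):
        ds = make_blobs(rng, [[0, 0], [2, 2]], 20, spread=1.0)
        p = SVMParams(C=2.0, gamma=0.3)
        assert cv_fitness(ds, p, 5, 11) == cv_fitness(ds, p, 5, 11)

    def test_small_class_rejected(self, rng):
        ds = make_blobs(rng, [[0, 0], [5, 5]], 3)
        with pytest.raises(ValueError):
            cv_fitness(ds, SVMParams(C=1.0, gamma=1.0), 5, 0)


class TestGaOptimize:
    def test_recovers_known_optimum_stub_landscape(self):
        def stub(params):
            return -((np.log2(params.C) - 2.0) ** 2) - (np.log2(params.gamma) + 3.0) ** 2

        cfg = GAConfig(pop_size=50, max_gen=50, seed=5)
        result = ga_optimize(None, cfg, fitness_fn=stub)
        assert abs(np.log2(result.best_params.C) - 2.0) <= 0.5
        assert abs(np.log2(result.best_params.gamma) + 3.0) <= 0.5

    def test_history_best_nondecreasing(self, rng):
        ds = make_blobs(rng, [[0, 0], [1.5, 1.5]], 15, spread=1.0)
        cfg = GAConfig(pop_size=10, max_gen=8, seed=2)
        result = ga_optimize(ds, cfg)
        best = [g["best"] for g in result.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_never_below_default_baseline(self, rng):
        ds = make_blobs(rng, [[0, 0], [2, 0], [0, 2]], 10, spread=1.2)
        cfg = GAConfig(pop_size=8, max_gen=5, seed=4)
        result = ga_optimize(ds, cfg)
        baseline = cv_fitness(
            ds, SVMParams(C=1.0, gamma=1.0 / ds.n_features), cfg.cv_folds, result.fold_seed
        )
        assert result.best_fitness >= baseline

    def test_bit_identical_reproducibility(self, rng):
        ds = make_blobs(rng, [[0, 0], [3, 3]], 10, spread=1.0)
        cfg = GAConfig(pop_size=6, max_gen=4, seed=9)
        r1 = ga_optimize(ds, cfg)
        r2 = ga_optimize(ds, cfg)
        assert r1.history == r2.history
        assert r1.best_params == r2.best_params
        assert r1.best_fitness == r2.best_fitness


class TestModelSerialization:
    def test_round_trip_predictions(self, tmp_path, rng):
        ds = make_blobs(rng, [[0, 0], [5, 0], [0, 5]], 12)
        model = train_svm(ds, SVMParams(C=4.0, gamma=0.6))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        probe = rng.uniform(-2, 7, (25, 2))
        assert list(predict(model, probe)) == list(predict(back, probe))
        back.check_dual_feasibility()
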