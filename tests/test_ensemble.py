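import numpy as np
import pandas as pd
import pytest

from riverrange.ensemble import (
    FEATURE_CLASS_GRID,
    REG_MULT_GRID,
    EnsembleModel,
    FittedModel,
    LearnerConfig,
    aicc,
    auc,
    build_ensemble,
    classify_performance,
    expand_features,
    fit_all,
    fit_maxent_like,
    tss_max,
    tune_maxent,
    variable_importance,
)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_tss(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    u = np.sort(np.unique(scores))
    best, best_t = -np.inf, None
    for t in (u[:-1] + u[1:]) / 2:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        tss = sens + spec - 1
        if tss > best + 1e-12:
            best, best_t = tss, t
    return best, best_t


def linear_logistic_table(n=500, beta=3.0, seed=0, n_vars=2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_vars))
    eta = beta * X[:, 0] - 1.0
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(n_vars)])
    df.insert(0, "label", y)
    df.insert(0, "record_id", [f"r{i}" for i in range(n)])
    return df


class TestExpandFeatures:
    def test_column_counts(self):
        X = np.random.default_rng(0).random((20, 3))
        assert expand_features(X, "L").shape[1] == 3
        assert expand_features(X, "LQ").shape[1] == 6
        k = 10
        # H: 2 hinge directions x k knots per variable
        assert expand_features(X, "H", k).shape[1] == 3 * 2 * k
        assert expand_features(X, "LQH", k).shape[1] == 6 + 3 * 2 * k
        assert expand_features(X, "LQHP", k).shape[1] == 6 + 3 * 2 * k + 3
        assert expand_features(X, "LQHPT", k).shape[1] == 6 + 3 * 2 * k + 3 + 3 * k

    def test_hinge_values(self):
        from riverrange.ensemble import FeatureExpander

        X = np.linspace(0, 10, 11)[:, None]
        exp = FeatureExpander("H", knots_per_var=3).fit(X)
        knots = exp.knots_[0]
        k = knots[0]
        fwd_at_k = max(0.0, k - k)
        fwd_at_k1 = max(0.0, (k + 1) - k)
        assert fwd_at_k == 0.0
        assert fwd_at_k1 == 1.0
        D = exp.transform(np.array([[k], [k + 1]]))
        assert D[0, 0] == pytest.approx(0.0)
        assert D[1, 0] == pytest.approx(1.0)

    def test_unknown_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            expand_features(X, "LZ")
        with pytest.raises(ValueError):
            expand_features(X, "QP")  # not one of the six stated combinations


class TestFitMaxentLike:
    def test_huge_penalty_predicts_prevalence(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((300, 4))
        y = (rng.random(300) < 0.2).astype(int)
        fit = fit_maxent_like(X, y, reg_mult=1e6)
        assert fit.k == 0
        np.testing.assert_allclose(fit.predict(X), y.mean(), atol=1e-6)

    def test_separable_training_auc_one(self):
        x = np.concatenate([np.linspace(-3, -1, 30), np.linspace(1, 3, 30)])
        y = np.concatenate([np.zeros(30, int), np.ones(30, int)])
        fit = fit_maxent_like(x[:, None], y, reg_mult=0.5, base_penalty=0.1)
        assert auc(fit.predict(x[:, None]), y) == 1.0

    def test_k_monotone_in_reg_mult(self):
        table = linear_logistic_table(n=400, seed=1, n_vars=4)
        X = table[[c for c in table if c.startswith("v")]].to_numpy()
        D = expand_features(X, "LQ")
        y = table["label"].to_numpy()
        ks = [fit_maxent_like(D, y, rm).k for rm in REG_MULT_GRID]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_one_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_maxent_like(X, np.ones(10, int), 1.0)


class TestAicc:
    def test_zero(self):
        assert aicc(0.0, 0, 10) == 0.0

    def test_hand_computed(self):
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_monotone_in_k(self):
        vals = [aicc(-5.0, k, 50) for k in range(6)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_undefined_correction(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 9, 10)


class TestTuneMaxent:
    def test_48_rows(self):
        table = linear_logistic_table(n=200, seed=2)
        config, tuning = tune_maxent(table, knots_per_var=4)
        assert len(tuning) == 48
        assert config.algorithm == "MAXENT"

    def test_reduced_class_grid(self):
        table = linear_logistic_table(n=200, seed=2)
        _, tuning = tune_maxent(
            table, feature_classes=FEATURE_CLASS_GRID[:-1], knots_per_var=4
        )
        assert len(tuning) == 40

    def test_linear_truth_selects_simple_class(self):
        wins = 0
        for seed in range(50):
            table = linear_logistic_table(n=500, beta=3.0, seed=seed)
            config, _ = tune_maxent(table, knots_per_var=4)
            if config.hyperparameters["feature_classes"] in ("L", "LQ"):
                wins += 1
        assert wins >= 45


class TestAuc:
    def test_perfect(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 20), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestTssMax:
    def test_perfect_separation(self):
        t, thr = tss_max([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert t == pytest.approx(1.0)
        assert 0.2 < thr < 0.8

    def test_worked_example(self):
        t, _ = tss_max([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert t == pytest.approx(0.5)

    def test_no_skill(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        t, _ = tss_max(scores, labels)
        assert t < 0.1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(8, 60))
        scores = rng.choice(np.linspace(0, 1, 10), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        t, thr = tss_max(scores, labels)
        bt, _ = brute_force_tss(scores, labels)
        assert t == pytest.approx(bt, abs=1e-12)

    def test_internal_consistency_with_auc(self):
        """Max TSS equals 2*AUC - 1 of the classifier binarized at its own
        threshold."""
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)
        t, thr = tss_max(scores, labels)
        binarized = (scores >= thr).astype(float)
        assert t == pytest.approx(2 * auc(binarized, labels) - 1, abs=1e-12)


class TestClassifyPerformance:
    def test_excellent(self):
        assert classify_performance(0.98, 0.88) == ("excellent", "excellent")

    def test_good(self):
        assert classify_performance(0.84, 0.52) == ("good", "good")

    def test_scale_gap(self):
        auc_class, _ = classify_performance(0.65, 0.5)
        assert auc_class == "unclassified (scale gap)"

    def test_poor(self):
        assert classify_performance(0.55, 0.2) == ("poor", "poor")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_performance(1.2, 0.5)
        with pytest.raises(ValueError):
            classify_performance(0.8, -1.5)


class _StubLearner:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def stub_model(algorithm, mean_auc, pred_value, cols=("v0",)):
    return FittedModel(
        config=LearnerConfig(algorithm),
        learner=_StubLearner(pred_value),
        feature_cols=list(cols),
        fold_scores=pd.DataFrame(
            {"fold": range(4), "auc": [mean_auc] * 4, "tss": [0.5] * 4}
        ),
    )


class TestBuildEnsemble:
    def test_single_member_identity(self):
        m = stub_model("GLM", 0.8, 0.3)
        ens = build_ensemble([m])
        X = np.zeros((5, 1))
        np.testing.assert_allclose(ens.predict(X), 0.3)

    def test_equal_weights(self):
        ens = build_ensemble([stub_model("GLM", 0.8, 0.2),
                              stub_model("RF", 0.8, 0.6)])
        np.testing.assert_allclose(ens.predict(np.zeros((3, 1))), 0.4)

    def test_weighted_mean(self):
        ens = build_ensemble([stub_model("GLM", 0.9, 1.0),
                              stub_model("RF", 0.7, 0.0)])
        np.testing.assert_allclose(
            ens.predict(np.zeros((2, 1))), 0.9 / 1.6, rtol=1e-12
        )

    def test_gate_excludes_members(self):
        ens = build_ensemble([stub_model("GLM", 0.9, 1.0),
                              stub_model("RF", 0.5, 0.0)])
        assert len(ens.members) == 1

    def test_all_below_gate_rejected(self):
        with pytest.raises(ValueError, match="gate"):
            build_ensemble([stub_model("GLM", 0.6, 0.5)])

    def test_prediction_within_member_envelope(self):
        rng = np.random.default_rng(0)

        class R:
            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)

            def predict(self, X):
                return self.rng.random(len(X))

        members = []
        for i, a in enumerate((0.8, 0.85, 0.9)):
            m = stub_model("GLM", a, 0)
            m.learner = R(i)
            members.append(m)
        ens = build_ensemble(members)
        X = np.zeros((50, 1))
        preds = np.stack([m.predict(X) for m in ens.members])
        # fresh RNG state per call: re-predict for the ensemble
        for m in ens.members:
            m.learner.rng = np.random.default_rng(ens.members.index(m))
        combo = ens.predict(X)
        assert (combo >= preds.min(axis=0) - 1e-12).all()
        assert (combo <= preds.max(axis=0) + 1e-12).all()


def spatial_table(seed=0, n_pres=150, n_bg=600, beta=2.5):
    """Feature table with coordinates so checkerboard folds can be built."""
    from riverrange.occurrences import checkerboard2
    from riverrange.grid import Grid

    rng = np.random.default_rng(seed)
    n = n_pres + n_bg
    xy = rng.random((n, 2)) * 32_000
    x1 = np.sin(xy[:, 0] / 8000) + rng.normal(0, 0.3, n)
    x2 = rng.standard_normal(n)
    eta = beta * x1 - 1.5
    p = 1 / (1 + np.exp(-eta))
    # presences: accept-reject toward high-suitability locations
    order = np.argsort(-(p + rng.normal(0, 0.05, n)))
    label = np.zeros(n, int)
    label[order[:n_pres]] = 1
    df = pd.DataFrame({"record_id": [f"r{i}" for i in range(n)],
                       "label": label, "v0": x1, "v1": x2})
    pts = pd.DataFrame({"id": df["record_id"], "x": xy[:, 0], "y": xy[:, 1],
                        "year": 2020, "uncertainty_m": 0.0})
    grid = Grid(values=np.zeros((32, 32)), cell_size_m=1000.0)
    folds = checkerboard2(pts, grid, 8, 2)
    return df, folds


class TestFitAll:
    def test_fold_scores_bounded(self):
        table, folds = spatial_table(seed=1)
        models = fit_all(table, folds, knots_per_var=4, seed=0)
        assert {m.algorithm for m in models} == {"GLM", "GAM", "GBM", "RF",
                                                 "MAXENT"}
        for m in models:
            assert len(m.fold_scores) == 4
            assert 0.0 <= m.mean_auc <= 1.0
            assert -1.0 <= m.mean_tss <= 1.0

    def test_strong_signal_recovers(self):
        for seed in (2, 3, 4):
            table, folds = spatial_table(seed=seed, beta=3.0)
            models = fit_all(table, folds, knots_per_var=4, seed=0)
            for m in models:
                assert m.mean_auc > 0.7, (seed, m.algorithm, m.mean_auc)

    def test_label_permutation_is_null(self):
        rng = np.random.default_rng(9)
        for seed in (5, 6):
            table, folds = spatial_table(seed=seed)
            table = table.assign(label=rng.permutation(table["label"].to_numpy()))
            models = fit_all(table, folds, knots_per_var=4, seed=0)
            for m in models:
                assert 0.35 <= m.mean_auc <= 0.65, (m.algorithm, m.mean_auc)


class TestVariableImportance:
    def test_absent_variable_zero(self):
        table, folds = spatial_table(seed=1)

        class OnlyV0:
            def predict(self, X):
                return 1 / (1 + np.exp(-X[:, 0]))

        m = stub_model("GLM", 0.8, 0, cols=("v0", "v1"))
        m.learner = OnlyV0()
        imp = variable_importance(build_ensemble([m]), table, permutations=3,
                                  seed=0)
        assert imp["v1"] == 0.0
        assert imp["v0"] > 0.1

    def test_truth_variable_ranks_first(self):
        hits = 0
        for seed in (1, 2, 3, 4, 5):
            table, folds = spatial_table(seed=seed, beta=3.0)
            models = fit_all(table, folds, algorithms=("GLM",), seed=0)
            ens = build_ensemble(models, min_auc=0.0)
            imp = variable_importance(ens, table, permutations=3, seed=seed)
            if imp.idxmax() == "v0":
                hits += 1
        assert hits >= 4

    def test_deterministic(self):
        table, folds = spatial_table(seed=1)
        models = fit_all(table, folds, algorithms=("GLM",), seed=0)
        ens = build_ensemble(models, min_auc=0.0)
        a = variable_importance(ens, table, permutations=4, seed=11)
        b = variable_importance(ens, table, permutations=4, seed=11)
        pd.testing.assert_series_equal(a, b)
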