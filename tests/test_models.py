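import warnings

import numpy as np
import pandas as pd
import pytest

from prosodia import models as mdl

warnings.filterwarnings("ignore", category=FutureWarning)


def toy_table(n_recs=(50, 30, 20), utt_per_rec=1, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    rec = 0
    for cls, n in enumerate(n_recs):
        for _ in range(n):
            for u in range(utt_per_rec):
                rows.append({"recording_id": f"r{rec:03d}",
                             "speaker_id": f"r{rec:03d}",
                             "utterance_id": f"r{rec:03d}_u{u}",
                             "x": rng.normal(cls, 1.0), "label": cls})
            rec += 1
    return pd.DataFrame(rows)


def separable_features(n_per_class=30, n_features=5, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(3):
        mu = np.zeros(n_features)
        mu[0] = cls * sep
        X.append(rng.normal(mu, 1.0, (n_per_class, n_features)))
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestStratifiedSplit:
    def test_per_class_test_counts_follow_rounding(self):
        table = toy_table()
        train, test = mdl.stratified_split(table, 0.25, seed=3)
        counts = test.groupby("label")["recording_id"].nunique()
        assert counts[0] in (12, 13) and counts[1] in (7, 8) \
            and counts[2] == 5

    def test_same_seed_reproduces_split(self):
        table = toy_table()
        a = mdl.stratified_split(table, 0.25, seed=5)[1]
        b = mdl.stratified_split(table, 0.25, seed=5)[1]
        assert a["recording_id"].tolist() == b["recording_id"].tolist()

    def test_recordings_never_straddle_the_split(self):
        table = toy_table(utt_per_rec=3)
        train, test = mdl.stratified_split(table, 0.25, seed=1)
        assert not set(train["recording_id"]) & set(test["recording_id"])

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            mdl.stratified_split(toy_table(n_recs=(10, 10, 3)), 0.25, 0)


class TestFilterCorrelated:
    def test_duplicated_column_reduced_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "a_copy": x,
                          "b": rng.normal(size=50)})
        y = (x > 0).astype(int)
        kept, dropped = mdl.filter_correlated(X, y)
        assert len([c for c in kept.columns if c.startswith("a")]) == 1
        assert len(dropped) == 1

    def test_survivor_has_highest_outcome_correlation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        y = np.digitize(base, [-0.5, 0.5])
        X = pd.DataFrame({
            "a": base + rng.normal(0, 0.05, 200),
            "b": base,                          # strongest link to y
            "c": base + rng.normal(0, 0.05, 200),
        })
        kept, dropped = mdl.filter_correlated(X, y)
        assert list(kept.columns) == ["b"]
        assert set(dropped) == {"a", "c"}

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 4)),
                         columns=list("abcd"))
        y = rng.integers(0, 3, 100)
        kept, dropped = mdl.filter_correlated(X, y)
        assert list(kept.columns) == list("abcd") and not dropped

    def test_constant_column_does_not_crash(self):
        X = pd.DataFrame({"const": np.ones(30),
                          "x": np.arange(30.0)})
        kept, _ = mdl.filter_correlated(X, np.arange(30) % 3)
        assert "x" in kept.columns


class TestMeanLogLoss:
    def test_perfect_one_hot_is_zero(self):
        proba = np.eye(3)[[0, 1, 2, 1]]
        assert mdl.mean_log_loss(proba, [0, 1, 2, 1]) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_is_ln3(self):
        proba = np.full((6, 3), 1 / 3)
        assert mdl.mean_log_loss(proba, [0, 1, 2, 0, 1, 2]) == \
            pytest.approx(np.log(3), abs=1e-12)

    def test_hand_computed_four_rows(self):
        proba = np.array([[0.7, 0.2, 0.1],
                          [0.1, 0.8, 0.1],
                          [0.2, 0.3, 0.5],
                          [0.25, 0.25, 0.5]])
        truth = [0, 1, 2, 0]
        expected = -np.mean(np.log([0.7, 0.8, 0.5, 0.25]))
        assert mdl.mean_log_loss(proba, truth) == pytest.approx(expected, abs=1e-12)

    def test_invalid_probability_rows_rejected(self):
        with pytest.raises(ValueError):
            mdl.mean_log_loss(np.array([[0.5, 0.2, 0.1]]), [0])


class TestSpaceFillingCandidates:
    @pytest.mark.parametrize("kind", mdl.MODEL_KINDS)
    def test_candidates_respect_bounds(self, kind):
        grid = mdl.TuningGrid(kind, mdl.default_grid(kind), 20, seed=2)
        for cand in mdl.space_filling_candidates(grid):
            for name, pr in grid.ranges.items():
                if pr.choices is not None:
                    assert cand[name] in pr.choices
                else:
                    assert pr.lo - 1e-9 <= cand[name] <= pr.hi + 1e-9

    def test_maximin_beats_plain_uniform_draw(self):
        grid = mdl.TuningGrid("random_forest",
                              mdl.default_grid("random_forest"), 20, seed=4)
        cands = mdl.space_filling_candidates(grid)
        names = list(grid.ranges)

        def unit(c):
            out = []
            for nm in names:
                pr = grid.ranges[nm]
                out.append((c[nm] - pr.lo) / (pr.hi - pr.lo))
            return out

        pts = np.array([unit(c) for c in cands])
        rng = np.random.default_rng(4)
        uni = rng.uniform(size=pts.shape)

        def min_dist(p):
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            return d.min()

        # integer rounding can only merge points, so compare pre-rounding
        # spread via a generous margin
        assert min_dist(pts) >= min_dist(uni) * 0.9

    def test_knn_kernels_drawn_from_the_nine_options(self):
        grid = mdl.TuningGrid("knn", mdl.default_grid("knn"), 30, seed=5)
        kernels = {c["kernel"] for c in mdl.space_filling_candidates(grid)}
        assert kernels <= set(mdl.KNN_KERNELS)
        assert len(kernels) >= 5  # the cycle covers the options


class TestTuneCv:
    def test_separable_features_beat_chance(self):
        X, y = separable_features()
        tuned = mdl.tune_cv("knn", X, y, k=5, seed=0, n_candidates=5)
        assert tuned.cv_loss < np.log(3)

    def test_same_seed_same_choice(self):
        X, y = separable_features(seed=1)
        a = mdl.tune_cv("random_forest", X, y, k=5, seed=7, n_candidates=4,
                        grid=mdl.TuningGrid("random_forest", {
                            "n_trees": mdl.ParamRange(10, 50, "int"),
                            "mtry": mdl.ParamRange(1, 5, "int"),
                            "min_node": mdl.ParamRange(2, 10, "int")}, 4, 7))
        b = mdl.tune_cv("random_forest", X, y, k=5, seed=7, n_candidates=4,
                        grid=mdl.TuningGrid("random_forest", {
                            "n_trees": mdl.ParamRange(10, 50, "int"),
                            "mtry": mdl.ParamRange(1, 5, "int"),
                            "min_node": mdl.ParamRange(2, 10, "int")}, 4, 7))
        assert a.params == b.params
        assert a.cv_loss == pytest.approx(b.cv_loss, abs=1e-12)

    def test_cv_loss_is_mean_of_fold_losses(self):
        X, y = separable_features(seed=2)
        tuned = mdl.tune_cv("knn", X, y, k=5, seed=0, n_candidates=3)
        assert tuned.cv_loss == pytest.approx(np.mean(tuned.fold_losses),
                                              abs=1e-12)

    def test_probabilities_form_simplex(self):
        X, y = separable_features(seed=3)
        tuned = mdl.tune_cv("ordinal_elasticnet", X, y, k=5, seed=0,
                            n_candidates=2)
        proba = tuned.fold_models[0].predict_proba(X[:10])
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)


class _FixedModel:
    def __init__(self, proba_row):
        self.row = np.asarray(proba_row, float)

    def predict_proba(self, X):
        return np.tile(self.row, (len(X), 1))


class TestAveraging:
    def test_identical_fold_models_average_to_themselves(self):
        m = _FixedModel([0.2, 0.5, 0.3])
        avg = mdl.AveragedModel("knn", [m, m, m])
        assert np.allclose(avg.predict_proba(np.zeros((4, 2))),
                           [0.2, 0.5, 0.3])

    def test_mean_of_two_one_hot_models(self):
        avg = mdl.AveragedModel("knn", [_FixedModel([1, 0, 0]),
                                        _FixedModel([0, 1, 0])])
        assert np.allclose(avg.predict_proba(np.zeros((2, 2))),
                           [0.5, 0.5, 0.0])

    def test_averaged_rows_sum_to_one(self):
        avg = mdl.AveragedModel("knn", [_FixedModel([0.6, 0.3, 0.1]),
                                        _FixedModel([0.1, 0.1, 0.8])])
        assert np.allclose(avg.predict_proba(np.zeros((3, 2))).sum(axis=1), 1)

    def test_single_fold_model_rejected(self):
        with pytest.raises(ValueError):
            mdl.AveragedModel("knn", [_FixedModel([1, 0, 0])])


def _tuned_stub(kind, oof, proba_row):
    return mdl.TunedModel(kind, {}, [_FixedModel(proba_row)] * 2,
                          [0.0, 0.0], 0.0, np.asarray(oof, float))


class TestStacking:
    def test_better_base_model_gets_largest_weight(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 3, 90)
        good = np.full((90, 3), 0.05)
        good[np.arange(90), y] = 0.9
        bad = np.full((90, 3), 1 / 3)
        tuned = {"random_forest": _tuned_stub("random_forest", good, [1, 0, 0]),
                 "knn": _tuned_stub("knn", bad, [1 / 3] * 3)}
        ens = mdl.stack_ensemble(tuned, y)
        w = dict(zip(tuned, ens.weights))
        assert w["random_forest"] > w["knn"]
        assert w["random_forest"] == max(ens.weights)

    def test_identical_bases_equal_any_base(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 3, 60)
        oof = rng.dirichlet(np.ones(3), 60)
        tuned = {k: _tuned_stub(k, oof, [0.2, 0.5, 0.3])
                 for k in ("svm_poly", "knn")}
        ens = mdl.stack_ensemble(tuned, y)
        X = np.zeros((5, 2))
        assert np.allclose(ens.predict_proba(X), [0.2, 0.5, 0.3], atol=1e-6)

    def test_ensemble_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 3, 60)
        tuned = {"a": _tuned_stub("a", rng.dirichlet(np.ones(3), 60),
                                  [0.7, 0.2, 0.1]),
                 "b": _tuned_stub("b", rng.dirichlet(np.ones(3), 60),
                                  [0.1, 0.8, 0.1])}
        ens = mdl.stack_ensemble(tuned, y)
        assert np.allclose(ens.predict_proba(np.zeros((4, 2))).sum(axis=1), 1)


class _LinearProbModel:
    """p(class 2) = sigmoid(w.x / 4); remainder on class 0."""

    def __init__(self, w):
        self.w = np.asarray(w, float)

    def predict_proba(self, X):
        from scipy.special import expit
        p2 = expit(np.asarray(X) @ self.w / 4.0)
        return np.stack([1 - p2, np.zeros_like(p2), p2], axis=1)


class TestFirmImportance:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.X = rng.normal(0, [1.0, 2.0, 0.5, 1.5, 1.0], (300, 5))
        self.names = [f"f{j}" for j in range(5)]

    def test_ignored_predictor_scores_zero(self):
        model = _LinearProbModel([1.0, 0.5, 0.0, 0.3, 0.2])
        imp = mdl.firm_importance(model, self.X, feature_names=self.names)
        assert imp["f2"] == pytest.approx(0.0, abs=1e-9)

    def test_rank_order_follows_weight_times_spread(self):
        w = np.array([1.0, 0.8, 2.0, 0.1, 0.5])
        model = _LinearProbModel(w)
        imp = mdl.firm_importance(model, self.X, feature_names=self.names)
        sd = self.X.std(axis=0)
        expected_order = np.argsort(-np.abs(w) * sd)
        got_order = np.argsort([-imp[f"f{j}"] for j in range(5)])
        assert list(expected_order) == list(got_order)

    def test_scale_times_weight_invariance(self):
        w = np.array([1.0, 0.5, 0.7, 0.2, 0.9])
        base = mdl.firm_importance(_LinearProbModel(w), self.X,
                                   feature_names=self.names)
        X2 = self.X.copy()
        X2[:, 0] *= 2.0
        w2 = w.copy()
        w2[0] /= 2.0
        rescaled = mdl.firm_importance(_LinearProbModel(w2), X2,
                                       feature_names=self.names)
        assert rescaled["f0"] == pytest.approx(base["f0"], rel=0.02)

    def test_constant_predictor_zero(self):
        X = self.X.copy()
        X[:, 3] = 1.23
        imp = mdl.firm_importance(_LinearProbModel([1, 1, 1, 1, 1]), X,
                                  feature_names=self.names)
        assert imp["f3"] == 0.0


class TestOrdinalBaseline:
    def test_monotone_predictor_monotone_prediction(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(0, 0.3, 40),
                            rng.normal(2, 0.3, 40),
                            rng.normal(4, 0.3, 40)])
        y = np.repeat([0, 1, 2], 40)
        m = mdl.baseline_f0sd_model(x, y)
        grid = np.array([[0.0], [2.0], [4.0]])
        preds = m.predict(grid)
        assert list(preds) == sorted(preds)

    def test_deterministic_fit(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=90)
        y = np.repeat([0, 1, 2], 30)
        a = mdl.baseline_f0sd_model(x, y).predict(x.reshape(-1, 1))
        b = mdl.baseline_f0sd_model(x, y).predict(x.reshape(-1, 1))
        assert np.array_equal(a, b)
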