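import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pcg_emotion.classify import (EmotionLabel, aggregate_selection, cv_fitness,
                                  evaluate, ga_select, map_labels, tune_cg)
from pcg_emotion.errors import ConfigError

REFERENCE_COUNTS = {"relaxed": 43, "happy": 21, "sad": 18, "angry": 14}


def emotion_vector():
    out = []
    for emo, n in REFERENCE_COUNTS.items():
        out += [emo] * n
    return out


def planted_problem(seed, n=60, d=50, informative=None):
    """Only two of d features carry the class signal."""
    if informative is None:
        informative = (3, 17) if d > 17 else (0, 1)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = np.where(X[:, informative[0]] + X[:, informative[1]] > 0, "a", "b")
    return X, y


class TestEmotionLabel:
    def test_russell_mapping(self):
        assert EmotionLabel("relaxed").valence == "high"
        assert EmotionLabel("happy").valence == "high"
        assert EmotionLabel("sad").valence == "low"
        assert EmotionLabel("angry").valence == "low"
        assert EmotionLabel("relaxed").arousal == "low"
        assert EmotionLabel("sad").arousal == "low"
        assert EmotionLabel("happy").arousal == "high"
        assert EmotionLabel("angry").arousal == "high"

    def test_unknown_emotion_rejected(self):
        with pytest.raises(ValueError):
            EmotionLabel("meh")


class TestMapLabels:
    def test_valence_counts(self):
        _, counts = map_labels(emotion_vector(), "valence")
        assert counts == {"low": 32, "high": 64}

    def test_arousal_counts(self):
        _, counts = map_labels(emotion_vector(), "arousal")
        assert counts == {"low": 61, "high": 35}

    def test_four_class_counts(self):
        _, counts = map_labels(emotion_vector(), "four_class")
        assert counts == REFERENCE_COUNTS

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            map_labels(["relaxed"], "dominance")


class TestCvFitness:
    def test_separable_classes(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(6, 1, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        mask = np.ones(2, bool)
        assert cv_fitness(X, y, mask, c=1.0, g=0.5, seed=1) >= 0.95

    def test_permutation_null(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(6, 1, (50, 2))])
        y = rng.permutation(np.array(["a"] * 50 + ["b"] * 50))
        acc = cv_fitness(X, y, np.ones(2, bool), seed=2)
        se = np.sqrt(0.25 / 100)
        assert abs(acc - 0.5) <= 3 * se + 0.05

    def test_empty_mask_penalized(self):
        X = np.random.default_rng(3).standard_normal((20, 4))
        y = np.array(["a", "b"] * 10)
        assert cv_fitness(X, y, np.zeros(4, bool)) == 0.0

    def test_matches_manual_fold_loop(self):
        # independent re-implementation: per-fold scaler fit on train only
        X, y = planted_problem(seed=5)
        mask = np.zeros(X.shape[1], bool)
        mask[[3, 17, 20]] = True
        c, g, seed = 2.0, 0.25, 7
        got = cv_fitness(X, y, mask, c=c, g=g, seed=seed)
        Xm = X[:, mask]
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=seed).split(Xm, y):
            sc = StandardScaler().fit(Xm[tr])
            clf = SVC(kernel="rbf", C=c, gamma=g, class_weight="balanced")
            clf.fit(sc.transform(Xm[tr]), y[tr])
            accs.append(np.mean(clf.predict(sc.transform(Xm[te])) == y[te]))
        assert got == pytest.approx(float(np.mean(accs)), abs=1e-12)

    def test_deterministic(self):
        X, y = planted_problem(seed=8)
        mask = np.ones(X.shape[1], bool)
        assert cv_fitness(X, y, mask, seed=4) == cv_fitness(X, y, mask, seed=4)


class TestGaSelect:
    def test_minimal_run(self):
        X, y = planted_problem(seed=0, n=30, d=5)
        run = ga_select(X, y, ga_config={"population": 2, "generations": 1}, seed=0)
        assert len(run.fitness_trace) == 1
        assert run.best_mask.any()

    def test_trace_non_decreasing(self):
        X, y = planted_problem(seed=1, n=40, d=12)
        run = ga_select(X, y, ga_config={"population": 10, "generations": 8}, seed=3)
        best = run.fitness_trace["best"].to_numpy()
        assert np.all(np.diff(best) >= -1e-12)
        assert run.best_fitness == pytest.approx(best.max())

    def test_planted_features_recovered(self):
        hits = 0
        for seed in range(5):
            X, y = planted_problem(seed=100 + seed)
            run = ga_select(X, y, ga_config={"population": 20, "generations": 15},
                            seed=seed)
            hits += bool(run.best_mask[3] and run.best_mask[17])
        assert hits >= 4

    def test_degenerate_config_rejected(self):
        X, y = planted_problem(seed=2, n=30, d=5)
        with pytest.raises(ConfigError):
            ga_select(X, y, ga_config={"population": 1, "generations": 5})
        with pytest.raises(ConfigError):
            ga_select(X, y, ga_config={"generations": 0})

    def test_deterministic(self):
        X, y = planted_problem(seed=3, n=30, d=8)
        cfg = {"population": 8, "generations": 4}
        r1 = ga_select(X, y, ga_config=cfg, seed=11)
        r2 = ga_select(X, y, ga_config=cfg, seed=11)
        assert np.array_equal(r1.best_mask, r2.best_mask)
        assert r1.best_fitness == r2.best_fitness


class TestAggregateSelection:
    def make_runs(self, n, masks, fits):
        X, y = planted_problem(seed=4, n=30, d=len(masks[0]))
        runs = []
        for i, (m, f) in enumerate(zip(masks, fits)):
            run = ga_select(X, y, ga_config={"population": 2, "generations": 1},
                            seed=i)
            run.best_mask = np.asarray(m, bool)
            run.best_fitness = f
            runs.append(run)
        return runs

    def test_retention_count_30_runs(self):
        masks = [np.ones(6, bool)] * 30
        runs = self.make_runs(30, masks, np.linspace(0.5, 0.9, 30))
        agg = aggregate_selection(runs)
        assert len(agg.retained) == 6

    def test_identical_masks(self):
        mask = np.array([1, 0, 1, 0, 1, 0], bool)
        runs = self.make_runs(30, [mask] * 30, [0.8] * 30)
        agg = aggregate_selection(runs)
        assert np.array_equal(agg.weight, mask.astype(float))
        assert np.array_equal(agg.optimal_subset, mask)

    def test_unanimous_feature_weight(self):
        base = np.array([1, 0, 0, 0, 0, 0], bool)
        masks = [base | (np.arange(6) == (i % 5) + 1) for i in range(30)]
        runs = self.make_runs(30, masks, np.linspace(0.5, 0.9, 30))
        agg = aggregate_selection(runs)
        assert agg.weight[0] == 1.0  # feature 0 selected by every retained run

    def test_too_few_runs_rejected(self):
        runs = self.make_runs(3, [np.ones(4, bool)] * 3, [0.5] * 3)
        with pytest.raises(ValueError):
            aggregate_selection(runs)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(5, 1, (30, 3))])
    y = np.array(["a"] * 30 + ["b"] * 30)
    return X, y


class TestTuneCg:
    def test_argmax_contract(self, separable):
        X, y = separable
        grid = {"log2c": (-3, 3, 2), "log2g": (-5, 1, 2)}
        c, g, curve = tune_cg(X, y, np.ones(3, bool), grid_config=grid, seed=0)
        best = curve["accuracy"].max()
        corners = curve[(curve["log2c"].isin([-3, 3]))
                        & (curve["log2g"].isin([-5, 1]))]["accuracy"]
        assert best >= corners.max() - 1e-12
        assert curve.loc[(curve["c"] == c) & (curve["g"] == g),
                         "accuracy"].iloc[0] == pytest.approx(best)

    def test_curve_length_is_grid_size(self, separable):
        X, y = separable
        grid = {"log2c": (-3, 3, 2), "log2g": (-5, 1, 2)}
        _, _, curve = tune_cg(X, y, np.ones(3, bool), grid_config=grid, seed=0)
        assert len(curve) == 4 * 4

    def test_deterministic(self, separable):
        X, y = separable
        grid = {"log2c": (-1, 3, 2), "log2g": (-3, 1, 2)}
        a = tune_cg(X, y, np.ones(3, bool), grid_config=grid, seed=5)
        b = tune_cg(X, y, np.ones(3, bool), grid_config=grid, seed=5)
        assert a[:2] == b[:2]

    def test_empty_subset_rejected(self, separable):
        X, y = separable
        with pytest.raises(ValueError):
            tune_cg(X, y, np.zeros(3, bool))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["low"] * 5 + ["high"] * 5)
        rep = evaluate(y, y)
        assert rep["accuracy"] == 1.0
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 1.0

    def test_all_positive_on_64_32_split(self):
        y = np.array(["high"] * 64 + ["low"] * 32)
        pred = np.array(["high"] * 96)
        rep = evaluate(y, pred)
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 0.0
        assert rep["accuracy"] == pytest.approx(2 / 3, abs=1e-4)

    def test_confusion_row_sums_are_class_counts(self):
        rng = np.random.default_rng(9)
        y = rng.choice(["relaxed", "happy", "sad", "angry"], size=60)
        pred = rng.choice(["relaxed", "happy", "sad", "angry"], size=60)
        rep = evaluate(y, pred)
        cm = np.array(rep["confusion_matrix"])
        for lab, row_sum in zip(rep["labels"], cm.sum(axis=1)):
            assert row_sum == np.sum(y == lab)

    def test_single_class_truth_metrics_missing(self):
        y = np.array(["high"] * 10)
        pred = np.array(["high"] * 9 + ["low"])
        rep = evaluate(y, pred)
        assert rep["specificity"] is None
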