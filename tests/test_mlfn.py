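"""Feature expansion, partitioning, network training and interpretation."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from coralrhythm.fixtures import SeriesSpec, generate_series
from coralrhythm.mlfn import (
    ConfusionMetrics,
    Standardizer,
    binarize,
    build_base_block,
    confusion_metrics,
    enumerate_monomials,
    expand_features,
    feature_importance,
    fit_activity_model,
    interval_error_summary,
    partition_euclidean,
    select_feature_count,
    sigmoid_profile,
    train_mlfn,
)


def _brute_force_monomials(n_base, max_degree):
    """Independent enumeration oracle: canonicalized index multisets."""
    seen = set()
    for deg in range(1, max_degree + 1):
        for tup in itertools.product(range(n_base), repeat=deg):
            seen.add(tuple(sorted(tup)))
    return seen


class TestBinarize:
    @pytest.mark.parametrize("pct,expected", [(50.0, 1), (49.999, 0), (100.0, 1), (0.0, 0)])
    def test_threshold_rule(self, pct, expected):
        assert binarize(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(101.0)
        with pytest.raises(ValueError):
            binarize(np.array([50.0, -2.0]))


class TestExpandFeatures:
    @pytest.mark.parametrize("n_base", [2, 3, 4, 5, 6, 7])
    def test_count_matches_brute_force(self, n_base):
        provs = enumerate_monomials(n_base, 3, binary_cols=())
        assert len(provs) == len(_brute_force_monomials(n_base, 3))
        assert set(provs) == _brute_force_monomials(n_base, 3)

    def test_seven_columns_degree_three_is_119(self):
        assert len(enumerate_monomials(7, 3, binary_cols=())) == 119

    def test_enumeration_order_degree_then_lexicographic(self):
        provs = enumerate_monomials(3, 2, binary_cols=())
        assert provs == [(0,), (1,), (2,), (0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

    def test_monomial_columns_are_products(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 7))
        X[:, 6] = rng.integers(0, 2, 50)
        blk = expand_features(X)
        j = blk.provenance.index((2, 2))
        assert np.allclose(blk.X[:, j], X[:, 2] ** 2)
        j3 = blk.provenance.index((1, 3, 5))
        assert np.allclose(blk.X[:, j3], X[:, 1] * X[:, 3] * X[:, 5])

    def test_binary_powers_collapse(self):
        X = np.random.default_rng(1).standard_normal((20, 7))
        X[:, 6] = (X[:, 6] > 0).astype(float)
        blk = expand_features(X)
        assert (6, 6) not in blk.provenance and (6, 6, 6) not in blk.provenance
        assert (6,) in blk.provenance
        assert len(blk.provenance) == len(set(blk.provenance)) == 111

    def test_non_finite_rejected(self):
        X = np.zeros((5, 7))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            expand_features(X)


class TestPartitionEuclidean:
    def test_square_picks_diagonal_corners(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        train, test = partition_euclidean(X, 0.5)
        assert set(train) in ({0, 1}, {2, 3})  # a diagonal pair
        d = np.linalg.norm(X[train[0]] - X[train[1]])
        assert d == pytest.approx(np.sqrt(2))

    def test_observatory_scale_partition_size(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((1643, 6))
        train, test = partition_euclidean(X, 0.70)
        assert len(train) in (1150, 1151)
        assert len(train) + len(test) == 1643
        assert len(np.intersect1d(train, test)) == 0

    def test_deterministic(self):
        X = np.random.default_rng(3).standard_normal((60, 4))
        a = partition_euclidean(X, 0.7)
        b = partition_euclidean(X, 0.7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_maximin_property_of_each_addition(self):
        """Every selected point (after the seed pair) maximizes the minimal
        distance to the previously selected set — checked by replay."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((24, 3))
        train, _ = partition_euclidean(X, 0.5)
        d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
        # reconstruct the selection order greedily and compare the sets
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        chosen = [min(i, j), max(i, j)]
        while len(chosen) < len(train):
            mind = np.min(d2[:, chosen], axis=1)
            mind[chosen] = -np.inf
            chosen.append(int(np.argmax(mind)))
        assert set(chosen) == set(train)


class TestTrainMlfn:
    def test_linearly_separable_data_fit_to_under_one_percent(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        model = train_mlfn(X, y, seed=0)
        err = (model.predict(X) != y).mean()
        assert err <= 0.01

    def test_constant_response_predicts_the_constant(self):
        X = np.random.default_rng(6).standard_normal((50, 3))
        with pytest.warns(UserWarning, match="constant response"):
            model = train_mlfn(X, np.ones(50, int), seed=0)
        assert (model.predict(X) == 1).all()

    def test_regularization_keeps_effective_parameters_small(self):
        """Evidence-updated alpha shrinks gamma well below the raw count."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((300, 30))
        y = rng.binomial(1, expit(X[:, 0]))
        model = train_mlfn(X, y, seed=0)
        n_params = model.w1.size + model.b1.size + model.w2.size + model.b2.size
        assert model.bayes
        assert model.gamma < 0.5 * n_params

    def test_close_to_bayes_optimal_on_logistic_fixture(self):
        """Trained net approaches the oracle classifier of the generating model."""
        ser = generate_series(SeriesSpec(n_hours=1500, seed=3))
        Xb, _ = build_base_block(ser)
        Z = Standardizer(tuple(range(6))).fit(Xb).transform(Xb)
        rng = np.random.default_rng(107)
        eta = 2 * Z[:, 1] - 1.5 * Z[:, 3]
        y = rng.binomial(1, expit(eta))
        blk = expand_features(Z)
        tr, te = partition_euclidean(Z, 0.7)
        model = train_mlfn(blk.X[tr], y[tr], seed=0)
        pred = model.predict(blk.X[te])
        oracle = (eta[te] > 0).astype(int)
        cm_model = confusion_metrics(y[te], pred)
        cm_oracle = confusion_metrics(y[te], oracle)
        assert cm_model.precision >= cm_oracle.precision - 0.06
        assert cm_model.recall >= cm_oracle.recall - 0.06
        # and it recovers the decision rule itself
        assert (pred == oracle).mean() >= 0.85


class TestConfusionMetrics:
    def test_published_test_matrix_arithmetic(self):
        m = ConfusionMetrics.from_matrix([[223, 70], [86, 124]])
        assert m.precision_3dp == pytest.approx(0.721, abs=1e-9)
        assert m.recall_3dp == pytest.approx(0.761, abs=1e-9)
        assert m.n_bad == 156
        assert m.pct_bad == pytest.approx(100 * 156 / 503)

    def test_perfect_prediction(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.precision == 1.0 and m.recall == 1.0 and m.pct_bad == 0.0

    def test_all_predicted_positive(self):
        y = np.array([1, 1, 0, 0, 0])
        m = confusion_metrics(y, np.ones(5, int))
        assert m.recall == 1.0
        assert m.precision == pytest.approx(y.mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics([], [])

    def test_interval_error_summary_arithmetic(self):
        # 10 observations: 4 in the 20-80 band (1 error), 6 outside (3 errors)
        b = np.array([10, 15, 90, 95, 85, 5, 30, 40, 60, 70.0])
        correct = np.array([0, 1, 1, 0, 0, 1, 1, 1, 0, 1], bool)
        out = interval_error_summary(b, correct)
        assert out["n_interval"] == 4 and out["n_errors"] == 4
        assert out["pct_errors_in_interval"] == pytest.approx(25.0)
        assert out["error_rate_in_interval_pct"] == pytest.approx(25.0)
        assert out["error_rate_outside_pct"] == pytest.approx(50.0)


class TestFeatureImportance:
    def test_zero_column_ranked_last(self):
        from coralrhythm.mlfn import MlfnModel

        w1 = np.abs(np.random.default_rng(8).standard_normal((9, 5))) + 0.1
        w1[:, 2] = 0.0
        model = MlfnModel(w1, np.zeros(9), np.zeros((2, 9)), np.zeros(2),
                          1.0, 1.0, 1.0, True, True, 0)
        imp = feature_importance(model, top=5)
        assert imp.iloc[-1]["column"] == 2
        assert imp.iloc[-1]["importance"] == 0.0

    def test_ties_break_by_column_index(self):
        from coralrhythm.mlfn import MlfnModel

        model = MlfnModel(np.eye(4), np.zeros(4), np.zeros((2, 4)), np.zeros(2),
                          1.0, 1.0, 1.0, True, True, 0)
        imp = feature_importance(model, top=4)
        assert list(imp["column"]) == [0, 1, 2, 3]

    def test_informative_features_recovered_majority_of_seeds(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((400, 33))
            y = rng.binomial(1, expit(2 * X[:, 0] - 2 * X[:, 1] + 1.5 * X[:, 2]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = train_mlfn(X, y, seed=seed, max_iter=200)
            top5 = set(feature_importance(model, top=5)["column"])
            hits += len(top5 & {0, 1, 2}) >= 2
        assert hits >= 3


class TestSigmoidProfile:
    def test_self_comparison_near_one(self):
        b = np.linspace(0, 100, 300)
        r, p = sigmoid_profile(b, b.copy())
        assert r >= 0.99 and p < 1e-6

    def test_antisymmetric_variable(self):
        b = np.linspace(0, 100, 300)
        r, _ = sigmoid_profile(b, -b)
        assert r <= -0.99

    def test_independent_noise_mostly_uncorrelated(self):
        rng = np.random.default_rng(9)
        b = rng.uniform(0, 100, 1000)
        small = sum(abs(sigmoid_profile(b, rng.standard_normal(1000), smooth_window=11)[0]) < 0.2
                    for _ in range(200))
        assert small >= 0.9 * 200

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = sigmoid_profile(np.linspace(0, 100, 50), np.full(50, 3.0))
        assert np.isnan(r) and np.isnan(p)


class TestFeatureCountSelection:
    def test_signal_in_first_columns_pushes_k_past_them(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((500, 20))
        y = rng.binomial(1, expit(2.5 * X[:, 0] - 2.5 * X[:, 1] + 2.5 * X[:, 2]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k_star, curve = select_feature_count(X, y, ks=[1, 2, 3, 6, 12], cv_folds=3,
                                                 seed=0, max_iter=80)
        assert k_star >= 3
        assert np.isfinite(curve["cv_rms"]).all() and (curve["cv_rms"] >= 0).all()
        first3 = curve.set_index("k")["cv_rms"]
        assert first3.loc[3] <= first3.loc[1]

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100, 5))
        y = rng.integers(0, 2, 100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k_star, curve = select_feature_count(X, y, ks=[4], cv_folds=3, seed=0, max_iter=30)
        assert k_star == 4 and len(curve) == 1


class TestActivityModel:
    def test_no_leakage_and_summary(self):
        ser = generate_series(SeriesSpec(n_hours=600, seed=9))
        fit = fit_activity_model(ser, k=14, seed=0)
        # standardization was fit on the training partition only
        Xb, _ = build_base_block(ser)
        train_std = fit.standardizer.transform(Xb[fit.train_idx])
        assert np.allclose(train_std[:, :6].mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(train_std[:, :6].std(axis=0), 1.0, atol=1e-9)
        assert fit.k == 14
        assert "MLFN activity model" in fit.summary()
        assert fit.test_metrics.pct_bad <= 25.0  # rhythm-driven fixture is learnable

    def test_rows_with_missing_sensors_dropped(self):
        ser = generate_series(SeriesSpec(
            n_hours=600, gap_windows=(("2018-02-05", "2018-02-10"),), seed=10))
        Xb, y = build_base_block(ser)
        assert len(Xb) < 600
        assert np.isfinite(Xb).all()
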