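import itertools

import numpy as np
import pandas as pd
import pytest

from ramancellid.chemometrics import (
    classification_report,
    error_average,
    fit_pca,
    fit_plsda,
    predict,
    roc_auc,
    select_n_lv,
    split_every_fourth,
    venetian_cv,
    vip_scores,
)
from ramancellid.preprocess import PreprocessRecipe
from ramancellid.spectral_data import SpectralDataError

from conftest import make_dataset

RAW = PreprocessRecipe(())


def two_class_toy(n_per_class=8, p=6, sep=5.0, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, noise, size=(2 * n_per_class, p))
    X[n_per_class:, 0] += sep  # classes separated along one variable
    labels = ["A"] * n_per_class + ["B"] * n_per_class
    return make_dataset(X, labels=labels, cells=[f"c{i}" for i in range(2 * n_per_class)])


class TestPCA:
    def test_rank_one_dataset(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer([1.0, 2.0, 3.0, 5.0], v)
        d = make_dataset(X)
        res = fit_pca(d, 2, RAW)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=500)
        d = make_dataset(X)
        res = fit_pca(d, 2, RAW)
        # dense eigendecomposition of the sample covariance as oracle
        evals, evecs = np.linalg.eigh(np.cov(X.T))
        order = np.argsort(evals)[::-1]
        for i in range(2):
            v = evecs[:, order[i]]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(res.loadings[i], v, atol=1e-8)

    def test_loadings_orthonormal_and_scores_centered(self, small_sim):
        d, _ = small_sim
        res = fit_pca(d, 5, RAW)
        np.testing.assert_allclose(
            res.loadings @ res.loadings.T, np.eye(5), atol=1e-8
        )
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)
        assert res.explained_variance_fraction.sum() <= 1 + 1e-9

    def test_too_many_components_rejected(self):
        d = make_dataset(np.eye(3))
        with pytest.raises(SpectralDataError):
            fit_pca(d, 4, RAW)


class TestSplitEveryFourth:
    def test_eight_spectra_rule(self):
        d = make_dataset(np.arange(8)[:, None] * np.ones((8, 4)))
        cal, val = split_every_fourth(d)
        assert val.matrix[:, 0].tolist() == [3.0, 7.0]
        assert cal.n_spectra == 6

    def test_study_scale_arithmetic(self):
        d = make_dataset(np.zeros((1500, 3)))
        cal, val = split_every_fourth(d)
        assert (cal.n_spectra, val.n_spectra) == (1125, 375)

    def test_partition_is_exact(self, small_sim):
        d, _ = small_sim
        cal, val = split_every_fourth(d)
        assert cal.n_spectra + val.n_spectra == d.n_spectra
        combined = np.vstack([cal.matrix, val.matrix])
        assert sorted(map(tuple, combined)) == sorted(map(tuple, d.matrix))


class TestFitPLSDA:
    def test_separable_two_class_single_lv(self):
        d = two_class_toy()
        m = fit_plsda(d, 1, RAW)
        _, labels = predict(m, d)
        assert np.all(labels == d.class_labels)

    def test_full_rank_matches_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        labels = ["A", "B", "C", "D"] * 5
        d = make_dataset(X, labels=labels)
        m = fit_plsda(d, 6, RAW)
        scores, _ = predict(m, d)
        # normal-equations oracle on centered data
        Y = np.zeros((20, 4))
        for j, c in enumerate(m.class_order):
            Y[np.array(labels) == c, j] = 1.0
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        oracle = Xc @ B + Y.mean(axis=0)
        np.testing.assert_allclose(scores, oracle, atol=1e-8)

    def test_row_duplication_leaves_coefficients_unchanged(self):
        d = two_class_toy()
        m1 = fit_plsda(d, 2, RAW)
        dup = make_dataset(
            np.repeat(d.matrix, 2, axis=0),
            labels=np.repeat(d.class_labels, 2),
            cells=[f"c{i}" for i in range(2 * d.n_spectra)],
        )
        m2 = fit_plsda(dup, 2, RAW)
        np.testing.assert_allclose(
            m1.regression_coefficients, m2.regression_coefficients, atol=1e-8
        )

    def test_single_class_rejected(self):
        d = make_dataset(np.random.default_rng(0).normal(size=(6, 4)))
        with pytest.raises(SpectralDataError):
            fit_plsda(d, 1, RAW)

    def test_one_lv_agrees_with_sklearn_nipals(self):
        # scikit-learn's NIPALS PLS2 is an independent cross-check: for a
        # single latent variable both algorithms span the same direction
        from sklearn.cross_decomposition import PLSRegression

        d = two_class_toy(seed=11)
        m = fit_plsda(d, 1, RAW)
        scores, _ = predict(m, d)
        Y = np.column_stack(
            [(d.class_labels == c).astype(float) for c in m.class_order]
        )
        sk = PLSRegression(n_components=1, scale=False).fit(d.matrix, Y)
        np.testing.assert_allclose(scores, sk.predict(d.matrix), atol=1e-8)


class TestPredict:
    def test_tie_goes_to_first_class(self):
        d = two_class_toy()
        m = fit_plsda(d, 1, RAW)
        zero = make_dataset(
            np.tile(m.x_mean, (2, 1)), axis=d.axis, labels=["A", "B"]
        )
        scores, labels = predict(m, zero)
        # centered input -> scores equal the class means; equal-prior toy
        # gives identical scores, so argmax must return the first class
        assert np.allclose(scores[0], scores[0][0])
        assert labels[0] == m.class_order[0]

    def test_permuted_labels_predict_at_chance(self):
        rng = np.random.default_rng(13)
        n, p = 500, 20
        X = rng.normal(size=(n, p))
        labels = rng.permutation(np.repeat(list("ABCDE"), n // 5))
        d = make_dataset(X, labels=labels)
        cal, val = split_every_fourth(d)
        m = fit_plsda(cal, 3, RAW)
        _, assigned = predict(m, val)
        acc = np.mean(assigned == val.class_labels)
        sigma = np.sqrt(0.2 * 0.8 / val.n_spectra)
        assert abs(acc - 0.2) < 3 * sigma + 1e-12


class TestVenetianCV:
    def test_separable_data_zero_error(self):
        d = two_class_toy(n_per_class=20)
        curves = venetian_cv(d, 3, 10, RAW)
        assert np.all(curves.cv_error < 1e-12)
        assert np.all(curves.calibration_error < 1e-12)

    def test_pure_noise_two_class_near_half(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(400, 15))
        labels = rng.permutation(["A"] * 200 + ["B"] * 200)
        d = make_dataset(X, labels=labels)
        curves = venetian_cv(d, 3, 10, RAW)
        sigma = np.sqrt(0.25 / 400)
        assert np.all(np.abs(curves.cv_error - 0.5) < 5 * sigma)

    def test_bit_reproducible(self, small_sim):
        d, _ = small_sim
        cal, _ = split_every_fourth(d)
        c1 = venetian_cv(cal, 4, 10, RAW)
        c2 = venetian_cv(cal, 4, 10, RAW)
        assert np.array_equal(c1.cv_error, c2.cv_error)
        assert np.array_equal(c1.cv_predictions, c2.cv_predictions)

    def test_small_class_warns(self):
        d = two_class_toy(n_per_class=4)
        with pytest.warns(UserWarning, match="fewer members"):
            venetian_cv(d, 1, 10, RAW)


class TestSelectNLv:
    def test_smallest_meeting_target(self):
        from ramancellid.chemometrics import ErrorCurves

        curves = ErrorCurves(
            np.array([1, 2, 3]),
            np.array([0.30, 0.10, 0.04]),
            np.array([0.31, 0.12, 0.045]),
            np.zeros((3, 1, 1)),
            ["A", "B"],
        )
        assert select_n_lv(curves, 0.05) == (3, True)

    def test_fallback_to_cv_minimum(self):
        from ramancellid.chemometrics import ErrorCurves

        curves = ErrorCurves(
            np.array([1, 2, 3]),
            np.array([0.30, 0.20, 0.10]),
            np.array([0.31, 0.18, 0.22]),
            np.zeros((3, 1, 1)),
            ["A", "B"],
        )
        assert select_n_lv(curves, 0.05) == (2, False)


class TestVIP:
    def test_informative_variable_dominates(self):
        rng = np.random.default_rng(19)
        n = 60
        X = rng.normal(size=(n, 10))
        y = np.array(["A"] * 30 + ["B"] * 30)
        X[:, 4] += (y == "B") * 3.0  # single informative variable
        d = make_dataset(X, labels=list(y))
        m = fit_plsda(d, 1, RAW)
        v = vip_scores(m)
        assert np.argmax(v.vip) == 4
        assert v.vip[4] > 1.0
        # direct-formula oracle on the fitted weights
        W = m.x_weights
        w2 = (W[:, 0] ** 2) / np.sum(W[:, 0] ** 2)
        oracle = np.sqrt(10 * w2)
        np.testing.assert_allclose(v.vip, oracle, atol=1e-10)

    def test_symmetric_variables_all_unity(self):
        X = np.array([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        d = make_dataset(X, labels=["A", "B", "A", "B"])
        m = fit_plsda(d, 1, RAW)
        v = vip_scores(m)
        np.testing.assert_allclose(v.vip, 1.0, atol=1e-6)

    def test_mean_square_identity(self, small_sim):
        d, _ = small_sim
        m = fit_plsda(d, 5, RAW)
        v = vip_scores(m)
        assert np.mean(v.vip**2) == pytest.approx(1.0, abs=1e-8)


class TestROCAUC:
    def test_perfect_separation(self):
        truth = np.array([0, 0, 1, 1], dtype=bool)
        assert roc_auc(truth, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_ties_half(self):
        truth = np.array([0, 1, 0, 1], dtype=bool)
        assert roc_auc(truth, np.ones(4)) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(23)
        truth = np.array([1] * 7 + [0] * 9, dtype=bool)
        scores = rng.normal(size=16)
        scores[3] = scores[10]  # plant a tie across classes
        got = roc_auc(truth, scores)
        wins = 0.0
        for sp, sn in itertools.product(scores[truth], scores[~truth]):
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert got == pytest.approx(wins / 63.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SpectralDataError):
            roc_auc(np.ones(5, dtype=bool), np.arange(5.0))


class TestClassificationReport:
    def test_confusion_arithmetic(self):
        assert error_average(
            np.array(["A"] * 10 + ["B"] * 10),
            np.array(["A"] * 9 + ["B"] + ["B"] * 10),
            ["A", "B"],
        ) == pytest.approx(0.05)  # A: (FNR .1 + FPR 0)/2; B: (0 + .1)/2; mean

    def test_perfect_classifier_metrics(self):
        d = two_class_toy(n_per_class=16)
        cal, val = split_every_fourth(d)
        curves = venetian_cv(cal, 2, 4, RAW)
        m = fit_plsda(cal, 2, RAW)
        rep = classification_report(m, cal, val, curves, "spectrum")
        assert rep.average_sensitivity == 1.0
        assert rep.average_specificity == 1.0
        assert np.all(rep.per_class["auc"] == 1.0)
        assert int(np.trace(rep.confusion_matrix.to_numpy())) == val.n_spectra
        assert np.all(rep.per_class["rmsec"] >= 0)
        assert np.isfinite(rep.per_class["rmsecv"]).all()

    def test_missing_validation_class_flagged_nan(self):
        d = two_class_toy(n_per_class=16)
        cal, val = split_every_fourth(d)
        val_a_only = val.select((val.class_labels == "A"))
        m = fit_plsda(cal, 1, RAW)
        rep = classification_report(m, cal, val_a_only, None, "spectrum")
        assert np.isnan(rep.per_class.loc["B", "sensitivity"])
        assert np.isnan(rep.per_class.loc["B", "auc"])

    def test_cell_level_averages_line_scans(self, small_sim):
        d, _ = small_sim
        cal, val = split_every_fourth(d)
        m = fit_plsda(cal, 4, PreprocessRecipe(()))
        rep = classification_report(m, cal, val, None, "cell")
        # every simulated cell contributes exactly one averaged spectrum
        n_cells = val.meta.groupby(["cell_line", "cell_id"]).ngroups
        assert int(rep.confusion_matrix.to_numpy().sum()) == n_cells
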