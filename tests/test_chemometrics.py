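"""Splitting, PCA/Q², SIMCA membership, OPLS-DA and validation statistics."""

import numpy as np
import pandas as pd
import pytest

import tristepir as t
from tristepir import chemometrics as chem
from tristepir.errors import DegenerateDataError, ParameterError


def _labelled(X, labels):
    return chem.DataMatrix(X=X, y=np.asarray(labels, dtype=object))


def _three_class(n_per=10, p=25, sep=6.0, noise=1.0, seed=0):
    """Noisy three-class data with well-separated class means."""
    rng = np.random.default_rng(seed)
    means = rng.normal(size=(3, p)) * sep
    X = np.vstack([means[k] + noise * rng.normal(size=(n_per, p))
                   for k in range(3)])
    y = ["a"] * n_per + ["b"] * n_per + ["c"] * n_per
    return _labelled(X, y)


class TestStratifiedSplit:
    def test_exact_fraction(self):
        data = _three_class(n_per=10)
        cal, val = chem.stratified_split(data, 0.6, seed=1)
        for c in ("a", "b", "c"):
            assert np.sum(cal.y == c) == 6
            assert np.sum(val.y == c) == 4

    def test_ceil_rule_on_seven_samples(self):
        rng = np.random.default_rng(0)
        data = _labelled(rng.normal(size=(7, 5)), ["seed"] * 7)
        cal, val = chem.stratified_split(data, 0.6, seed=3)
        assert cal.n_samples == 5 and val.n_samples == 2

    def test_deterministic_and_disjoint(self):
        data = _three_class()
        a = chem.stratified_split(data, 0.6, seed=9)
        b = chem.stratified_split(data, 0.6, seed=9)
        np.testing.assert_array_equal(a[0].X, b[0].X)
        assert a[0].n_samples + a[1].n_samples == data.n_samples

    def test_single_sample_class_rejected(self):
        data = _labelled(np.random.default_rng(0).normal(size=(3, 4)),
                         ["a", "a", "b"])
        with pytest.raises(DegenerateDataError):
            chem.stratified_split(data, 0.6, seed=0)


class TestCancellationGroups:
    def test_partition_and_stratification(self):
        y = np.asarray(["a"] * 14 + ["b"] * 21, dtype=object)
        g = chem.cancellation_groups(y, 7, seed=4)
        assert sorted(np.unique(g)) == list(range(7))
        for c in ("a", "b"):
            counts = np.bincount(g[y == c], minlength=7)
            assert counts.max() - counts.min() <= 1
        np.testing.assert_array_equal(g, chem.cancellation_groups(y, 7, seed=4))


class TestPCA:
    def test_rank_one_explains_everything(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=12), rng.normal(size=8))
        m = chem.pca_fit(X, 1)
        assert m.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_are_centred(self):
        X = np.random.default_rng(2).normal(size=(15, 10))
        m = chem.pca_fit(X, 3)
        np.testing.assert_allclose(m.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(3).normal(size=(20, 30))
        m = chem.pca_fit(X, 5)
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(5),
                                   atol=1e-8)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.normal(size=(20, 50))
            mine = chem.pca_fit(X, 2)
            ref = PCA(n_components=2, svd_solver="full").fit(X)
            np.testing.assert_allclose(
                mine.explained_variance_ratio,
                ref.explained_variance_ratio_, atol=1e-10)
            for a in range(2):
                dot = abs(float(mine.loadings[:, a] @ ref.components_[a]))
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateDataError):
            chem.pca_fit(np.ones((5, 4)), 1)


class TestPCAQ2:
    def test_noiseless_rank_two_is_predictive(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 40))
        q2 = chem.pca_q2(X, 2, seed=5)
        assert q2[1] > 0.9

    def test_pure_noise_is_not_predictive(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 40))
        q2 = chem.pca_q2(X, 3, seed=6)
        assert np.all(q2 <= 0.0)

    def test_q2_never_exceeds_r2x_componentwise(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 2)) @ rng.normal(size=(2, 30)) \
            + 0.3 * rng.normal(size=(25, 30))
        q2 = chem.pca_q2(X, 3, seed=7)
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        ss = float(np.sum(Xc ** 2))
        ss_after = ss - np.concatenate(([0.0], np.cumsum(sv ** 2)))
        r2x_cw = 1.0 - ss_after[1:4] / ss_after[0:3]
        assert np.all(q2 <= r2x_cw + 1e-12)

    def test_too_many_groups_rejected(self):
        with pytest.raises(ParameterError):
            chem.pca_q2(np.random.default_rng(0).normal(size=(5, 4)), 2,
                        n_groups=7)


class TestSIMCA:
    def test_calibration_rows_accepted_at_alpha(self):
        data = _three_class(n_per=20, p=40, seed=8)
        model = chem.simca_fit(data, alpha=0.05, seed=8)
        for c in data.classes:
            rows = data.X[data.y == c]
            d = model.dmodx(rows, c)
            crit = model.class_models[c].critical_dmodx
            assert np.mean(d <= crit) >= 0.95

    def test_gross_outlier_far_above_critical(self):
        data = _three_class(seed=9)
        model = chem.simca_fit(data, seed=9)
        c = data.classes[0]
        outlier = data.X[data.y == c].mean(axis=0) + 10.0 * np.ptp(data.X)
        d = model.dmodx(outlier[None, :], c)
        assert d[0] > 5.0 * model.class_models[c].critical_dmodx

    def test_oversized_component_request_rejected(self):
        data = _three_class(n_per=5, seed=10)
        with pytest.raises(ParameterError):
            chem.simca_fit(data, components_per_class={"a": 4, "b": 1, "c": 1})

    def test_membership_invariant_to_row_order(self):
        data = _three_class(seed=11)
        model = chem.simca_fit(data, seed=11)
        cal, val = chem.stratified_split(data, 0.6, seed=11)
        fwd = chem.simca_classify(model, val)
        rev = chem.simca_classify(model, val.subset(np.arange(val.n_samples)[::-1]))
        for c in data.classes:
            np.testing.assert_array_equal(
                fwd[f"member_{c}"].to_numpy()[::-1],
                rev[f"member_{c}"].to_numpy())

    def test_separated_classes_rejected_from_other_models(self):
        data = _three_class(n_per=15, sep=8.0, seed=12)
        model = chem.simca_fit(data, seed=12)
        out = chem.simca_classify(model, data)
        for c in data.classes:
            other = out.loc[np.asarray(data.y != c), f"member_{c}"]
            assert other.mean() < 0.05


def _orth_structure_data(n=30, p=20, seed=13):
    """X = class structure + a strictly Y-orthogonal direction (no noise)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
    data = _labelled(np.zeros((n, p)), y)
    Y = data.one_hot()
    Yc = Y - Y.mean(axis=0)
    B = rng.normal(size=(3, p))
    v = rng.normal(size=n)
    v -= Yc @ np.linalg.lstsq(Yc, v, rcond=None)[0]     # exactly Y-orthogonal
    # the orthogonal variation overlaps the predictive features (as real
    # structured interference does), so the filter has something to remove
    a_dir = B[0] + 0.5 * rng.normal(size=p)
    X = Y @ B + 3.0 * np.outer(v, a_dir)
    return _labelled(X, y)


class TestOPLSDA:
    def test_orthogonal_scores_uncorrelated_with_response(self):
        data = _orth_structure_data()
        model = chem.oplsda_fit(data, n_orthogonal=1, seed=13)
        assert model.n_orthogonal == 1
        Y = data.one_hot()
        Yc = Y - Y.mean(axis=0)
        cov = model.t_orth.T @ Yc
        assert np.max(np.abs(cov)) < 1e-8 * np.linalg.norm(model.t_orth)

    def test_separable_data_fits_perfectly(self):
        data = _three_class(sep=10.0, noise=0.01, seed=14)
        model = chem.oplsda_fit(data, seed=14)
        assert model.r2y >= 0.99
        labels, _ = chem.oplsda_predict(model, data)
        assert np.all(labels == data.y)

    def test_yhat_invariant_to_extra_orthogonal_components(self):
        data = _orth_structure_data()
        yhats = [chem.oplsda_fit(data, n_orthogonal=k, seed=13)
                 .predict_yhat(data.X) for k in (1, 2, 3)]
        assert np.max(np.abs(yhats[0] - yhats[1])) < 1e-8
        assert np.max(np.abs(yhats[0] - yhats[2])) < 1e-8

    def test_no_orthogonal_variation_reduces_to_plain_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(15)
        y = np.asarray(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
        data = _labelled(np.zeros((30, 12)), y)
        Y = data.one_hot()
        X = Y @ rng.normal(size=(3, 12))        # all variation is Y-predictive
        data = _labelled(X, y)
        model = chem.oplsda_fit(data, n_orthogonal="auto", seed=15)
        assert model.n_orthogonal == 0
        ref = PLSRegression(n_components=2, scale=False, tol=1e-14,
                            max_iter=5000).fit(X, Y)
        np.testing.assert_allclose(model.predict_yhat(X), ref.predict(X),
                                   atol=1e-8)

    def test_pls_core_matches_sklearn_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 15))
        Y = rng.normal(size=(30, 3))
        W, P, Q = chem._pls2_nipals(X - X.mean(0), Y - Y.mean(0), 4)
        T = chem._pls2_scores(W, P, X - X.mean(0))
        yhat = Y.mean(0) + T @ Q.T
        ref = PLSRegression(n_components=4, scale=False, tol=1e-14,
                            max_iter=5000).fit(X, Y)
        np.testing.assert_allclose(yhat, ref.predict(X), atol=1e-6)

    def test_duplicated_query_rows_agree(self):
        data = _three_class(seed=17)
        model = chem.oplsda_fit(data, seed=17)
        q = np.vstack([data.X[0], data.X[0]])
        labels, yhat = chem.oplsda_predict(model, chem.DataMatrix(X=q))
        assert labels[0] == labels[1]
        np.testing.assert_array_equal(yhat[0], yhat[1])

    def test_exact_tie_resolves_to_first_declared_class(self):
        model = chem.OPLSDAModel(
            classes=("a", "b"), x_mean=np.zeros(2), y_mean=np.array([0.5, 0.5]),
            w_orth=np.zeros((2, 0)), p_orth=np.zeros((2, 0)),
            t_orth=np.zeros((1, 0)), weights=np.array([[1.0], [0.0]]),
            x_loadings=np.array([[1.0], [0.0]]),
            y_loadings=np.zeros((2, 1)), scores=np.zeros((1, 1)),
            r2x=1.0, r2y=1.0, q2y=1.0)
        labels = model.predict_labels(np.array([[3.0, 1.0]]))
        assert labels[0] == "a"

    def test_single_class_rejected(self):
        data = _labelled(np.random.default_rng(0).normal(size=(6, 4)),
                         ["a"] * 6)
        with pytest.raises(DegenerateDataError):
            chem.oplsda_fit(data)


class TestRMSEMetrics:
    def test_hand_computed_rmsee(self):
        # residuals (0.1, -0.1, 0.1, -0.1), N=4, A=1 -> sqrt(0.04/2)
        res = np.array([0.1, -0.1, 0.1, -0.1])
        rmsee = np.sqrt(np.sum(res ** 2) / (4 - 1 - 1))
        assert rmsee == pytest.approx(0.14142135623730953)

    def test_perfect_model_zero_errors(self):
        data = _three_class(sep=10.0, noise=1e-6, seed=18)
        cal, val = chem.stratified_split(data, 0.6, seed=18)
        model = chem.oplsda_fit(cal, seed=18)
        m = chem.rmse_metrics(model, cal, val)
        assert m.rmsee < 1e-4 and m.rmsecv < 1e-4 and m.rmsep < 1e-4

    def test_rmsecv_at_least_rmsee_on_noisy_data(self):
        data = _three_class(n_per=12, sep=3.0, noise=1.5, seed=19)
        cal, val = chem.stratified_split(data, 0.6, seed=19)
        model = chem.oplsda_fit(cal, seed=19)
        m = chem.rmse_metrics(model, cal, val)
        assert m.rmsecv >= m.rmsee

    def test_dof_error_when_too_few_samples(self):
        data = _three_class(n_per=2, p=6, seed=20)
        model = chem.oplsda_fit(data, n_orthogonal=3, n_groups=2, seed=20)
        with pytest.raises(ParameterError):
            chem.rmse_metrics(model, data, data)


class TestPermutationTest:
    def test_informative_data_validates(self):
        data = _three_class(n_per=10, sep=6.0, seed=21)
        res = chem.permutation_test(data, n_permutations=30, seed=21)
        anchor = res.table.iloc[0]
        assert anchor["correlation"] == 1.0 and not anchor["permuted"]
        permuted = res.table[res.table.permuted]
        # permuted models have no real predictive power
        assert (permuted["q2y"] <= 0).mean() > 0.8
        assert res.valid
        assert res.valid == ((res.r2y_intercept < 0.3)
                             and (res.q2y_intercept < 0.05))

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ParameterError):
            chem.permutation_test(_three_class(), n_permutations=1)


class TestClassificationMetrics:
    def test_perfect_diagonal(self):
        m = chem.classification_metrics(np.diag([5, 8, 3]), 0)
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0,
                                                              100.0)

    def test_worked_counts(self):
        # TP=3, FN=1, FP=1, TN=5
        cm = np.array([[3, 1], [1, 5]])
        m = chem.classification_metrics(cm, 0)
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(83.33333333333333)
        assert m.accuracy == pytest.approx(80.0)

    def test_all_misclassified(self):
        cm = np.array([[0, 4], [3, 0]])
        assert chem.classification_metrics(cm, 0).sensitivity == 0.0

    def test_zero_denominator_flagged_not_zeroed(self):
        cm = np.array([[0, 0], [2, 5]])   # no true positives exist
        m = chem.classification_metrics(cm, 0)
        assert np.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined

    def test_confusion_matrix_row_sums(self):
        y_true = ["a", "a", "b", "c", "c", "c"]
        y_pred = ["a", "b", "b", "c", "a", "c"]
        cm = chem.confusion_matrix(y_true, y_pred, ["a", "b", "c"])
        np.testing.assert_array_equal(cm.sum(axis=1), [2, 1, 3])
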