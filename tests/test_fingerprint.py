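import numpy as np
import pytest
from scipy import linalg

from nmrfp import (
    PCACAKNN,
    CohortSpec,
    fit_ca,
    fit_fingerprint,
    fit_pca,
    generate_cohort,
    loocv_evaluate,
    project,
    stratify_risk,
)
from nmrfp.fingerprint import _loocv_fold_pca_scores, knn_vote
from nmrfp.spectra_io import assemble_matrix


def _two_clouds(n=30, d=5, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep / np.sqrt(d), 1, (n, d))])
    y = np.array(["early"] * n + ["metastatic"] * n, dtype=object)
    return X, y


class TestPCA:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=10)
        X = np.outer(rng.normal(size=12), u)
        _, basis, m, _ = fit_pca(X)
        assert m == 1

    def test_orthonormal_basis(self):
        X = np.random.default_rng(1).normal(size=(40, 15))
        _, basis, m, _ = fit_pca(X)
        np.testing.assert_allclose(basis @ basis.T, np.eye(m), atol=1e-10)

    def test_reconstruction_error_bounded_by_threshold(self):
        X = np.random.default_rng(2).normal(size=(50, 156))
        center, basis, m, ratio = fit_pca(X, var_threshold=0.999)
        Xc = X - center
        resid = Xc - (Xc @ basis.T) @ basis
        assert (resid**2).sum() <= 0.001 * (Xc**2).sum() + 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((5, 4)))


class TestCanonicalAnalysis:
    def test_axis_matches_generalized_eigen_oracle(self):
        # independent oracle: leading eigenvector of the W^-1 B pencil
        X, y = _two_clouds(n=40, d=6, sep=3.0, seed=3)
        a = fit_ca(X, y)
        mask = y == "metastatic"
        mu1, mu0 = X[mask].mean(0), X[~mask].mean(0)
        d_ = mu1 - mu0
        B = np.outer(d_, d_)
        W = sum(
            (X[m] - X[m].mean(0)).T @ (X[m] - X[m].mean(0)) for m in (mask, ~mask)
        )
        w, v = linalg.eigh(B, W)
        oracle = v[:, np.argmax(w)]
        cos = abs(a @ oracle) / (np.linalg.norm(a) * np.linalg.norm(oracle))
        assert cos > 1 - 1e-8

    def test_separable_clouds_fully_ordered(self):
        X, y = _two_clouds(n=25, d=4, sep=12.0, seed=4)
        a = fit_ca(X, y)
        s = X @ a
        assert s[y == "metastatic"].min() > s[y == "early"].max()

    def test_metastatic_mean_positive(self):
        X, y = _two_clouds(seed=5)
        a = fit_ca(X, y)
        s = X @ a
        assert s[y == "metastatic"].mean() > s[y == "early"].mean()

    def test_unit_within_class_variance(self):
        X, y = _two_clouds(seed=6)
        a = fit_ca(X, y)
        s = X @ a
        pooled = np.concatenate([s[y == c] - s[y == c].mean() for c in ("early", "metastatic")])
        assert pooled @ pooled / (len(s) - 2) == pytest.approx(1.0, rel=1e-9)


class TestKNN:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        train = rng.normal(size=20)
        labels = np.array(["early", "metastatic"] * 10, dtype=object)
        queries = rng.normal(size=15)
        got = knn_vote(train, labels, queries, k=9)
        for q, g in zip(queries, got):
            order = sorted(range(20), key=lambda i: (abs(train[i] - q), i))[:9]
            votes = sum(labels[i] == "metastatic" for i in order)
            assert g == ("metastatic" if votes > 4 else "early")

    def test_query_on_training_point_k1(self):
        train = np.array([0.0, 1.0, 2.0])
        labels = np.array(["early", "metastatic", "early"], dtype=object)
        assert knn_vote(train, labels, [1.0], k=1)[0] == "metastatic"

    def test_uniform_labels_always_returned(self):
        train = np.arange(10.0)
        labels = np.array(["early"] * 10, dtype=object)
        assert set(knn_vote(train, labels, [-5.0, 20.0], k=9)) == {"early"}

    def test_distance_ties_broken_by_index(self):
        train = np.array([1.0, -1.0, 5.0])
        labels = np.array(["metastatic", "early", "early"], dtype=object)
        # query 0 is equidistant from indices 0 and 1; index 0 wins
        assert knn_vote(train, labels, [0.0], k=1)[0] == "metastatic"

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_vote(np.arange(3.0), np.array(["early"] * 3, dtype=object), [0.0], k=9)


class TestEstimatorInterface:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        clf = PCACAKNN(k=5, var_threshold=0.99)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    def test_fit_predict_roundtrip(self):
        X, y = _two_clouds(n=30, sep=8.0, seed=8)
        clf = PCACAKNN(k=9).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_even_k_rejected(self):
        X, y = _two_clouds(seed=9)
        with pytest.raises(ValueError, match="odd"):
            PCACAKNN(k=8).fit(X, y)

    def test_model_persistence_roundtrip(self, tmp_path):
        from nmrfp.fingerprint import FingerprintModel

        X, y = _two_clouds(n=20, sep=4.0, seed=10)
        model = fit_fingerprint(np.abs(X) + 0.5, y)
        path = tmp_path / "model.json"
        model.save(path)
        back = FingerprintModel.load(path)
        Xq = np.abs(_two_clouds(n=10, sep=4.0, seed=11)[0]) + 0.5
        np.testing.assert_array_equal(
            project(model, Xq).y_pred, project(back, Xq).y_pred
        )


class TestLOOCV:
    def test_no_leakage_of_held_out_row(self, noesy_training):
        X = noesy_training["X"][:40]
        folds1 = _loocv_fold_pca_scores(X, 0.999, True)
        X2 = X.copy()
        X2[7] = X2[7] * 13.0 + 5.0  # corrupt the held-out sample of fold 7
        folds2 = _loocv_fold_pca_scores(X2, 0.999, True)
        np.testing.assert_array_equal(folds1[7][0], folds2[7][0])

    def test_separable_limit_perfect_accuracy(self):
        # strong effect sizes, no nuisances: the classes separate completely
        strong = {}
        base = CohortSpec()
        for name, d in base.target_deltas.items():
            strong[name] = float(np.sign(d) * 0.98) if d != 0 else 0.9
        spec = CohortSpec(
            n_ecrc_free=20, n_ecrc_relapsed=0, n_mcrc=20, n_points=2048, seed=5,
            target_deltas=strong, noise_sd=0.0, miscalibration_sd=0.0,
            dilution_sd=0.0, water_amplitude=0.0, ethanol_probability=0.0,
            n_background_signals=0,
        )
        cohort = generate_cohort(spec)
        matrix = assemble_matrix(cohort.spectra["NOESY"])
        groups = cohort.clinical.set_index("id")["group"]
        y = np.array(
            ["metastatic" if groups[s] == "mCRC" else "early" for s in matrix.sample_ids],
            dtype=object,
        )
        res = loocv_evaluate(matrix.values, y)
        assert res.accuracy == 1.0

    def test_metric_identities(self, noesy_training):
        res = loocv_evaluate(noesy_training["X"], noesy_training["y"], noesy_training["ids"])
        (tn, fp), (fn, tp) = res.confusion
        n = len(noesy_training["y"])
        assert tn + fp + fn + tp == n
        n_met = int((noesy_training["y"] == "metastatic").sum())
        n_early = n - n_met
        assert res.accuracy * n == pytest.approx(
            res.sensitivity * n_met + res.specificity * n_early
        )

    def test_fold_losing_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(12, 5))
        y = np.array(["metastatic"] + ["early"] * 11, dtype=object)
        with pytest.raises(ValueError, match="lose class"):
            loocv_evaluate(X, y)

    def test_deterministic(self, noesy_training):
        sel = np.r_[0:30, 110:140]  # balanced slice across both classes
        X, y = noesy_training["X"][sel], noesy_training["y"][sel]
        r1 = loocv_evaluate(X, y)
        r2 = loocv_evaluate(X, y)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)
        np.testing.assert_array_equal(r1.ca_scores, r2.ca_scores)


class TestProjection:
    def test_resubstitution_not_much_below_loocv(self, noesy_training):
        X, y = noesy_training["X"], noesy_training["y"]
        model = fit_fingerprint(X, y)
        resub = (project(model, X).y_pred == y).mean()
        loocv = loocv_evaluate(X, y).accuracy
        assert resub >= loocv - 0.02

    def test_full_metastatic_fraction_tracks_sensitivity(self):
        spec = CohortSpec(relapsed_metastatic_fraction=1.0, seed=21)
        cohort = generate_cohort(spec)
        matrix = assemble_matrix(cohort.spectra["NOESY"])
        groups = cohort.clinical.set_index("id")["group"]
        tr = [i for i, s in enumerate(matrix.sample_ids) if groups[s] != "eCRC_relapsed"]
        rel = [i for i, s in enumerate(matrix.sample_ids) if groups[s] == "eCRC_relapsed"]
        y = np.array(
            ["metastatic" if groups[matrix.sample_ids[i]] == "mCRC" else "early" for i in tr],
            dtype=object,
        )
        res = loocv_evaluate(matrix.values[tr], y)
        model = fit_fingerprint(matrix.values[tr], y)
        frac = (project(model, matrix.values[rel]).y_pred == "metastatic").mean()
        # the projection model is fit on the full training set while LOOCV
        # sensitivity is downward-biased, so the identity is one-sided loose
        assert res.sensitivity - 0.15 <= frac <= min(1.0, res.sensitivity + 0.25)
        assert frac > 0.5

    def test_empty_matrix_empty_result(self, noesy_training):
        model = fit_fingerprint(noesy_training["X"], noesy_training["y"])
        res = project(model, np.empty((0, noesy_training["X"].shape[1])))
        assert len(res.y_pred) == 0

    def test_bin_grid_mismatch_rejected(self, noesy_training):
        model = fit_fingerprint(noesy_training["X"], noesy_training["y"])
        with pytest.raises(ValueError, match="bin-grid mismatch"):
            project(model, np.ones((3, 10)))


class TestStratifyRisk:
    def _result(self, ids, preds):
        from nmrfp.fingerprint import ClassificationResult

        return ClassificationResult(
            sample_ids=ids, y_true=None,
            y_pred=np.array(preds, dtype=object), ca_scores=np.zeros(len(ids)),
        )

    def test_all_early_all_low(self):
        risk = stratify_risk(self._result(["a", "b"], ["early", "early"]),
                             self._result(["c"], ["early"]))
        assert set(risk) == {"low"}

    def test_metastatic_maps_high(self):
        risk = stratify_risk(self._result([], []), self._result(["p"], ["metastatic"]))
        assert risk["p"] == "high"

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            stratify_risk(self._result(["a"], ["early"]), self._result(["a"], ["early"]))
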