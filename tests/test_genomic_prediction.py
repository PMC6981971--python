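import numpy as np
import pandas as pd
import pytest

from phenogs.genomic_prediction import (
    CollinearityError,
    EmptyMatrixError,
    filter_maf,
    fit_rrblup,
    impute_missing,
    independent_validation,
    kfold_cv,
    predict_gebv,
    prediction_accuracy,
)
from phenogs.io_formats import GenotypeMatrix, ValidationError


def gmatrix(dosage, **kw):
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    return GenotypeMatrix(line_ids=[f"L{i}" for i in range(n)],
                          marker_ids=[f"M{j}" for j in range(m)],
                          dosage=dosage, **kw)


def random_gmatrix(n, m, seed, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        dosage[rng.random((n, m)) < missing_rate] = -1
    return gmatrix(dosage)


class TestMafFilter:
    def test_monomorphic_always_removed(self):
        g = gmatrix(np.column_stack([np.zeros(6), [0, 1, 2, 1, 0, 2]]).astype(int))
        kept = filter_maf(g, 0.0)
        assert kept.marker_ids.tolist() == ["M1"]

    def test_boundary_is_strict(self):
        # 10 lines: one marker with exactly MAF 0.05 (1 minor allele / 20)
        col_low = np.zeros(10, int); col_low[0] = 1      # maf 0.05
        col_high = np.zeros(10, int); col_high[:2] = 1   # maf 0.10
        g = gmatrix(np.column_stack([col_low, col_high]))
        kept = filter_maf(g, 0.05)
        assert kept.marker_ids.tolist() == ["M1"]

    def test_hand_counted_retention(self):
        # 50 lines; marker j carries j+1 copies of the minor allele, so
        # mafs are 0.01..0.10 in steps of 0.01; threshold 0.05 keeps 5
        cols = []
        for j in range(10):
            c = np.zeros(50, int)
            c[: j + 1] = 1
            cols.append(c)
        g = gmatrix(np.column_stack(cols))
        kept = filter_maf(g, 0.05)
        assert kept.n_markers == 5
        assert kept.marker_ids.tolist() == [f"M{j}" for j in range(5, 10)]

    def test_empty_result_is_an_error(self):
        g = gmatrix(np.zeros((4, 3), int))
        with pytest.raises(EmptyMatrixError):
            filter_maf(g, 0.05)


class TestImputation:
    def test_no_missing_is_identity(self):
        g = random_gmatrix(10, 8, seed=1)
        for method in ("mean", "ld_knn"):
            out = impute_missing(g, method)
            assert np.array_equal(out.dosage, g.dosage.astype(float))

    def test_unanimous_marker_imputes_unanimously(self):
        d = np.full((6, 2), 2, dtype=int)
        d[:, 1] = [0, 1, 2, 0, 1, 2]
        d[0, 0] = -1
        g = gmatrix(d)
        for method in ("mean", "ld_knn"):
            # minor-allele orientation maps the all-2 column to all-0
            out = impute_missing(g, method)
            assert out.dosage[0, 0] == pytest.approx(out.dosage[1, 0])

    def test_mean_imputation_is_marker_mean(self):
        d = np.array([[0, 0], [2, 0], [-1, 1], [1, 2]])
        g = gmatrix(d)
        out = impute_missing(g, "mean")
        assert out.dosage[2, 0] == pytest.approx(1.0)

    def test_ld_knn_uses_correlated_marker(self):
        # markers 0 and 1 perfectly correlated; line 5 missing marker 0 but
        # carries 2 at marker 1, whose dosage-2 twins all carry 2 at marker 0
        d = np.array([
            [0, 0, 1], [0, 0, 0], [2, 2, 1],
            [2, 2, 2], [0, 0, 1], [-1, 2, 0],
        ])
        g = gmatrix(d)
        out = impute_missing(g, "ld_knn", k=2, l=1)
        assert out.dosage[5, 0] == pytest.approx(2.0)

    def test_fully_missing_marker_is_an_error(self):
        d = np.array([[1, -1], [0, -1], [2, -1]])
        with pytest.raises(ValidationError, match="M1"):
            impute_missing(gmatrix(d), "mean")


class TestRRBlup:
    def test_closed_form_single_marker_ridge(self):
        # centered M = [1, -1]', y = [1, -1]', lambda = 1:
        # u = (M'M + 1)^-1 M'y = 2/3; GEBVs = [2/3, -2/3]
        g = gmatrix([[2], [0]])
        y = pd.Series([1.0, -1.0], index=["L0", "L1"])
        model = fit_rrblup(y, g, lambda_=1.0)
        assert model.u[0] == pytest.approx(2 / 3, abs=1e-12)
        pred = predict_gebv(model, g)
        assert pred.tolist() == pytest.approx([2 / 3, -2 / 3], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_gblup_oracle(self, seed):
        n, m = 15, 60
        g = random_gmatrix(n, m, seed=seed)
        rng = np.random.default_rng(seed + 100)
        y = pd.Series(rng.normal(size=n), index=list(g.line_ids))
        model = fit_rrblup(y, g)
        pred = predict_gebv(model, g)
        # GBLUP oracle with kernel MM' at the same variance ratio
        M = g.dosage_float() - g.dosage_float().mean(axis=0)
        K = M @ M.T
        H = K + model.lambda_ * np.eye(n)
        X = np.ones((n, 1))
        Hi = np.linalg.inv(H)
        beta = np.linalg.solve(X.T @ Hi @ X, X.T @ Hi @ y.to_numpy())
        oracle = X @ beta + K @ Hi @ (y.to_numpy() - X @ beta)
        assert np.abs(pred.to_numpy() - oracle).max() < 1e-8

    def test_coding_invariance_after_centering(self):
        # {0,1,2} vs {-1,0,1}: identical centered matrix, identical GEBVs
        g = random_gmatrix(10, 25, seed=5)
        y = pd.Series(np.random.default_rng(6).normal(size=10),
                      index=list(g.line_ids))
        model = fit_rrblup(y, g, lambda_=3.0)
        pred = predict_gebv(model, g)
        M_shift = (g.dosage_float() - 1.0)       # {-1,0,1} coding
        Mc = M_shift - M_shift.mean(axis=0)
        u = Mc.T @ np.linalg.solve(Mc @ Mc.T + 3.0 * np.eye(10),
                                   y.to_numpy() - y.mean())
        oracle = y.mean() + Mc @ u
        assert np.abs(pred.to_numpy() - oracle).max() < 1e-10

    def test_infinite_shrinkage_returns_grand_mean(self):
        g = random_gmatrix(8, 10, seed=2)
        y = pd.Series(np.random.default_rng(3).normal(size=8),
                      index=list(g.line_ids))
        model = fit_rrblup(y, g, lambda_=1e12)
        pred = predict_gebv(model, g)
        assert np.abs(model.u).max() < 1e-6
        assert pred.to_numpy() == pytest.approx(np.full(8, y.mean()), abs=1e-4)

    def test_constant_response_rejected(self):
        g = random_gmatrix(6, 5, seed=1)
        with pytest.raises(ValidationError):
            fit_rrblup(pd.Series(1.0, index=list(g.line_ids)), g)

    def test_collinear_covariates_named(self):
        g = random_gmatrix(8, 5, seed=4)
        y = pd.Series(np.random.default_rng(1).normal(size=8),
                      index=list(g.line_ids))
        fixed = pd.DataFrame({"a": np.arange(8.0), "b": 2 * np.arange(8.0)},
                             index=list(g.line_ids))
        with pytest.raises(CollinearityError, match="b"):
            fit_rrblup(y, g, fixed)

    def test_missing_calls_must_be_imputed_first(self):
        g = random_gmatrix(8, 5, seed=4, missing_rate=0.2)
        y = pd.Series(np.random.default_rng(1).normal(size=8),
                      index=list(g.line_ids))
        with pytest.raises(ValidationError, match="impute"):
            fit_rrblup(y, g)


class TestPredict:
    def test_training_line_predicts_its_fitted_value(self):
        g = random_gmatrix(10, 30, seed=8)
        y = pd.Series(np.random.default_rng(9).normal(size=10),
                      index=list(g.line_ids))
        model = fit_rrblup(y, g)
        full = predict_gebv(model, g)
        one = predict_gebv(model, g.take_lines(np.array([3])))
        assert one.iloc[0] == pytest.approx(full.iloc[3], abs=1e-12)

    def test_permutation_of_test_lines_permutes_predictions(self):
        g = random_gmatrix(9, 20, seed=10)
        y = pd.Series(np.random.default_rng(11).normal(size=9),
                      index=list(g.line_ids))
        model = fit_rrblup(y, g)
        perm = np.array([4, 0, 8, 2, 6, 1, 7, 3, 5])
        pred = predict_gebv(model, g)
        pred_perm = predict_gebv(model, g.take_lines(perm))
        assert pred_perm.to_numpy() == pytest.approx(pred.to_numpy()[perm])

    def test_marker_mismatch_counts_missing(self):
        g = random_gmatrix(8, 10, seed=12)
        y = pd.Series(np.random.default_rng(13).normal(size=8),
                      index=list(g.line_ids))
        model = fit_rrblup(y, g)
        with pytest.raises(ValidationError, match="3 model markers"):
            predict_gebv(model, g.take_markers(np.arange(7)))

    def test_covariate_policy(self):
        g = random_gmatrix(10, 15, seed=14)
        rng = np.random.default_rng(15)
        y = pd.Series(rng.normal(size=10), index=list(g.line_ids))
        fixed = pd.DataFrame({"ndvi": rng.normal(size=10)}, index=list(g.line_ids))
        model = fit_rrblup(y, g, fixed)
        with pytest.raises(ValidationError, match="covariate"):
            predict_gebv(model, g)  # requires covariates by default
        pred = predict_gebv(model, g, covariate_policy="train-mean")
        assert len(pred) == 10


class TestAccuracy:
    def test_perfect_and_inverted(self):
        obs = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert prediction_accuracy(obs, obs) == pytest.approx(1.0)
        assert prediction_accuracy(obs, -obs) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        obs = pd.Series([1.0, 2, 3], index=list("abc"))
        gebv = pd.Series([1.0, 2, 4], index=list("abc"))
        assert prediction_accuracy(obs, gebv) == pytest.approx(0.98198, abs=1e-4)

    def test_affine_invariance_with_positive_slope(self):
        rng = np.random.default_rng(16)
        obs = pd.Series(rng.normal(size=20), index=range(20))
        gebv = pd.Series(rng.normal(size=20), index=range(20))
        base = prediction_accuracy(obs, gebv)
        assert prediction_accuracy(obs, 3.5 * gebv + 2.0) == pytest.approx(base, abs=1e-12)

    def test_constant_input_rejected(self):
        obs = pd.Series([1.0, 1, 1], index=list("abc"))
        with pytest.raises(ValidationError):
            prediction_accuracy(obs, pd.Series([1.0, 2, 3], index=list("abc")))


class TestKfold:
    def test_fold_sizes_near_equal(self):
        g = random_gmatrix(456, 20, seed=17)
        rng = np.random.default_rng(18)
        y = pd.Series(rng.normal(size=456), index=list(g.line_ids))
        res = kfold_cv(y, g, k=5, seed=0)
        sizes = sorted(res.assignment.value_counts().tolist())
        assert sizes == [91, 91, 91, 91, 92]

    def test_same_seed_reproduces_folds_and_accuracy(self):
        g = random_gmatrix(40, 30, seed=19)
        rng = np.random.default_rng(20)
        y = pd.Series(rng.normal(size=40) + g.dosage_float()[:, 0],
                      index=list(g.line_ids))
        r1 = kfold_cv(y, g, k=4, seed=7)
        r2 = kfold_cv(y, g, k=4, seed=7)
        assert r1.assignment.equals(r2.assignment)
        assert r1.accuracy == r2.accuracy

    def test_pure_noise_has_near_zero_accuracy(self):
        accs = []
        for seed in range(6):
            g = random_gmatrix(80, 150, seed=seed)
            y = pd.Series(np.random.default_rng(seed + 50).normal(size=80),
                          index=list(g.line_ids))
            accs.append(kfold_cv(y, g, k=5, seed=seed).accuracy)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs)) < max(3 * se, 0.08)

    def test_true_covariate_raises_accuracy(self):
        # a covariate equal to the true genetic value plus small noise must
        # strictly beat the marker-only model
        rng = np.random.default_rng(21)
        n, m = 120, 400
        g = random_gmatrix(n, m, seed=22)
        M = g.dosage_float() - g.dosage_float().mean(axis=0)
        u = rng.normal(size=m)
        bv = M @ u
        bv = bv / bv.std()
        y = pd.Series(bv + rng.normal(0, 1.5, n), index=list(g.line_ids))
        cov = pd.DataFrame({"proxy": bv + rng.normal(0, 0.3, n)},
                           index=list(g.line_ids))
        acc0 = kfold_cv(y, g, None, k=5, seed=1).accuracy
        acc1 = kfold_cv(y, g, cov, k=5, seed=1).accuracy
        assert acc1 > acc0


class TestIndependentValidation:
    def test_train_equals_test_matches_in_sample_fit(self):
        g = random_gmatrix(30, 50, seed=23)
        rng = np.random.default_rng(24)
        y = pd.Series(rng.normal(size=30) + g.dosage_float()[:, :5].sum(1) * 0.3,
                      index=list(g.line_ids))
        res = independent_validation((y, g, None), (y, g, None))
        model = fit_rrblup(y, g)
        in_sample = prediction_accuracy(y, predict_gebv(model, g))
        assert res.accuracy == pytest.approx(in_sample, abs=1e-10)

    def test_accuracy_increases_with_heritability(self):
        accs = {}
        for h2 in (0.1, 0.3, 0.5):
            vals = []
            for seed in (1, 2, 3):
                rng = np.random.default_rng(seed)
                n, m = 300, 800
                dos = rng.integers(0, 3, size=(n + 100, m)).astype(np.int8)
                g_all = gmatrix(dos)
                M = g_all.dosage_float() - g_all.dosage_float().mean(axis=0)
                bv = M @ rng.normal(size=m)
                bv = bv / bv.std()
                noise_sd = np.sqrt(1 / h2 - 1)
                y_all = bv + rng.normal(0, noise_sd, n + 100)
                tr, te = np.arange(n), np.arange(n, n + 100)
                y_tr = pd.Series(y_all[tr], index=list(g_all.line_ids[tr]))
                y_te = pd.Series(y_all[te], index=list(g_all.line_ids[te]))
                res = independent_validation(
                    (y_tr, g_all.take_lines(tr), None),
                    (y_te, g_all.take_lines(te), None))
                vals.append(res.accuracy)
            accs[h2] = np.mean(vals)
        assert accs[0.1] < accs[0.3] < accs[0.5]
        assert accs[0.5] > 0

    def test_unrelated_panels_predict_nothing(self):
        vals = []
        for seed in range(4):
            rng = np.random.default_rng(seed + 200)
            g_tr = random_gmatrix(100, 300, seed=seed)
            g_te = random_gmatrix(60, 300, seed=seed + 1000)
            y_tr = pd.Series(rng.normal(size=100), index=list(g_tr.line_ids))
            y_te = pd.Series(rng.normal(size=60),
                             index=[f"T{i}" for i in range(60)])
            g_te = GenotypeMatrix(line_ids=[f"T{i}" for i in range(60)],
                                  marker_ids=g_te.marker_ids,
                                  dosage=g_te.dosage)
            vals.append(independent_validation(
                (y_tr, g_tr, None), (y_te, g_te, None)).accuracy)
        assert abs(np.mean(vals)) < 0.1
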