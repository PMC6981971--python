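"""Ridge-regression BLUP genomic prediction with secondary-trait fixed effects.

The model is y = X beta + M u + e with M the column-centered minor-allele
dosage matrix, u ~ N(0, sigma2_u I) (infinitesimal model: every marker has
the same effect variance, effects shrunk toward zero) and e ~ N(0,
sigma2_e I). X carries the intercept plus optional secondary-trait
covariates (spectral indices measured on the same lines).

The variance ratio lambda = sigma2_e / sigma2_u is estimated once on the
training set by REML, profiled over lambda through the eigendecomposition
of the marker kernel K = M M' (the marker model and GBLUP with kernel K
are the same model, so the n x n decomposition suffices whatever the
marker count). Marker effects then follow from the dual ridge identity
u = M' (K + lambda I)^-1 (y - X beta_hat).

Also here: minor-allele-frequency filtering, mean and LD-k-nearest-
neighbour imputation, k-fold cross-validation, independent train/test
validation, and Pearson prediction accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_formats import GenotypeMatrix, ValidationError


class EmptyMatrixError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# marker QC and imputation
# ---------------------------------------------------------------------------


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain markers with MAF strictly greater than ``threshold``."""
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    keep = np.flatnonzero(g.maf > threshold)
    if keep.size == 0:
        raise EmptyMatrixError(f"no markers pass MAF > {threshold}")
    return g.take_markers(keep)


def impute_missing(g: GenotypeMatrix, method: str = "mean",
                   k: int = 10, l: int = 30) -> GenotypeMatrix:
    """Fill missing dosages; returns a fractional-dosage matrix.

    ``mean``: marker mean of non-missing calls. ``ld_knn``: for each missing
    cell, take the ``l`` markers most correlated (r^2 over complete pairs)
    with the target marker, rank lines by matching distance on those
    markers, and impute the inverse-distance-weighted mean of the ``k``
    nearest lines' calls. Deterministic given the data.
    """
    d = g.dosage_float()
    miss = np.isnan(d)
    all_missing = np.flatnonzero(miss.all(axis=0))
    if all_missing.size:
        raise ValidationError(
            f"markers with 100% missing calls: {g.marker_ids[all_missing].tolist()}"
        )
    if not miss.any():
        out = d
    elif method == "mean":
        col_means = np.nanmean(d, axis=0)
        out = np.where(miss, col_means[None, :], d)
    elif method == "ld_knn":
        out = _impute_ld_knn(d, k=k, l=l)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return GenotypeMatrix(
        line_ids=g.line_ids,
        marker_ids=g.marker_ids,
        dosage=out,
        chrom=g.chrom,
        pos=g.pos,
        flipped=g.flipped,
        fractional=True,
    )


def _pairwise_r2(d: np.ndarray, j: int) -> np.ndarray:
    """Squared Pearson correlation of marker j with every marker, over
    lines where both calls are present."""
    n, m = d.shape
    x = d[:, j]
    ok_x = ~np.isnan(x)
    r2 = np.full(m, np.nan)
    for kcol in range(m):
        if kcol == j:
            continue
        ok = ok_x & ~np.isnan(d[:, kcol])
        if ok.sum() < 3:
            continue
        xv, yv = x[ok], d[ok, kcol]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            continue
        r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
        r2[kcol] = r * r
    return r2


def _impute_ld_knn(d: np.ndarray, k: int, l: int) -> np.ndarray:
    out = d.copy()
    eps = 1e-6
    for j in np.flatnonzero(np.isnan(d).any(axis=0)):
        r2 = _pairwise_r2(d, j)
        order = np.argsort(-np.nan_to_num(r2, nan=-1.0), kind="stable")
        sites = order[: min(l, np.isfinite(r2).sum())]
        donors = np.flatnonzero(~np.isnan(d[:, j]))
        for i in np.flatnonzero(np.isnan(d[:, j])):
            if sites.size:
                diff = np.abs(d[np.ix_(donors, sites)] - d[i, sites][None, :]) / 2.0
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", category=RuntimeWarning)
                    dist = np.nanmean(diff, axis=1)
                dist = np.where(np.isnan(dist), 1.0, dist)
            else:
                dist = np.zeros(donors.size)
            nearest = np.argsort(dist, kind="stable")[: min(k, donors.size)]
            w = 1.0 / (dist[nearest] + eps)
            out[i, j] = float(np.sum(w * d[donors[nearest], j]) / np.sum(w))
    return out


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------


@dataclass
class GSModel:
    """Fitted RRBLUP state sufficient to reproduce predictions bit-exactly."""

    beta: np.ndarray
    beta_names: list[str]
    u: np.ndarray
    lambda_: float
    sigma2_u: float
    sigma2_eps: float
    marker_ids: np.ndarray
    centering: np.ndarray  # training-set column means of dosage
    flipped: np.ndarray    # training orientation relative to source coding
    covariates: list[str] = field(default_factory=list)
    covariate_means: np.ndarray | None = None


@dataclass
class PredictionResult:
    gebv: pd.Series
    accuracy: float
    assignment: pd.Series | None = None
    per_fold: list[float] | None = None
    scenario: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _design(fixed: pd.DataFrame | None, lines: np.ndarray) -> tuple[np.ndarray, list[str]]:
    X = [np.ones((len(lines), 1))]
    names = ["intercept"]
    if fixed is not None and len(fixed.columns):
        missing = [li for li in lines if li not in fixed.index]
        if missing:
            raise ValidationError(f"covariates missing for {len(missing)} lines")
        vals = fixed.loc[list(lines)].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("NaN covariate values for training lines")
        X.append(vals)
        names += list(fixed.columns)
    Xm = np.concatenate(X, axis=1)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise CollinearityError(f"rank-deficient fixed-effect design; columns: {names}")
    return Xm, names


def _reml_lambda(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> tuple[float, float]:
    """Profile REML for delta = sigma2_e/sigma2_u on eigenvalues of SKS.

    Returns (delta, sigma2_u)."""
    n, p = X.shape
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    SKS = S @ K @ S
    SKS = 0.5 * (SKS + SKS.T)
    w, U = np.linalg.eigh(SKS)
    order = np.argsort(w)[::-1][: n - p]  # non-null spectrum
    xi = np.maximum(w[order], 0.0)
    eta = U[:, order].T @ y
    eta2 = eta**2

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = xi + delta
        s2u = np.sum(eta2 / denom) / (n - p)
        if s2u <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(s2u) + np.log(denom).sum())

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_restricted_ll, bracket=None,
                          bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
                          options={"xatol": 1e-10})
    log_delta = res.x if res.fun <= vals.min() else g0
    delta = float(np.exp(log_delta))
    s2u = float(np.sum(eta2 / (xi + delta)) / (n - p))
    return delta, s2u


def fit_rrblup(y: pd.Series, g: GenotypeMatrix,
               fixed: pd.DataFrame | None = None,
               lambda_: float | None = None) -> GSModel:
    """Fit RRBLUP on the training lines of ``y``.

    ``lambda_`` overrides the REML shrinkage estimate (useful for oracle
    checks and forced-shrinkage limits). Missing genotype calls must be
    imputed first.
    """
    lines = np.asarray(y.index, dtype=object)
    line_pos = {li: i for i, li in enumerate(g.line_ids)}
    absent = [li for li in lines if li not in line_pos]
    if absent:
        raise ValidationError(f"{len(absent)} phenotyped lines absent from genotypes")
    if len(lines) < 2:
        raise ValidationError("need >= 2 training lines")
    yv = y.to_numpy(dtype=float)
    if np.nanstd(yv) == 0:
        raise ValidationError("constant response; RRBLUP undefined")
    d = g.dosage_float()[[line_pos[li] for li in lines], :]
    if np.isnan(d).any():
        raise ValidationError("missing genotype calls present; run impute_missing first")
    centering = d.mean(axis=0)
    M = d - centering[None, :]
    X, names = _design(fixed, lines)
    K = M @ M.T
    if lambda_ is None:
        delta, s2u = _reml_lambda(yv, X, K)
    else:
        delta, s2u = float(lambda_), np.nan
    # GLS beta under V propto (K + delta I)
    H = K + delta * np.eye(len(lines))
    Hinv_X = np.linalg.solve(H, X)
    Hinv_y = np.linalg.solve(H, yv)
    beta = np.linalg.solve(X.T @ Hinv_X, X.T @ Hinv_y)
    resid = yv - X @ beta
    u = M.T @ np.linalg.solve(H, resid)
    cov_names = names[1:]
    return GSModel(
        beta=beta, beta_names=names, u=u, lambda_=delta,
        sigma2_u=s2u, sigma2_eps=(s2u * delta if np.isfinite(s2u) else np.nan),
        marker_ids=g.marker_ids.copy(), centering=centering,
        flipped=g.flipped.copy(), covariates=cov_names,
        covariate_means=(None if fixed is None or not cov_names
                         else fixed.loc[list(lines), cov_names].to_numpy(float).mean(axis=0)),
    )


def predict_gebv(model: GSModel, g_test: GenotypeMatrix,
                 fixed_test: pd.DataFrame | None = None,
                 covariate_policy: str = "require") -> pd.Series:
    """Predicted values X_test beta + M_test u, using training centering.

    Test markers are matched to the model's markers by id; orientation is
    aligned through the recorded per-panel minor-allele flips so both
    panels count the same allele. For a model with covariates,
    ``covariate_policy='require'`` errors when test covariates are absent;
    ``'train-mean'`` substitutes the training means (an extrapolation).
    """
    pos = {mid: j for j, mid in enumerate(g_test.marker_ids)}
    missing = [mid for mid in model.marker_ids if mid not in pos]
    if missing:
        raise ValidationError(f"{len(missing)} model markers absent from test panel")
    idx = [pos[mid] for mid in model.marker_ids]
    d = g_test.dosage_float()[:, idx]
    if np.isnan(d).any():
        raise ValidationError("missing genotype calls in test panel; impute first")
    # re-express the test dosage in the training orientation
    mismatch = g_test.flipped[idx] ^ model.flipped
    d[:, mismatch] = 2.0 - d[:, mismatch]
    M = d - model.centering[None, :]
    pred = M @ model.u
    if model.covariates:
        if fixed_test is not None:
            absent = [li for li in g_test.line_ids if li not in fixed_test.index]
            if absent:
                raise ValidationError(f"test covariates missing for {len(absent)} lines")
            Xc = fixed_test.loc[list(g_test.line_ids), model.covariates].to_numpy(float)
        elif covariate_policy == "train-mean":
            Xc = np.tile(model.covariate_means, (g_test.n_lines, 1))
        else:
            raise ValidationError(
                "model has covariates but no test covariates given "
                "(use covariate_policy='train-mean' to extrapolate)"
            )
        X = np.concatenate([np.ones((g_test.n_lines, 1)), Xc], axis=1)
    else:
        X = np.ones((g_test.n_lines, 1))
    pred = pred + X @ model.beta
    return pd.Series(pred, index=list(g_test.line_ids))


# ---------------------------------------------------------------------------
# validation schemes
# ---------------------------------------------------------------------------


def prediction_accuracy(observed: pd.Series, gebv: pd.Series) -> float:
    """Pearson correlation between observed values and predictions."""
    common = observed.index.intersection(gebv.index)
    if len(common) < 3:
        raise ValidationError("need >= 3 paired values for an accuracy")
    a = observed.loc[common].to_numpy(float)
    b = gebv.loc[common].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("constant values; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def kfold_cv(y: pd.Series, g: GenotypeMatrix,
             fixed: pd.DataFrame | None = None,
             k: int = 5, seed: int = 0,
             lambda_per_fold: bool = False) -> PredictionResult:
    """Seeded k-fold cross-validation; accuracy per fold, then averaged.

    By default the shrinkage parameter is re-estimated per training split
    only when ``lambda_per_fold`` is set; otherwise it is estimated once on
    the full data and reused (standard rrBLUP practice).
    """
    n = len(y)
    if k < 2 or n < k:
        raise ValidationError("need k >= 2 and n >= k")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    lam = None
    if not lambda_per_fold:
        lam = fit_rrblup(y, g, fixed).lambda_
    gebv = pd.Series(np.nan, index=y.index, dtype=float)
    assignment = pd.Series(-1, index=y.index, dtype=int)
    per_fold = []
    lines = np.asarray(y.index, dtype=object)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        train_lines, test_lines = lines[train_idx], lines[test_idx]
        model = fit_rrblup(y.loc[train_lines], g, fixed, lambda_=lam)
        keep = np.isin(g.line_ids, test_lines)
        g_fold = g.take_lines(np.flatnonzero(keep))
        pred = predict_gebv(model, g_fold,
                            None if fixed is None else fixed)
        gebv.loc[pred.index] = pred
        assignment.loc[list(test_lines)] = f
        obs = y.loc[list(test_lines)]
        if obs.std() == 0:
            warnings.warn(f"fold {f}: constant observed values; accuracy excluded")
            continue
        per_fold.append(prediction_accuracy(obs, pred))
    acc = float(np.mean(per_fold)) if per_fold else np.nan
    return PredictionResult(gebv=gebv, accuracy=acc, assignment=assignment,
                            per_fold=per_fold,
                            scenario={"k": k, "seed": seed,
                                      "covariates": [] if fixed is None else list(fixed.columns)})


def independent_validation(train: tuple, test: tuple,
                           covariate_policy: str = "require") -> PredictionResult:
    """Fit on one panel, predict another; accuracy on the test panel.

    ``train`` and ``test`` are (y, genotype_matrix, fixed-or-None) triples.
    Panels are intersected on shared marker ids before fitting.
    """
    y_tr, g_tr, f_tr = train
    y_te, g_te, f_te = test
    shared = [mid for mid in g_tr.marker_ids if mid in set(g_te.marker_ids)]
    if not shared:
        raise ValidationError("no shared markers between panels")
    tr_idx = np.flatnonzero(np.isin(g_tr.marker_ids, shared))
    model = fit_rrblup(y_tr, g_tr.take_markers(tr_idx), f_tr)
    pred = predict_gebv(model, g_te, f_te, covariate_policy=covariate_policy)
    acc = prediction_accuracy(y_te, pred)
    return PredictionResult(
        gebv=pred, accuracy=acc,
        scenario={"n_train": len(y_tr), "n_test": len(y_te),
                  "n_markers": len(shared),
                  "covariates": [] if f_tr is None else list(f_tr.columns)},
    )
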