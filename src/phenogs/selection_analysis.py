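"""Empirical selection comparisons and least-squares index-to-yield models.

``selection_overlap`` mimics a breeder's shortlist comparison: take the
top fraction q of entries by yield and by a candidate criterion (a
spectral index), and report what percentage of the top-yield set the
criterion recovered. Criteria negatively correlated with yield (the water
index) are ranked from the low end under ``direction='auto'``.

``fit_ls_yield_model`` regresses yield on spectral indices across growth
stages by ordinary least squares, reporting RMSE = sqrt(SSE/n), a Gaussian
BIC = n*ln(SSE/n) + p*ln(n), and the predicted-vs-actual correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SelectionReport:
    criterion: str
    q: float
    direction: str          # resolved direction: high | low
    selected: list          # entries picked by the criterion
    top_yield: list         # entries in the top-q yield set
    overlap_percent: float
    n_selected: int = 0

    def __post_init__(self):
        self.n_selected = len(self.selected)


@dataclass
class LSYieldModel:
    coefficients: pd.Series
    rmse: float
    bic: float
    correlation: float
    n: int
    environment: str | None = None
    dropped_terms: list = field(default_factory=list)
    predicted: pd.Series | None = None


def _top_set(values: pd.Series, q: float, high: bool) -> set:
    """Top-q entries by value; threshold ties are all included, so the
    realized set can exceed ceil(q*n)."""
    n = len(values)
    k = int(np.ceil(q * n))
    ranked = values.sort_values(ascending=not high, kind="stable")
    threshold = ranked.iloc[k - 1]
    if high:
        return set(values.index[values >= threshold])
    return set(values.index[values <= threshold])


def selection_overlap(yield_values: pd.Series, criterion_values: pd.Series,
                      q: float = 0.25, direction: str = "auto",
                      criterion_name: str = "criterion") -> SelectionReport:
    """Percent of the top-q yield entries recovered by criterion ranking."""
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    common = yield_values.index.intersection(criterion_values.index)
    if q * len(common) < 1:
        raise ValueError("q*n < 1: selected set would be empty")
    yv = yield_values.loc[common]
    cv = criterion_values.loc[common]
    if direction == "auto":
        r = np.corrcoef(yv.to_numpy(float), cv.to_numpy(float))[0, 1]
        direction = "low" if r < 0 else "high"
    if direction not in ("high", "low"):
        raise ValueError("direction must be high, low, or auto")
    top_yield = _top_set(yv, q, high=True)
    selected = _top_set(cv, q, high=(direction == "high"))
    pct = 100.0 * len(top_yield & selected) / len(top_yield)
    return SelectionReport(
        criterion=criterion_name, q=q, direction=direction,
        selected=sorted(selected), top_yield=sorted(top_yield),
        overlap_percent=pct,
    )


def fit_ls_yield_model(sri_table: pd.DataFrame, yield_values: pd.Series,
                       environment: str | None = None,
                       rmse_denominator: str = "n") -> LSYieldModel:
    """OLS of yield on spectral-index columns of ``sri_table``.

    Rows with missing covariates are dropped (and logged via the returned
    model's ``n``); collinear columns are dropped with a warning.
    """
    common = sri_table.index.intersection(yield_values.index)
    X_df = sri_table.loc[common].apply(pd.to_numeric)
    y = yield_values.loc[common].astype(float)
    ok = ~(X_df.isna().any(axis=1) | y.isna())
    X_df, y = X_df.loc[ok], y.loc[ok]
    n = len(y)
    terms = list(X_df.columns)
    dropped = []
    X = np.concatenate([np.ones((n, 1)), X_df.to_numpy(float)], axis=1)
    # drop collinear terms left-to-right until full rank
    while np.linalg.matrix_rank(X) < X.shape[1] and terms:
        for j, t in enumerate(terms):
            trial = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                warnings.warn(f"dropping collinear term {t!r}")
                dropped.append(t)
                terms.pop(j)
                X = trial
                break
        else:
            break
    p = X.shape[1]
    if n <= p:
        raise ValueError(f"need n > {p} fitted parameters, got n = {n}")
    coef, _, _, _ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    pred = X @ coef
    sse = float(np.sum((y.to_numpy() - pred) ** 2))
    denom = n if rmse_denominator == "n" else n - p
    rmse = float(np.sqrt(sse / denom))
    with np.errstate(divide="ignore"):
        bic = n * np.log(sse / n) + p * np.log(n) if sse > 0 else -np.inf
    corr = (float(np.corrcoef(y, pred)[0, 1])
            if np.std(pred) > 0 and np.std(y) > 0 else np.nan)
    return LSYieldModel(
        coefficients=pd.Series(coef, index=["intercept"] + terms),
        rmse=rmse, bic=float(bic), correlation=corr, n=n,
        environment=environment, dropped_terms=dropped,
        predicted=pd.Series(pred, index=y.index),
    )
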