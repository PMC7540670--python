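"""Predictors of map performance and AICc multimodel inference.

Computes occurrence-geometry predictors (point count, density per
10,000 km^2, Moran's I of per-cell counts) and performs exhaustive
main-effects multimodel inference: every non-empty predictor subset is
fit by OLS, assigned an AICc-based Akaike weight, and per-predictor
importance is the summed weight of models containing that predictor;
predictors with importance >= 0.8 (configurable) are deemed important
and refit as a single linear model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse

from .geometry import StudyArea
from .scoring import GridSpec

__all__ = [
    "grid_rook_weights",
    "morans_i",
    "occurrence_predictors",
    "enumerate_models",
    "fit_and_weigh",
    "select_important",
    "ModelEnsemble",
]

DEFAULT_IMPORTANCE_THRESHOLD = 0.8
MAX_PREDICTORS = 16


def grid_rook_weights(grid: GridSpec, queen: bool = False) -> sparse.csr_matrix:
    """Row-standardized contiguity weights over the masked cells of a grid.

    Rook contiguity (shared edge) by default; ``queen=True`` adds
    diagonal neighbours.  Cells with no masked neighbour get a zero row.
    """
    m = grid.mask
    idx = -np.ones(m.shape, dtype=int)
    idx[m] = np.arange(m.sum())
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if queen:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = [], []
    ri, ci = np.nonzero(m)
    for dr, dc in offsets:
        rj, cj = ri + dr, ci + dc
        ok = (rj >= 0) & (rj < m.shape[0]) & (cj >= 0) & (cj < m.shape[1])
        ok[ok] &= m[rj[ok], cj[ok]]
        rows.append(idx[ri[ok], ci[ok]])
        cols.append(idx[rj[ok], cj[ok]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    W = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(int(m.sum()), int(m.sum()))
    )
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    return sparse.diags(inv) @ W


def morans_i(values: np.ndarray, weights: sparse.spmatrix) -> float:
    """Moran's I spatial autocorrelation statistic.

    I = (n / W_sum) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z = x - mean(x):
    1 for perfect clustering of similar values, ~0 for spatial
    randomness (expectation -1/(n-1)), -1 for perfect alternation.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 cells")
    w_sum = weights.sum()
    if w_sum <= 0:
        raise ValueError("weight structure has zero total weight")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: values are constant")
    num = float(z @ (weights @ z))
    return (n / w_sum) * num / denom


def occurrence_predictors(
    points: np.ndarray, study_area: StudyArea, grid: GridSpec
) -> dict[str, float]:
    """Occurrence-geometry predictors for one species.

    Returns n_points (count inside S), point_density (count per
    10,000 km^2 of S), and Moran's I of per-cell occurrence counts with
    row-standardized rook weights on the study grid.
    """
    from shapely import contains_xy

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of lon/lat")
    inside = contains_xy(study_area.geom, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("no occurrence points inside the study area")
    row, col = grid.cell_index(pts[:, 0], pts[:, 1])
    counts = np.zeros((grid.n_rows, grid.n_cols))
    np.add.at(counts, (row, col), 1.0)
    W = grid_rook_weights(grid)
    mi = morans_i(counts[grid.mask], W)
    density = len(pts) / (study_area.area_km2 / 1e4)
    return {"n_points": float(len(pts)), "morans_i": mi, "point_density": density}


@dataclass
class ModelEnsemble:
    """Exhaustive main-effects OLS ensemble with AICc Akaike weights."""

    models: pd.DataFrame  # predictors, k, rss, aicc, delta_aicc, weight, adj_r2
    importance: pd.Series  # per-predictor summed weight
    response: str
    n: int


def enumerate_models(predictors: list[str]) -> list[tuple[str, ...]]:
    """All 2^p - 1 non-empty main-effects predictor subsets.

    No interactions; the intercept is implicit in every fitted model.
    Guarded at 16 predictors (65,535 models).
    """
    p = len(predictors)
    if p < 1:
        raise ValueError("need at least one predictor")
    if p > MAX_PREDICTORS:
        raise ValueError(f"combinatorial guard: more than {MAX_PREDICTORS} predictors")
    return list(
        chain.from_iterable(combinations(predictors, r) for r in range(1, p + 1))
    )


def _design_columns(table: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    """Dummy-code categoricals (first level reference); a categorical enters
    as its full dummy block."""
    cols = []
    for name in predictors:
        s = table[name]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            d = pd.get_dummies(s, prefix=name, drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(s.astype(float).to_frame(name))
    return pd.concat(cols, axis=1)


def aicc_ols(n: int, rss: float, n_coef: int) -> float:
    """Small-sample AIC for a least-squares fit.

    k counts the regression coefficients plus the residual variance
    (Burnham–Anderson convention):
    AICc = n log(RSS/n) + 2k + 2k(k+1)/(n-k-1).
    """
    k = n_coef + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_and_weigh(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
) -> ModelEnsemble:
    """Fit every main-effects OLS model and assign AICc Akaike weights.

    Akaike weights are exp(-delta_m/2) normalized over the candidate
    set; per-predictor importance is the summed weight of the models
    containing it.  Rank-deficient models are dropped with a warning and
    weights renormalized.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    if table[response].isna().any():
        raise ValueError("missing values in the response")
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    subsets = enumerate_models(list(predictors))

    records = []
    for subset in subsets:
        X = _design_columns(table, subset)
        Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        n_coef = Xc.shape[1]
        if n <= n_coef + 2:
            raise ValueError(
                f"n={n} too small for the largest model (k={n_coef}); AICc undefined"
            )
        if np.linalg.matrix_rank(Xc) < n_coef:
            warnings.warn(f"rank-deficient design for {subset}; model dropped", stacklevel=2)
            continue
        fit = sm.OLS(y, Xc).fit()
        rss = float(fit.ssr)
        records.append(
            {
                "predictors": subset,
                "k": n_coef + 1,
                "rss": rss,
                "aicc": aicc_ols(n, rss, n_coef),
                "adj_r2": float(fit.rsquared_adj),
            }
        )
    if not records:
        raise ValueError("no estimable models")
    df = pd.DataFrame.from_records(records)
    df["delta_aicc"] = df["aicc"] - df["aicc"].min()
    rel = np.exp(-df["delta_aicc"] / 2.0)
    df["weight"] = rel / rel.sum()
    df = df.sort_values("aicc", ignore_index=True)

    importance = pd.Series(
        {
            name: float(df.loc[df["predictors"].map(lambda s: name in s), "weight"].sum())
            for name in predictors
        },
        name="importance",
    )
    return ModelEnsemble(models=df, importance=importance, response=response, n=n)


@dataclass
class ImportantModel:
    """Refit of the linear model on the important predictors only."""

    predictors: list[str]
    adj_r2: float | None
    adj_r2_truncated: float | None
    coefficients: dict[str, float] = field(default_factory=dict)


def select_important(
    ensemble: ModelEnsemble,
    table: pd.DataFrame,
    threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
) -> ImportantModel:
    """Predictors with importance >= threshold, refit as one OLS model.

    An empty selection returns an empty model with a warning (the
    procedure is silent on this case).
    """
    selected = [p for p, v in ensemble.importance.items() if v >= threshold]
    if not selected:
        warnings.warn("no predictor reaches the importance threshold", stacklevel=2)
        return ImportantModel(predictors=[], adj_r2=None, adj_r2_truncated=None)
    y = table[ensemble.response].to_numpy(dtype=float)
    X = _design_columns(table, tuple(selected))
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    coefs = dict(zip(["intercept"] + list(X.columns), (float(b) for b in fit.params)))
    adj = float(fit.rsquared_adj)
    return ImportantModel(
        predictors=selected,
        adj_r2=adj,
        adj_r2_truncated=max(adj, 0.0),
        coefficients=coefs,
    )
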