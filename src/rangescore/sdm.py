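"""Log-linear inhomogeneous Poisson point-process (IPP) intensity fitting.

The occurrence pattern is modelled as an IPP with intensity
log lambda(s) = beta0 + sum_k beta_k x_k(s), where x_k are per-cell
environmental covariates.  The log-likelihood is evaluated with a
Berman–Turner style quadrature on the scoring grid (cell centers as
quadrature nodes, geodesic cell areas as weights):

    loglik(beta) = sum_i log lambda(s_i) - sum_j lambda(c_j) a_j.

This is concave in beta; it is maximized by quasi-Newton iteration with
the analytic gradient.  The fitted per-cell integrated intensities
lambda_bar_j = lambda(c_j) a_j feed the occupancy-probability surface.
For any model with an intercept the score equation forces
sum_j lambda_bar_j = n (the observed point count) at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .scoring import GridSpec

__all__ = ["CovariateStack", "IntensityModel", "ipp_loglik", "fit_ipp", "predict_lambda_bar"]


@dataclass
class CovariateStack:
    """Per-cell covariate values on a GridSpec.

    ``values`` has shape (k, n_rows, n_cols); standardization parameters
    (mean, sd inside the mask) are recorded when fitting standardizes
    the stack, so coefficients can be reported on the natural scale.
    """

    values: np.ndarray
    names: list[str]
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_3d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 3 or self.values.shape[0] != len(self.names):
            raise ValueError("values must be (k, n_rows, n_cols) matching names")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @classmethod
    def empty(cls, grid: GridSpec) -> "CovariateStack":
        return cls(np.zeros((0, grid.n_rows, grid.n_cols)), [])


@dataclass
class IntensityModel:
    """A fitted log-linear IPP intensity.

    ``beta`` is on the standardized-covariate scale used internally;
    ``beta_natural`` on the original covariate scale.  Standard errors
    come from the inverse observed information at the optimum.
    """

    beta: np.ndarray
    beta_natural: np.ndarray
    covariate_names: list[str]
    fit_loglik: float
    converged: bool
    grad_norm: float
    se: np.ndarray | None = None
    se_natural: np.ndarray | None = None
    means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sds: np.ndarray = field(default_factory=lambda: np.ones(0))

    def to_dict(self) -> dict:
        return {
            "covariate_names": list(self.covariate_names),
            "beta_standardized": [float(b) for b in self.beta],
            "beta_natural": [float(b) for b in self.beta_natural],
            "se_natural": None if self.se_natural is None else [float(s) for s in self.se_natural],
            "loglik": float(self.fit_loglik),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
        }


def _design(covariates: CovariateStack, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix with intercept over masked cells, and cell areas."""
    m = grid.mask
    n_masked = int(m.sum())
    X = np.ones((n_masked, covariates.k + 1))
    for i in range(covariates.k):
        band = covariates.values[i]
        if np.any(~np.isfinite(band[m])):
            raise ValueError(f"covariate '{covariates.names[i]}' has missing values inside the mask")
        X[:, i + 1] = band[m]
    return X, grid.cell_areas_km2[m]


def _point_rows(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Masked-cell flat index for each point; error if any falls off the mask."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of lon/lat")
    row, col = grid.cell_index(pts[:, 0], pts[:, 1])
    bad = (row < 0) | (row >= grid.n_rows) | (col < 0) | (col >= grid.n_cols)
    inside = ~bad
    off_mask = np.zeros(len(pts), dtype=bool)
    off_mask[bad] = True
    off_mask[inside] = ~grid.mask[row[inside], col[inside]]
    if off_mask.any():
        idx = np.flatnonzero(off_mask)
        raise ValueError(
            f"{len(idx)} occurrence point(s) fall outside the masked study area "
            f"(rows {idx[:10].tolist()}{'...' if len(idx) > 10 else ''})"
        )
    # position of each point's cell among masked cells, in mask raveled order
    flat_masked = np.flatnonzero(grid.mask.ravel())
    lookup = -np.ones(grid.n_rows * grid.n_cols, dtype=int)
    lookup[flat_masked] = np.arange(len(flat_masked))
    return lookup[row * grid.n_cols + col]


def ipp_loglik(
    beta: np.ndarray, points: np.ndarray, covariates: CovariateStack, grid: GridSpec
) -> float:
    """IPP quadrature log-likelihood at ``beta`` (natural covariate scale)."""
    X, a = _design(covariates, grid)
    rows = _point_rows(points, grid)
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    return float(np.sum(eta[rows]) - np.sum(np.exp(eta) * a))


def fit_ipp(
    points: np.ndarray,
    covariates: CovariateStack | None,
    grid: GridSpec,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_points: int | None = None,
) -> IntensityModel:
    """Maximize the IPP log-likelihood by quasi-Newton (BFGS) iteration.

    Covariates are standardized to zero mean / unit variance inside the
    mask before optimization; coefficients are reported on both scales.
    Non-convergence returns a model flagged ``converged=False`` with a
    warning rather than raising.
    """
    if covariates is None:
        covariates = CovariateStack.empty(grid)
    pts = np.asarray(points, dtype=float)
    floor = max(10, 2 * covariates.k) if min_points is None else min_points
    if len(pts) == 0:
        raise ValueError("no points")
    if len(pts) < floor:
        raise ValueError(f"need at least {floor} points to fit {covariates.k} covariates")

    X, a = _design(covariates, grid)
    rows = _point_rows(pts, grid)
    # standardize covariate columns (not the intercept)
    means = X[:, 1:].mean(axis=0)
    sds = X[:, 1:].std(axis=0)
    sds[sds == 0] = 1.0
    Xs = X.copy()
    Xs[:, 1:] = (X[:, 1:] - means) / sds
    sum_x_points = Xs[rows].sum(axis=0)
    n = len(pts)

    def negloglik_grad(beta):
        eta = Xs @ beta
        lam_bar = np.exp(eta) * a
        ll = float(np.sum(eta[rows]) - lam_bar.sum())
        grad = sum_x_points - Xs.T @ lam_bar
        return -ll, -grad

    if init is None:
        beta0 = np.zeros(Xs.shape[1])
        beta0[0] = np.log(n / a.sum())  # homogeneous MLE start
    else:
        beta0 = np.asarray(init, dtype=float)

    res = minimize(
        negloglik_grad,
        beta0,
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    beta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or grad_norm <= max(tol, 1e-6 * n))
    if not converged:
        warnings.warn(f"IPP fit did not converge (grad norm {grad_norm:.3g})", stacklevel=2)

    # observed information (standardized scale) and covariance
    lam_bar = np.exp(Xs @ beta) * a
    H = Xs.T @ (Xs * lam_bar[:, None])
    se = None
    se_nat = None
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
        J = np.eye(len(beta))
        J[0, 1:] = -means / sds
        for i, s in enumerate(sds, start=1):
            J[i, i] = 1.0 / s
        cov_nat = J @ cov @ J.T
        se_nat = np.sqrt(np.diag(cov_nat))
    except np.linalg.LinAlgError:
        pass

    beta_nat = beta.copy()
    beta_nat[1:] = beta[1:] / sds
    beta_nat[0] = beta[0] - np.sum(beta[1:] * means / sds)

    return IntensityModel(
        beta=beta,
        beta_natural=beta_nat,
        covariate_names=["intercept"] + list(covariates.names),
        fit_loglik=float(-res.fun),
        converged=converged,
        grad_norm=grad_norm,
        se=se,
        se_natural=se_nat,
        means=means,
        sds=sds,
    )


def predict_lambda_bar(
    model: IntensityModel,
    covariates: CovariateStack | None,
    grid: GridSpec,
    allow_unconverged: bool = False,
) -> np.ndarray:
    """Per-cell integrated intensity lambda_bar_j = exp(beta' x(c_j)) * a_j.

    Returns a full (n_rows, n_cols) array, zero outside the mask.
    """
    if not model.converged and not allow_unconverged:
        raise ValueError("model did not converge; pass allow_unconverged=True to override")
    if covariates is None:
        covariates = CovariateStack.empty(grid)
    if covariates.k != len(model.covariate_names) - 1:
        raise ValueError("covariate stack does not match the fitted model")
    X, a = _design(covariates, grid)
    eta = X @ model.beta_natural
    lb = np.zeros((grid.n_rows, grid.n_cols))
    lb[grid.mask] = np.exp(eta) * a
    return lb
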