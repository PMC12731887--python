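"""Node-wise penalized regression estimator for the cross-lagged network.

One L1-penalized regression per T2 outcome node on all 11 standardized T1
predictors; the 11 fitted coefficient vectors are assembled into the
directed adjacency matrix (rows = T1 predictors, columns = T2 outcomes).

Model family
------------
The default is a Gaussian linear LASSO on z-scored continuous subscale
scores, so coefficients are standardized effects and the per-node penalty
trades prediction error against sparsity.  An optional logistic mode
median-dichotomizes each T2 outcome and fits an L1 logistic regression,
matching the odds-ratio reading of the reporting transform literally.  In
either mode, reported edge weights are the raw coefficients and their
elementwise exponentials ("odds ratios").

Covariates (age and categorical demographics) are adjustment terms, not
network candidates: in Gaussian mode they enter unpenalized, implemented by
exact partialling — outcome and lagged predictors are residualized on the
covariate design before the lasso, which yields the same solution as an
L1 problem with unpenalized covariate columns.  In logistic mode covariates
are appended as penalized columns (no exact partialling exists for GLMs).

The penalty weight per node is chosen by K-fold cross-validation over a
geometric path (minimum-CV-error rule by default, one-standard-error rule
optional); folds are seeded, so estimation is deterministic.  Gaussian
lasso problems are solved by the package's Gram-based coordinate-descent
path solver (see :mod:`clpn._solver`), which keeps resampling-heavy
diagnostics fast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from ._solver import cd_path, lasso_at

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .labels import NODE_CODES, NODES, t2_column
from .network import CLPNetwork
from .panel import PanelDataset

MIN_SUBJECTS = 30


@dataclass(frozen=True)
class EstimationSettings:
    """Settings shared by all node fits.

    mode            "gaussian" (default) or "logistic" (median split of T2).
    n_folds         cross-validation folds for the penalty path.
    lambda_rule     "min" (CV-error minimum) or "1se".
    n_lambdas       points on the geometric penalty path.
    lambda_min_ratio  smallest path point relative to the null penalty.
    fixed_lambda    bypass CV with a forced penalty (scalar, or per-node
                    array of length 11); 0 means unpenalized, inf the empty
                    network.
    use_covariates  adjust for the covariate table when present.
    seed            fold shuffling seed (network estimation is deterministic
                    given this).
    """

    mode: str = "gaussian"
    n_folds: int = 10
    lambda_rule: str = "min"
    n_lambdas: int = 60
    lambda_min_ratio: float = 1e-3
    fixed_lambda: float | np.ndarray | None = None
    use_covariates: bool = True
    seed: int = 0
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian", "logistic"):
            raise ValidationError(f"unknown estimation mode {self.mode!r}")
        if self.lambda_rule not in ("min", "1se"):
            raise ValidationError(f"unknown lambda rule {self.lambda_rule!r}")

    def frozen_at(self, lambdas: np.ndarray) -> "EstimationSettings":
        """Copy with the penalty frozen at the given per-node values."""
        return replace(self, fixed_lambda=np.asarray(lambdas, dtype=float))


@dataclass(frozen=True)
class NodeFit:
    coefficients: np.ndarray  # lagged-predictor coefficients
    lambda_: float
    covariate_coefficients: np.ndarray
    intercept: float


def _zscore(a: np.ndarray, name: str) -> np.ndarray:
    sd = a.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError(f"constant column in {name}")
    return (a - a.mean(axis=0)) / sd


def covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for the covariate table: numeric columns
    z-scored, categorical columns dummy-coded (first level dropped) with
    missing values as an explicit 'unknown' level."""
    if covariates is None or covariates.shape[1] == 0:
        return pd.DataFrame(index=getattr(covariates, "index", None))
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.astype(float)
            v = v.fillna(v.mean())
            sd = v.std(ddof=0)
            parts.append(((v - v.mean()) / sd if sd > 0 else v * 0.0).rename(col))
        else:
            cat = s.astype("object").where(s.notna(), "unknown").astype(str)
            dummies = pd.get_dummies(cat, prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1 | Z] (exact partialling)."""
    n = M.shape[0]
    Z1 = np.column_stack([np.ones(n), Z]) if Z.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Z1, M, rcond=None)
    return M - Z1 @ beta


def _lambda_path(X: np.ndarray, y: np.ndarray, settings: EstimationSettings):
    n = len(y)
    lam_max = np.max(np.abs(X.T @ y)) / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * settings.lambda_min_ratio,
                        settings.n_lambdas)


def _gaussian_cv(X, y, settings: EstimationSettings) -> tuple[float, np.ndarray]:
    """K-fold CV over the penalty path (Gram-based solver); returns the
    selected penalty and its coefficient vector."""
    n = len(y)
    G = X.T @ X
    q = X.T @ y
    path = _lambda_path(X, y, settings)
    kf = KFold(settings.n_folds, shuffle=True, random_state=settings.seed)
    errs = np.empty((settings.n_folds, len(path)))
    for f, (tr, te) in enumerate(kf.split(X)):
        Xte, yte = X[te], y[te]
        G_tr = G - Xte.T @ Xte
        q_tr = q - Xte.T @ yte
        B = cd_path(G_tr, q_tr, len(tr), path, settings.tol, 100_000)
        resid = yte[:, None] - Xte @ B.T
        errs[f] = (resid ** 2).mean(axis=0)
    mse = errs.mean(axis=0)
    i_min = int(np.argmin(mse))
    if settings.lambda_rule == "1se":
        se = errs.std(axis=0, ddof=1) / np.sqrt(settings.n_folds)
        ok = np.flatnonzero(mse <= mse[i_min] + se[i_min])
        i_sel = int(ok.min())  # path is descending: smallest index is the
        # largest (sparsest) penalty within one SE of the minimum
    else:
        i_sel = i_min
    lam = float(path[i_sel])
    b = cd_path(G, q, n, path[: i_sel + 1], settings.tol, 100_000)[-1]
    return lam, b


def fit_node(
    y: np.ndarray,
    X: np.ndarray,
    covariates: pd.DataFrame | None,
    settings: EstimationSettings,
    fixed_lambda: float | None = None,
) -> NodeFit:
    """Fit one outcome node: L1-penalized regression of a T2 variable on the
    standardized T1 predictors, covariates unpenalized (Gaussian mode).

    ``y`` and ``X`` are raw (unstandardized) values; standardization and
    partialling happen here so that bootstrap resamples re-learn both.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if n < MIN_SUBJECTS:
        raise InsufficientDataError(
            f"{n} subjects < minimum of {MIN_SUBJECTS}"
        )
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValidationError("missing values reached the estimator; apply "
                              "listwise deletion upstream")
    if y.std() == 0:
        raise DegenerateDataError("constant outcome")

    Xz = _zscore(X, "predictors")
    Z = (
        covariate_design(covariates).to_numpy(dtype=float)
        if (covariates is not None and settings.use_covariates)
        else np.empty((n, 0))
    )

    if settings.mode == "logistic":
        return _fit_node_logistic(y, Xz, Z, settings, fixed_lambda)

    yz = (y - y.mean()) / y.std()
    Xr = _residualize(Xz, Z)
    yr = _residualize(yz[:, None], Z)[:, 0]

    if fixed_lambda is not None:
        lam = float(fixed_lambda)
        b = lasso_at(Xr, yr, lam, tol=settings.tol)
    else:
        lam, b = _gaussian_cv(Xr, yr, settings)

    # profile the covariate coefficients back out of the partialled fit
    Z1 = np.column_stack([np.ones(n), Z])
    g, *_ = np.linalg.lstsq(Z1, yz - Xz @ b, rcond=None)
    return NodeFit(b, lam, g[1:], float(g[0]))


def _fit_node_logistic(y, Xz, Z, settings, fixed_lambda):
    """Median-split logistic mode; covariates (if any) are penalized along
    with the lagged predictors."""
    y01 = (y > np.median(y)).astype(int)
    if y01.min() == y01.max():
        raise DegenerateDataError("outcome constant after median split")
    D = np.column_stack([Xz, Z]) if Z.size else Xz
    n = len(y01)
    p_lag = Xz.shape[1]

    def fit_at(lam: float) -> np.ndarray:
        if not np.isfinite(lam):
            return np.zeros(D.shape[1])
        C = 1.0 / max(n * lam, 1e-12)
        m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                               max_iter=5000)
        m.fit(D, y01)
        return m.coef_[0]

    if fixed_lambda is not None:
        lam = float(fixed_lambda)
        coefs = fit_at(lam)
    else:
        lam_max = np.max(np.abs(D.T @ (y01 - y01.mean()))) / n
        path = np.geomspace(lam_max, lam_max * settings.lambda_min_ratio,
                            settings.n_lambdas)
        cv = StratifiedKFold(settings.n_folds, shuffle=True,
                             random_state=settings.seed)
        scores = np.zeros(len(path))
        for tr, te in cv.split(D, y01):
            for k, lam_k in enumerate(path):
                C = 1.0 / max(len(tr) * lam_k, 1e-12)
                m = LogisticRegression(l1_ratio=1.0, C=C,
                                       solver="liblinear", max_iter=5000)
                m.fit(D[tr], y01[tr])
                p = np.clip(m.predict_proba(D[te])[:, 1], 1e-12, 1 - 1e-12)
                scores[k] += -np.mean(
                    y01[te] * np.log(p) + (1 - y01[te]) * np.log(1 - p)
                )
        lam = float(path[int(np.argmin(scores))])
        coefs = fit_at(lam)
    return NodeFit(coefs[:p_lag], lam, coefs[p_lag:], 0.0)


def _fixed_lambda_for(fixed, j: int) -> float:
    arr = np.asarray(fixed).ravel()
    return float(arr[j % arr.size])


def _estimate_gaussian_network(
    X: np.ndarray,
    Y: np.ndarray,
    cov: pd.DataFrame | None,
    settings: EstimationSettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All 11 Gaussian node fits sharing one standardized/partialled design.

    Numerically identical to calling :func:`fit_node` per outcome (same
    standardization, partialling, penalty path and seeded folds), but the
    shared work — covariate design, residualization, Gram matrix, fold
    split — is done once, which matters inside bootstrap and case-dropping
    loops."""
    n, k = X.shape
    if n < MIN_SUBJECTS:
        raise InsufficientDataError(f"{n} subjects < minimum of "
                                    f"{MIN_SUBJECTS}")
    Xz = _zscore(X, "predictors")
    y_sd = Y.std(axis=0)
    bad = np.flatnonzero(y_sd == 0)
    if bad.size:
        raise DegenerateDataError(
            f"node {NODE_CODES[bad[0]]}: constant outcome"
        )
    Yz = (Y - Y.mean(axis=0)) / y_sd
    Z = (
        covariate_design(cov).to_numpy(dtype=float)
        if (cov is not None and cov.shape[1])
        else np.empty((n, 0))
    )
    Z1 = np.column_stack([np.ones(n), Z])
    M = np.column_stack([Xz, Yz])
    beta, *_ = np.linalg.lstsq(Z1, M, rcond=None)
    R = M - Z1 @ beta
    Xr, Yr = R[:, :k], R[:, k:]
    G = Xr.T @ Xr
    Q = Xr.T @ Yr  # (k predictors, k outcomes)

    coeff = np.zeros((k, k))
    lambdas = np.zeros(k)
    fixed = settings.fixed_lambda
    if fixed is not None:
        for j in range(k):
            lam = _fixed_lambda_for(fixed, j)
            lambdas[j] = lam
            if lam == 0.0:
                coeff[:, j] = np.linalg.lstsq(Xr, Yr[:, j], rcond=None)[0]
            elif np.isfinite(lam):
                coeff[:, j] = cd_path(
                    G, Q[:, j], n, np.array([lam]), settings.tol, 100_000
                )[-1]
    else:
        kf = KFold(settings.n_folds, shuffle=True,
                   random_state=settings.seed)
        folds = [
            (tr, te, G - Xr[te].T @ Xr[te]) for tr, te in kf.split(Xr)
        ]
        for j in range(k):
            yr = Yr[:, j]
            lam_max = np.max(np.abs(Q[:, j])) / n
            if lam_max <= 0:
                lam_max = 1e-3
            path = np.geomspace(
                lam_max, lam_max * settings.lambda_min_ratio,
                settings.n_lambdas,
            )
            errs = np.empty((settings.n_folds, len(path)))
            for f, (tr, te, G_tr) in enumerate(folds):
                q_tr = Q[:, j] - Xr[te].T @ yr[te]
                B = cd_path(G_tr, q_tr, len(tr), path, settings.tol,
                            100_000)
                resid = yr[te][:, None] - Xr[te] @ B.T
                errs[f] = (resid ** 2).mean(axis=0)
            mse = errs.mean(axis=0)
            i_min = int(np.argmin(mse))
            if settings.lambda_rule == "1se":
                se = errs.std(axis=0, ddof=1) / np.sqrt(settings.n_folds)
                i_sel = int(np.flatnonzero(
                    mse <= mse[i_min] + se[i_min]
                ).min())
            else:
                i_sel = i_min
            lambdas[j] = path[i_sel]
            coeff[:, j] = cd_path(G, Q[:, j], n, path[: i_sel + 1],
                                  settings.tol, 100_000)[-1]

    # profile covariate coefficients (incl. intercept) back out
    g, *_ = np.linalg.lstsq(Z1, Yz - Xz @ coeff, rcond=None)
    return coeff, lambdas, g[1:]


def estimate_clpn(
    data: PanelDataset, settings: EstimationSettings | None = None
) -> CLPNetwork:
    """Estimate the full directed network: one penalized node fit per T2
    outcome; ``coeff[i, j]`` is the coefficient of z(T1_i) in the model for
    T2_j.  Requires listwise-complete data."""
    settings = settings or EstimationSettings()
    if data.missing_mask.any().any():
        raise ValidationError(
            "dataset has missing analysis values; run listwise_complete first"
        )
    X = data.t1().to_numpy(dtype=float)
    k = len(NODE_CODES)
    coeff = np.zeros((k, k))
    lambdas = np.zeros(k)
    cov_cols: dict[str, np.ndarray] = {}
    fixed = settings.fixed_lambda
    cov = data.covariates if settings.use_covariates else None
    design_names = list(covariate_design(cov).columns) if (
        cov is not None and cov.shape[1]
    ) else []

    if settings.mode == "gaussian":
        Y = data.t2().to_numpy(dtype=float)
        coeff, lambdas, g = _estimate_gaussian_network(X, Y, cov, settings)
        cov_cols = {code: g[:, j] for j, code in enumerate(NODE_CODES)}
    else:
        for j, code in enumerate(NODE_CODES):
            y = data.values[t2_column(code)].to_numpy(dtype=float)
            lam_j = None
            if fixed is not None:
                lam_j = _fixed_lambda_for(fixed, j)
            try:
                fit = fit_node(y, X, cov, settings, fixed_lambda=lam_j)
            except (DegenerateDataError, InsufficientDataError) as err:
                raise type(err)(f"node {code}: {err}") from err
            coeff[:, j] = fit.coefficients
            lambdas[j] = fit.lambda_
            cov_cols[code] = fit.covariate_coefficients

    cov_df = (
        pd.DataFrame(cov_cols, index=design_names)
        if design_names
        else None
    )
    return CLPNetwork(
        NODES,
        coeff,
        lambda_per_node=lambdas,
        covariate_coeffs=cov_df,
        meta={
            "mode": settings.mode,
            "n_subjects": data.subjects,
            "n_folds": settings.n_folds,
            "lambda_rule": settings.lambda_rule,
            "seed": settings.seed,
        },
    )
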