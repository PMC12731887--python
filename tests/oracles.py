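"""Independent reference implementations used only to check the package.

These deliberately use different algorithms (or different codebases) from
the implementation under test.
"""

import numpy as np


def ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form least squares via the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def ista_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    n_iter: int = 200_000,
    tol: float = 1e-14,
) -> np.ndarray:
    """Proximal-gradient (ISTA) solver for
    (1/2n)||y - Xb||^2 + lam ||b||_1 — a different algorithm family from
    coordinate descent."""
    n, p = X.shape
    L = np.linalg.eigvalsh(X.T @ X / n).max()
    step = 1.0 / L
    b = np.zeros(p)
    for _ in range(n_iter):
        grad = X.T @ (X @ b - y) / n
        z = b - step * grad
        new = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0.0)
        if np.max(np.abs(new - b)) < tol:
            b = new
            break
        b = new
    return b


def sklearn_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """scikit-learn's coordinate descent, an independent implementation."""
    from sklearn.linear_model import Lasso

    model = Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                  max_iter=1_000_000)
    model.fit(X, y)
    return model.coef_


def spearman_brown_alpha(k: int, rho: float) -> float:
    """Cronbach's alpha of k parallel items with common correlation rho."""
    return k * rho / (1.0 + (k - 1) * rho)


def row_sums_by_subscale(items, item_map, codes) -> dict:
    """Brute-force per-row summation of items into subscales."""
    out = {}
    for code in codes:
        cols = [c for c, s in item_map.items() if s == code]
        if not cols:
            continue
        sums = []
        for _, row in items.iterrows():
            sums.append(sum(row[c] for c in cols))
        out[code] = np.array(sums)
    return out
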