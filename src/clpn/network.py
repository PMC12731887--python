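"""Directed cross-lagged network container and elementwise transforms.

``coeff[i, j]`` is the coefficient of predictor node ``i`` measured at T1 in
the regression for outcome node ``j`` at T2 (rows = predictors, columns =
outcomes).  The diagonal holds autoregressive paths.  Edge weights are
reported both on the coefficient (log-OR) scale and as odds ratios
``OR = exp(coeff)``, the reporting transform used throughout; a zero
coefficient is exactly OR = 1, an absent edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .labels import NODES, NodeLabel

#: coefficients below this magnitude are structural zeros (float hygiene)
ZERO_TOL = 1e-9


def to_odds_ratios(coeff: np.ndarray) -> np.ndarray:
    """Elementwise exponentiation; zero maps to exactly 1."""
    return np.exp(np.asarray(coeff, dtype=float))


@dataclass
class CLPNetwork:
    """Directed T1 -> T2 network over an ordered node set."""

    nodes: tuple[NodeLabel, ...]
    coeff: np.ndarray
    lambda_per_node: np.ndarray | None = None
    covariate_coeffs: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeff = np.asarray(self.coeff, dtype=float)
        k = len(self.nodes)
        if self.coeff.shape != (k, k):
            raise ValidationError(
                f"coefficient matrix {self.coeff.shape} does not match "
                f"{k} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(n.code for n in self.nodes)

    @property
    def or_matrix(self) -> np.ndarray:
        return to_odds_ratios(self.coeff)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown node code {code!r}") from None

    def __getitem__(self, edge: tuple[str, str]) -> float:
        i, j = edge
        return float(self.coeff[self.index(i), self.index(j)])

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_or_matrix(
        cls, or_matrix, nodes: tuple[NodeLabel, ...] = NODES, **kw
    ) -> "CLPNetwork":
        """Build a network from an OR adjacency table (e.g. a printed
        fixture); coefficients are the elementwise log."""
        arr = np.asarray(or_matrix, dtype=float)
        if np.any(arr <= 0):
            raise ValidationError("odds ratios must be positive")
        return cls(tuple(nodes), np.log(arr), **kw)

    # -- export -------------------------------------------------------------

    def to_frame(self, scale: str = "or") -> pd.DataFrame:
        """Adjacency as a DataFrame, predictors in rows (printed layout)."""
        mat = self.or_matrix if scale == "or" else self.coeff
        codes = list(self.codes)
        return pd.DataFrame(mat, index=codes, columns=codes)

    def to_csv(self, path, scale: str = "or") -> None:
        self.to_frame(scale).to_csv(path, index_label="predictor")

    def to_json(self, path=None) -> str:
        payload = {
            "nodes": [
                {"code": n.code, "name": n.name, "construct": n.construct}
                for n in self.nodes
            ],
            "coeff": self.coeff.tolist(),
            "or_matrix": self.or_matrix.tolist(),
            "lambda_per_node": (
                None
                if self.lambda_per_node is None
                else np.asarray(self.lambda_per_node).tolist()
            ),
            "covariate_coeffs": (
                None
                if self.covariate_coeffs is None
                else {
                    "index": list(self.covariate_coeffs.index),
                    "columns": list(self.covariate_coeffs.columns),
                    "data": self.covariate_coeffs.to_numpy().tolist(),
                }
            ),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CLPNetwork":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        nodes = tuple(
            NodeLabel(d["code"], d["name"], d["construct"])
            for d in payload["nodes"]
        )
        lam = payload.get("lambda_per_node")
        cov = payload.get("covariate_coeffs")
        return cls(
            nodes,
            np.array(payload["coeff"], dtype=float),
            lambda_per_node=None if lam is None else np.asarray(lam, float),
            covariate_coeffs=(
                None
                if cov is None
                else pd.DataFrame(
                    cov["data"], index=cov["index"], columns=cov["columns"]
                )
            ),
            meta=payload.get("meta", {}),
        )


def strip_autoregressive(net: CLPNetwork) -> CLPNetwork:
    """Copy with autoregressive (diagonal) coefficients set to zero (OR 1);
    idempotent, off-diagonal untouched."""
    coeff = net.coeff.copy()
    np.fill_diagonal(coeff, 0.0)
    return replace(net, coeff=coeff)


@dataclass(frozen=True)
class EdgeCensus:
    """Counts and means over retained (nonzero) edges.

    ``positive_share`` and the OR means are None when the respective edge
    set is empty (undefined-flagged rather than NaN-silent).
    """

    n_nonzero_cross: int
    n_positive: int
    positive_share: float | None
    mean_or_cross: float | None
    mean_or_auto: float | None


def edge_census(net: CLPNetwork, tol: float = ZERO_TOL) -> EdgeCensus:
    """Census of cross-lagged (off-diagonal) edges with |coeff| > tol:
    count, count positive (OR > 1), positive share, and mean ORs of the
    retained cross-lagged and of the autoregressive edge sets."""
    coeff = net.coeff
    ors = net.or_matrix
    off = ~np.eye(net.n_nodes, dtype=bool)
    nz = off & (np.abs(coeff) > tol)
    n_nz = int(nz.sum())
    n_pos = int((nz & (coeff > 0)).sum())
    auto = np.diag(coeff)
    auto_nz = np.abs(auto) > tol
    return EdgeCensus(
        n_nonzero_cross=n_nz,
        n_positive=n_pos,
        positive_share=(n_pos / n_nz) if n_nz else None,
        mean_or_cross=float(ors[nz].mean()) if n_nz else None,
        mean_or_auto=(
            float(np.exp(auto[auto_nz]).mean()) if auto_nz.any() else None
        ),
    )
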