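"""Directed centrality and ranked-edge reports.

Expected influence (EI) keeps edge signs: out-EI of a node is the signed sum
of its outgoing cross-lagged weights (predictive force), in-EI the signed
sum of incoming weights (predictability).  Bridge EI (one-step) restricts
the sums to edges crossing the construct partition (DA vs FCR).  The
autoregressive diagonal is always excluded.

Two weight scales are supported and surfaced explicitly: ``coeff`` (the
regression coefficients, i.e. log ORs — the natural scale for freshly
estimated networks) and ``or_minus_1`` (OR − 1, the natural scale when
working from a printed OR adjacency table).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError, PartitionError
from .network import CLPNetwork, ZERO_TOL

SCALES = ("coeff", "or_minus_1")


def _weights(net: CLPNetwork, scale: str) -> np.ndarray:
    if scale not in SCALES:
        raise DomainError(f"unknown scale {scale!r}; use one of {SCALES}")
    w = net.coeff.copy() if scale == "coeff" else net.or_matrix - 1.0
    np.fill_diagonal(w, 0.0)
    return w


def expected_influence(
    net: CLPNetwork, direction: str, scale: str = "coeff"
) -> pd.Series:
    """Signed sum of a node's outgoing (``out``) or incoming (``in``)
    cross-lagged edge weights."""
    if direction not in ("in", "out"):
        raise DomainError("direction must be 'in' or 'out'")
    w = _weights(net, scale)
    vals = w.sum(axis=1) if direction == "out" else w.sum(axis=0)
    name = "oei" if direction == "out" else "iei"
    return pd.Series(vals, index=list(net.codes), name=name)


def _partition_groups(net: CLPNetwork, partition: dict | None):
    if partition is None:
        partition = {n.code: n.construct for n in net.nodes}
    missing = [c for c in net.codes if c not in partition]
    if missing:
        raise PartitionError(f"nodes without a community: {missing}")
    groups = sorted(set(partition[c] for c in net.codes))
    if len(groups) != 2:
        raise PartitionError(
            f"partition must 2-color the nodes, got groups {groups}"
        )
    return np.array([partition[c] for c in net.codes])


def bridge_expected_influence(
    net: CLPNetwork,
    direction: str,
    scale: str = "coeff",
    partition: dict | None = None,
) -> pd.Series:
    """One-step bridge EI: signed sum restricted to edges whose endpoints
    lie in different communities of the two-block partition."""
    if direction not in ("in", "out"):
        raise DomainError("direction must be 'in' or 'out'")
    w = _weights(net, scale)
    labels = _partition_groups(net, partition)
    cross = labels[:, None] != labels[None, :]
    w = np.where(cross, w, 0.0)
    vals = w.sum(axis=1) if direction == "out" else w.sum(axis=0)
    name = "bridge_oei" if direction == "out" else "bridge_iei"
    return pd.Series(vals, index=list(net.codes), name=name)


def centrality_table(
    net: CLPNetwork, scale: str = "coeff", partition: dict | None = None
) -> pd.DataFrame:
    """All four indices (OEI, IEI, bridge-OEI, bridge-IEI) plus per-index
    z-scores across nodes; the scale is recorded in ``df.attrs['scale']``."""
    df = pd.DataFrame(
        {
            "oei": expected_influence(net, "out", scale),
            "iei": expected_influence(net, "in", scale),
            "bridge_oei": bridge_expected_influence(net, "out", scale,
                                                    partition),
            "bridge_iei": bridge_expected_influence(net, "in", scale,
                                                    partition),
        }
    )
    for col in list(df.columns):
        v = df[col]
        sd = v.std(ddof=0)
        df[f"z_{col}"] = (v - v.mean()) / sd if sd > 0 else 0.0
    df.attrs["scale"] = scale
    return df


def _block_indices(net: CLPNetwork, block: str) -> np.ndarray:
    if block == "all":
        return np.arange(net.n_nodes)
    idx = np.array([i for i, n in enumerate(net.nodes) if n.construct == block])
    if idx.size == 0:
        raise DomainError(f"empty block {block!r}")
    return idx


def _nonzero_edges(net: CLPNetwork, from_block: str, to_block: str):
    rows = _block_indices(net, from_block)
    cols = _block_indices(net, to_block)
    ors = net.or_matrix
    edges = [
        (i, j, ors[i, j])
        for i in rows
        for j in cols
        if i != j and abs(net.coeff[i, j]) > ZERO_TOL
    ]
    return edges


def block_extremum(
    net: CLPNetwork, from_block: str, to_block: str, rank: int = 1
) -> tuple[tuple[str, str], float]:
    """rank-th largest OR among nonzero edges from ``from_block`` into
    ``to_block`` (blocks: 'DA', 'FCR' or 'all'); ties break lexicographically
    in (row, column) node order.  Returns ((from, to), OR)."""
    if rank < 1:
        raise DomainError("rank must be a positive integer")
    edges = _nonzero_edges(net, from_block, to_block)
    if rank > len(edges):
        raise DomainError(
            f"rank {rank} exceeds the {len(edges)} nonzero edges in the block"
        )
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    i, j, v = edges[rank - 1]
    return (net.codes[i], net.codes[j]), float(v)


def ranked_edges(net: CLPNetwork, top_k: int | None = None) -> pd.DataFrame:
    """All nonzero cross-lagged edges sorted by |coefficient| descending
    (stable (row, column) tie-break), optionally truncated to ``top_k``."""
    edges = [
        (i, j, net.coeff[i, j], net.or_matrix[i, j])
        for i in range(net.n_nodes)
        for j in range(net.n_nodes)
        if i != j and abs(net.coeff[i, j]) > ZERO_TOL
    ]
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    if top_k is not None:
        edges = edges[:top_k]
    return pd.DataFrame(
        [
            {
                "from": net.codes[i],
                "to": net.codes[j],
                "coeff": c,
                "or": o,
            }
            for i, j, c, o in edges
        ]
    )
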