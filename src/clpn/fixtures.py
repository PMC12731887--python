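"""Bundled reference tables: the published adjacency matrix, subscale
descriptives and cohort composition, transcribed once and checksum-guarded.

These fixtures support worked examples and calibrate the synthetic cohort
generator; nothing in them is recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import FixtureLookupError
from .labels import NODE_CODES, NODES, NodeLabel
from .network import CLPNetwork

_CHECKSUMS = {
    "table3_or_matrix.csv": (
        "c60f225d37a55148dc2d3e5a02bcabdd1fab1f9a7e3599a2a2a22f316ab311b5"
    ),
    "table2_descriptives.csv": (
        "a8d29b69c674224199694bdcb74a74df6153275aa6a0b8657b5df12511843319"
    ),
    "table1_cohort.json": (
        "24a73b89356da1ce2c3a070064e1087aa853968fb1c13d6ca10cf2969bcbe2cb"
    ),
}


def _data_path(name: str):
    return resources.files("clpn.data").joinpath(name)


def fixture_sha256(name: str) -> str:
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


def expected_sha256(name: str) -> str:
    return _CHECKSUMS[name]


def load_table3() -> pd.DataFrame:
    """11x11 OR adjacency matrix, predictors in rows, as printed."""
    with _data_path("table3_or_matrix.csv").open() as fh:
        df = pd.read_csv(fh, index_col="predictor")
    assert list(df.index) == list(NODE_CODES)
    assert list(df.columns) == list(NODE_CODES)
    return df


def load_table2() -> pd.DataFrame:
    """Subscale labels and per-wave mean/SD descriptives."""
    with _data_path("table2_descriptives.csv").open() as fh:
        return pd.read_csv(fh, index_col="code")


def load_table1() -> dict:
    """Cohort composition: stage, demographics, recruitment counts."""
    with _data_path("table1_cohort.json").open() as fh:
        return json.load(fh)


_LOADERS = {
    "table3": load_table3,
    "table2": load_table2,
    "table1": load_table1,
    "nodes": lambda: NODES,
}


def load_fixture(name: str):
    """Look up a bundled fixture by id (``table1``/``table2``/``table3``/
    ``nodes``)."""
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_LOADERS)}"
        ) from None
    return loader()


@dataclass(frozen=True)
class FixtureBundle:
    table3_or_matrix: pd.DataFrame
    table2_descriptives: pd.DataFrame
    table1_cohort: dict
    node_labels: tuple[NodeLabel, ...]


def load_bundle() -> FixtureBundle:
    return FixtureBundle(load_table3(), load_table2(), load_table1(), NODES)


def fixture_network() -> CLPNetwork:
    """The published adjacency matrix as a :class:`CLPNetwork` (coefficients
    are elementwise logs of the printed ORs; entries printed as 1.000 are
    exact zeros)."""
    return CLPNetwork.from_or_matrix(
        load_table3().to_numpy(), NODES, meta={"source": "fixture:table3"}
    )
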