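"""Canonical node set of the death-anxiety / fear-of-recurrence network.

The network has 11 nodes: four subscales of Templer's Death Anxiety Scale
(DAS; construct ``DA``) and seven subscales of the Fear of Cancer Recurrence
Inventory (FCRI; construct ``FCR``).  Node order is fixed
(D1..D4, F1..F7) and every adjacency matrix in this package uses it for both
rows (T1 predictors) and columns (T2 outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class NodeLabel:
    """A network node: subscale code, human-readable name and construct."""

    code: str
    name: str
    construct: str  # "DA" or "FCR"

    def __post_init__(self) -> None:
        if self.construct not in ("DA", "FCR"):
            raise ValueError(f"unknown construct {self.construct!r}")


DA_NODES = (
    NodeLabel("D1", "Cognition", "DA"),
    NodeLabel("D2", "Emotion", "DA"),
    NodeLabel("D3", "Time awareness", "DA"),
    NodeLabel("D4", "Stress and pain", "DA"),
)

FCR_NODES = (
    NodeLabel("F1", "Triggers", "FCR"),
    NodeLabel("F2", "Severity", "FCR"),
    NodeLabel("F3", "Psychological distress", "FCR"),
    NodeLabel("F4", "Functioning impairment", "FCR"),
    NodeLabel("F5", "Insight", "FCR"),
    NodeLabel("F6", "Reassurance", "FCR"),
    NodeLabel("F7", "Coping strategies", "FCR"),
)

NODES: tuple[NodeLabel, ...] = DA_NODES + FCR_NODES
NODE_CODES: tuple[str, ...] = tuple(n.code for n in NODES)
CODE_TO_INDEX: dict[str, int] = {n.code: i for i, n in enumerate(NODES)}

#: Default construct partition used by bridge centrality.
CONSTRUCT_PARTITION: dict[str, str] = {n.code: n.construct for n in NODES}

N_NODES = len(NODES)

STAGES = ("I", "II", "III", "IV")
EARLY_STAGES = ("I", "II")
ADVANCED_STAGES = ("III", "IV")


def t1_column(code: str) -> str:
    return f"{code}_T1"


def t2_column(code: str) -> str:
    return f"{code}_T2"


T1_COLUMNS = tuple(t1_column(c) for c in NODE_CODES)
T2_COLUMNS = tuple(t2_column(c) for c in NODE_CODES)
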