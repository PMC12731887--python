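"""Markdown analysis reports.

Pure rendering: the same inputs always produce byte-identical output (no
timestamps), and every number is taken from the objects passed in.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import RenderError
from .metrics import ranked_edges
from .network import CLPNetwork, edge_census


def _has_tabulate() -> bool:
    try:
        import tabulate  # noqa: F401

        return True
    except ImportError:
        return False


def _frame(df: pd.DataFrame, floatfmt: str = ".3f") -> str:
    if _has_tabulate():
        return df.to_markdown(floatfmt=floatfmt)
    return "```\n" + df.round(3).to_string() + "\n```"


def render_report(
    network: CLPNetwork,
    centrality: pd.DataFrame,
    boot=None,
    comparison=None,
    title: str = "Cross-lagged panel network report",
) -> str:
    """Render the five-section analysis report (adjacency, ranked edges,
    centrality, stability, subgroup comparison).  ``network`` and
    ``centrality`` are mandatory; absent stability/comparison inputs are
    marked 'not computed'."""
    if network is None or centrality is None:
        raise RenderError("network and centrality sections are mandatory")
    lines = [f"# {title}", ""]

    census = edge_census(network)
    lines += [
        "## Adjacency (odds ratios, predictors in rows)",
        "",
        _frame(network.to_frame("or")),
        "",
        f"Nonzero cross-lagged edges: {census.n_nonzero_cross} "
        f"({census.n_positive} positive).",
        "",
    ]

    top = ranked_edges(network, top_k=10)
    lines += ["## Strongest cross-lagged edges", ""]
    lines += [_frame(top.set_index(["from", "to"])) if len(top) else
              "(no nonzero cross-lagged edges)"]
    lines += [""]

    lines += [
        "## Centrality (expected influence)",
        "",
        f"Scale: {centrality.attrs.get('scale', 'unspecified')}",
        "",
        _frame(centrality),
        "",
    ]

    lines += ["## Stability", ""]
    if boot is None:
        lines += ["Stability not computed.", ""]
    else:
        lines += [
            f"Bootstrap resamples: {boot.n_boot} "
            f"({boot.n_failures} failures).",
            "",
        ]
        if getattr(boot, "cs_results", None):
            for cs in boot.cs_results:
                lines += [f"- CS({cs.index}) = {cs.cs:.2f}"]
            lines += [""]

    lines += ["## Subgroup comparison", ""]
    if comparison is None:
        lines += ["Comparison not computed.", ""]
    else:
        for name, net in comparison.networks.items():
            c = edge_census(net)
            lines += [
                f"- {name}: n = {comparison.counts[name]}, "
                f"{c.n_nonzero_cross} nonzero cross-lagged edges"
            ]
        delta = comparison.edge_delta_frame()
        lines += ["", "Edge differences (early − advanced):", "",
                  _frame(delta), ""]

    return "\n".join(lines)
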