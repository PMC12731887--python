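"""Stage-stratified estimation and early- vs advanced-stage comparison.

Early stage is I/II, advanced is III/IV.  The primary comparison output is
descriptive: per-group networks, centralities and block extrema plus the
elementwise coefficient difference (early minus advanced).  A permutation
test of the maximum edge difference and of the global-strength difference
is available as an explicitly labeled inferential extension; the lambda
*selection procedure* (not the selected value) is shared across groups, so
sparsity is allowed to adapt to each group's sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import EstimationSettings, estimate_clpn
from .exceptions import DomainError, SubgroupError
from .labels import ADVANCED_STAGES, EARLY_STAGES
from .metrics import block_extremum, centrality_table
from .network import CLPNetwork
from .panel import PanelDataset, listwise_complete


def split_by_stage(data: PanelDataset) -> dict[str, PanelDataset]:
    """Partition subjects into early (I/II) and advanced (III/IV) groups."""
    out = {}
    for name, stages in (("early", EARLY_STAGES), ("advanced",
                                                   ADVANCED_STAGES)):
        mask = data.stage.isin(stages).to_numpy()
        if not mask.any():
            raise SubgroupError(f"subgroup {name!r} is empty")
        out[name] = data.select(np.flatnonzero(mask))
    return out


def _complete(data: PanelDataset) -> PanelDataset:
    if data.missing_mask.any().any():
        return listwise_complete(data).data
    return data


def _cross_stat(coeff: np.ndarray) -> np.ndarray:
    off = coeff.copy()
    np.fill_diagonal(off, 0.0)
    return off


@dataclass
class ComparisonReport:
    networks: dict  # group -> CLPNetwork
    centralities: dict  # group -> centrality DataFrame (coeff scale)
    extrema: dict  # group -> {block pair -> ((from, to), OR)}
    edge_delta: np.ndarray  # coeff_early - coeff_advanced (cross-lagged)
    counts: dict  # group -> analysed subjects

    def edge_delta_frame(self) -> pd.DataFrame:
        net = self.networks["early"]
        codes = list(net.codes)
        return pd.DataFrame(self.edge_delta, index=codes, columns=codes)


_BLOCK_PAIRS = (("DA", "DA"), ("FCR", "FCR"), ("DA", "FCR"), ("FCR", "DA"))


def compare_networks(
    early: PanelDataset,
    advanced: PanelDataset,
    settings: EstimationSettings | None = None,
) -> ComparisonReport:
    """Estimate each subgroup network with shared settings and summarize
    the differences descriptively."""
    settings = settings or EstimationSettings()
    networks, cents, extrema, counts = {}, {}, {}, {}
    for name, data in (("early", early), ("advanced", advanced)):
        data = _complete(data)
        counts[name] = data.subjects
        net = estimate_clpn(data, settings)
        networks[name] = net
        cents[name] = centrality_table(net, scale="coeff")
        ext = {}
        for fb, tb in _BLOCK_PAIRS:
            try:
                ext[(fb, tb)] = block_extremum(net, fb, tb, 1)
            except DomainError:
                ext[(fb, tb)] = None  # no retained edge in that block
        extrema[name] = ext
    delta = _cross_stat(networks["early"].coeff) - _cross_stat(
        networks["advanced"].coeff
    )
    return ComparisonReport(networks, cents, extrema, delta, counts)


@dataclass(frozen=True)
class PermutationResult:
    max_edge_diff: float
    strength_diff: float
    max_edge_diff_p: float
    strength_diff_p: float
    n_perm: int


def permutation_comparison(
    early: PanelDataset,
    advanced: PanelDataset,
    settings: EstimationSettings | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of network invariance across subgroups.

    Statistics: the maximum absolute cross-lagged coefficient difference,
    and the absolute difference of global strength (sum of |cross-lagged
    coefficients|).  Group labels are permuted over subjects; p is the
    fraction of permuted statistics >= the observed one.
    """
    if n_perm < 100:
        raise DomainError("n_perm must be at least 100")
    settings = settings or EstimationSettings()
    early = _complete(early)
    advanced = _complete(advanced)

    def stats_for(a: PanelDataset, b: PanelDataset) -> tuple[float, float]:
        ca = _cross_stat(estimate_clpn(a, settings).coeff)
        cb = _cross_stat(estimate_clpn(b, settings).coeff)
        return (
            float(np.max(np.abs(ca - cb))),
            float(abs(np.abs(ca).sum() - np.abs(cb).sum())),
        )

    obs_max, obs_strength = stats_for(early, advanced)

    pooled_vals = pd.concat(
        [early.values, advanced.values], ignore_index=True
    )
    pooled_cov = pd.concat(
        [early.covariates, advanced.covariates], ignore_index=True
    )
    pooled_stage = pd.concat(
        [early.stage, advanced.stage], ignore_index=True
    )
    pooled = PanelDataset(pooled_vals, pooled_cov, pooled_stage)
    n_a = early.subjects
    n = pooled.subjects

    children = np.random.SeedSequence(seed).spawn(n_perm)
    count_max = count_strength = 0
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        pa = pooled.select(perm[:n_a])
        pb = pooled.select(perm[n_a:])
        m, s = stats_for(pa, pb)
        count_max += m >= obs_max
        count_strength += s >= obs_strength
    return PermutationResult(
        obs_max,
        obs_strength,
        count_max / n_perm,
        count_strength / n_perm,
        n_perm,
    )
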