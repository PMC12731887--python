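"""Bootstrap accuracy and case-dropping stability for estimated networks.

Three procedures, all deterministic under a fixed seed (resample index ->
seed substream via ``numpy.random.SeedSequence.spawn``, so serial and any
parallel execution order agree):

* nonparametric bootstrap of subjects -> percentile 95% CIs per edge;
* case-dropping subset bootstrap -> correlation-stability (CS) coefficient
  per centrality index: the largest drop proportion at which, with 95%
  confidence, the subsample centrality still correlates >= 0.7 with the
  full-sample centrality (values above 0.25 acceptable, above 0.50 strong);
* bootstrap difference tests for edge pairs and node-centrality pairs
  (significant iff the percentile CI of the difference excludes zero).

By default the penalty is re-selected inside every resample (honest
full-pipeline uncertainty); freezing the full-sample penalties is available
for large calibration experiments via ``EstimationSettings.frozen_at``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import EstimationSettings, estimate_clpn
from .exceptions import ClpnError, DomainError
from .labels import CODE_TO_INDEX
from .metrics import bridge_expected_influence, expected_influence
from .network import CLPNetwork
from .panel import PanelDataset, listwise_complete

CS_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
MIN_RETAINED = 30

CENTRALITY_INDICES = ("oei", "iei", "bridge")


def _centrality_vector(net: CLPNetwork, index: str) -> np.ndarray:
    if index == "oei":
        return expected_influence(net, "out", "coeff").to_numpy()
    if index == "iei":
        return expected_influence(net, "in", "coeff").to_numpy()
    if index in ("bridge", "bridge_oei"):
        return bridge_expected_influence(net, "out", "coeff").to_numpy()
    if index == "bridge_iei":
        return bridge_expected_influence(net, "in", "coeff").to_numpy()
    raise DomainError(f"unknown centrality index {index!r}")


def _complete(data: PanelDataset) -> PanelDataset:
    if data.missing_mask.any().any():
        return listwise_complete(data).data
    return data


@dataclass
class BootstrapSummary:
    """Per-edge bootstrap distribution and percentile CIs."""

    n_boot: int
    estimate: np.ndarray  # full-sample coeff matrix
    boot_coeffs: np.ndarray  # (successful boots, k, k)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_failures: int
    seed: int
    settings: EstimationSettings
    network: CLPNetwork
    _centrality_cache: dict = field(default_factory=dict, repr=False)

    def edge_ci(self, edge: tuple[str, str]) -> tuple[float, float]:
        i, j = CODE_TO_INDEX[edge[0]], CODE_TO_INDEX[edge[1]]
        return float(self.ci_low[i, j]), float(self.ci_high[i, j])

    def boot_centrality(self, index: str) -> np.ndarray:
        """(n_boot, n_nodes) bootstrap centrality draws on the coeff scale."""
        if index not in self._centrality_cache:
            nets = [
                CLPNetwork(self.network.nodes, c) for c in self.boot_coeffs
            ]
            self._centrality_cache[index] = np.array(
                [_centrality_vector(n, index) for n in nets]
            )
        return self._centrality_cache[index]


def bootstrap_edges(
    data: PanelDataset,
    settings: EstimationSettings | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Resample subjects with replacement, re-estimate the network per
    resample, and form percentile 2.5/97.5 CIs per edge on the coefficient
    scale.  Resamples whose estimation degenerates are recorded and
    skipped; more than 10% failures aborts."""
    if n_boot < 100:
        raise DomainError("n_boot must be at least 100")
    settings = settings or EstimationSettings()
    data = _complete(data)
    full = estimate_clpn(data, settings)

    n = data.subjects
    children = np.random.SeedSequence(seed).spawn(n_boot)
    coeffs = []
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        try:
            net = estimate_clpn(data.select(idx), settings)
        except ClpnError as err:
            failures += 1
            if failures > 0.10 * n_boot:
                raise RuntimeError(
                    f"bootstrap aborted: {failures} resample failures "
                    f"(> 10% of {n_boot})"
                ) from err
            continue
        coeffs.append(net.coeff)
    boot = np.array(coeffs)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    return BootstrapSummary(
        n_boot=n_boot,
        estimate=full.coeff,
        boot_coeffs=boot,
        ci_low=lo,
        ci_high=hi,
        n_failures=failures,
        seed=seed,
        settings=settings,
        network=full,
    )


@dataclass(frozen=True)
class CSResult:
    cs: float
    index: str
    #: drop proportion -> fraction of subsamples with correlation >= 0.7
    stability_curve: dict
    infeasible: tuple


def cs_coefficient(
    data: PanelDataset,
    settings: EstimationSettings | None = None,
    index: str = "oei",
    n_sub: int = 250,
    seed: int = 0,
    cor_threshold: float = 0.7,
    confidence: float = 0.95,
) -> CSResult:
    """Case-dropping correlation-stability coefficient of one centrality
    index.  Drop proportions run over 0.05..0.75 in steps of 0.05;
    proportions leaving fewer than 30 subjects are marked infeasible and
    excluded.  CS is the largest grid proportion p such that the >= 0.7
    correlation criterion holds (with the requested confidence) at every
    feasible proportion up to p; 0.0 if it fails already at 0.05."""
    if index not in CENTRALITY_INDICES + ("bridge_oei", "bridge_iei"):
        raise DomainError(f"index must be one of {CENTRALITY_INDICES}")
    settings = settings or EstimationSettings()
    data = _complete(data)
    full = _centrality_vector(estimate_clpn(data, settings), index)
    n = data.subjects

    root = np.random.SeedSequence(seed)
    curve: dict[float, float] = {}
    infeasible = []
    for pi, p in enumerate(CS_GRID):
        m = int(round((1.0 - p) * n))
        if m < MIN_RETAINED:
            infeasible.append(p)
            continue
        children = np.random.SeedSequence((seed, pi)).spawn(n_sub)
        ok = 0
        for child in children:
            rng = np.random.default_rng(child)
            idx = rng.choice(n, size=m, replace=False)
            sub = _centrality_vector(
                estimate_clpn(data.select(idx), settings), index
            )
            if sub.std() == 0 or full.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(sub, full)[0, 1])
            ok += r >= cor_threshold
        curve[float(p)] = ok / n_sub

    cs = 0.0
    for p in CS_GRID:
        if p in infeasible:
            break
        if curve[float(p)] >= confidence:
            cs = float(p)
        else:
            break
    return CSResult(cs, index, curve, tuple(infeasible))


@dataclass(frozen=True)
class DifferenceTest:
    significant: bool
    ci: tuple[float, float]
    identical: bool = False


def edge_difference_test(
    boot: BootstrapSummary, edge_a: tuple[str, str], edge_b: tuple[str, str]
) -> DifferenceTest:
    """Percentile bootstrap test of w(edge_a) - w(edge_b); an edge compared
    with itself is flagged and trivially non-significant."""
    ia = (CODE_TO_INDEX[edge_a[0]], CODE_TO_INDEX[edge_a[1]])
    ib = (CODE_TO_INDEX[edge_b[0]], CODE_TO_INDEX[edge_b[1]])
    if ia == ib:
        return DifferenceTest(False, (0.0, 0.0), identical=True)
    diff = boot.boot_coeffs[:, ia[0], ia[1]] - boot.boot_coeffs[:, ib[0], ib[1]]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return DifferenceTest(bool(lo > 0 or hi < 0), (float(lo), float(hi)))


def centrality_difference_test(
    boot: BootstrapSummary, node_a: str, node_b: str, index: str = "oei"
) -> DifferenceTest:
    """Percentile bootstrap test of index(node_a) - index(node_b)."""
    if node_a == node_b:
        return DifferenceTest(False, (0.0, 0.0), identical=True)
    cent = boot.boot_centrality(index)
    ia, ib = CODE_TO_INDEX[node_a], CODE_TO_INDEX[node_b]
    diff = cent[:, ia] - cent[:, ib]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return DifferenceTest(bool(lo > 0 or hi < 0), (float(lo), float(hi)))
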