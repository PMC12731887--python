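"""Synthetic two-wave cohorts with known cross-lagged ground truth.

The raw questionnaire data behind the published network are not publicly
available, so this module generates cohorts that emulate the study design
end-to-end: 11 correlated subscale scores at discharge (T1) calibrated to
the published means/SDs, an autoregressive + sparse cross-lagged structural
model for the three-month follow-up (T2), demographic covariates matching
the published cohort composition, whole-wave MCAR dropout at T2, and stage
subgroups that may follow a different cross-lagged structure.

Generative model
----------------
T1 latent scores are multivariate normal with a block-exchangeable
correlation matrix (within-construct correlation for the DA and FCR blocks,
a lower between-construct correlation), rescaled to the target means/SDs
and truncated at zero (subscale sums are non-negative; the truncation is a
mild, documented distortion of the linear model).  On the standardized
scale,

    T2*_j = auto_j z(T1_j) + sum_i cross[i, j] z(T1_i)
            + sum_c effect[c, j] z(cov_c) + noise_j eps

and T2 is rescaled to the target follow-up means/SDs and truncated at 0.
When ``noise_sd`` is left unset, residual SDs are chosen so every T2* has
unit variance, which makes the stored ground truth exactly the estimand of
a regression of z(T2_j) on all z(T1): ``truth[:, j] = (auto + cross)[:, j]``.
With user-supplied noise the stored truth is rescaled accordingly.

All randomness flows from the spec's single seed; generation is
deterministic and has no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fixtures
from .exceptions import SpecError
from .labels import (
    ADVANCED_STAGES,
    CODE_TO_INDEX,
    N_NODES,
    NODE_CODES,
    STAGES,
    t1_column,
    t2_column,
)
from .panel import PanelDataset

_TABLE2 = fixtures.load_table2()
_TABLE1 = fixtures.load_table1()

T1_MEANS = _TABLE2["t1_mean"].to_numpy()
T1_SDS = _TABLE2["t1_sd"].to_numpy()
T2_MEANS = _TABLE2["t2_mean"].to_numpy()
T2_SDS = _TABLE2["t2_sd"].to_numpy()

_STAGE_MIX = np.array(
    [_TABLE1["stage_counts"][s] for s in STAGES], dtype=float
)
_STAGE_MIX /= _STAGE_MIX.sum()


def _counts_to_probs(counts: dict) -> tuple[list[str], np.ndarray]:
    names = list(counts)
    p = np.array([counts[k] for k in names], dtype=float)
    return names, p / p.sum()


_CATEGORICALS = {
    "education": _counts_to_probs(_TABLE1["education_counts"]),
    "marital": _counts_to_probs(_TABLE1["marital_counts"]),
    "occupation": _counts_to_probs(_TABLE1["occupation_counts"]),
    "income": _counts_to_probs(_TABLE1["income_counts"]),
}


def default_cross_matrix() -> np.ndarray:
    """Sparse standardized cross-lagged truth qualitatively mirroring the
    published edge pattern: strong positive within-DA and DA->FCR paths,
    moderate within-FCR paths, weak negatives out of the coping node."""
    cross = np.zeros((N_NODES, N_NODES))

    def put(a: str, b: str, v: float) -> None:
        cross[CODE_TO_INDEX[a], CODE_TO_INDEX[b]] = v

    put("D2", "D1", 0.30)
    put("D3", "F3", 0.30)
    put("D1", "F2", 0.25)
    put("D3", "D4", 0.25)
    put("D1", "F4", 0.20)
    put("D1", "F7", 0.20)
    put("F2", "F1", 0.20)
    put("F1", "F6", 0.18)
    put("F7", "F1", -0.08)
    put("F7", "F3", -0.08)
    put("F7", "F4", -0.08)
    put("F6", "D1", -0.05)
    put("F2", "F7", -0.06)
    return cross


def _default_covariate_effects() -> dict[str, np.ndarray]:
    age = np.zeros(N_NODES)
    age[CODE_TO_INDEX["D1"]] = 0.05
    age[CODE_TO_INDEX["D3"]] = 0.05
    return {"age": age}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a synthetic two-wave cohort."""

    n: int = 426
    t1_means: np.ndarray = field(default_factory=lambda: T1_MEANS.copy())
    t1_sds: np.ndarray = field(default_factory=lambda: T1_SDS.copy())
    t2_means: np.ndarray = field(default_factory=lambda: T2_MEANS.copy())
    t2_sds: np.ndarray = field(default_factory=lambda: T2_SDS.copy())
    within_construct_corr: float = 0.4
    between_construct_corr: float = 0.2
    auto_coeffs: np.ndarray = field(
        default_factory=lambda: np.full(N_NODES, 0.45)
    )
    cross_matrix: np.ndarray = field(default_factory=default_cross_matrix)
    covariate_effects: dict = field(
        default_factory=_default_covariate_effects
    )
    noise_sd: np.ndarray | None = None
    mcar_rate: float = 0.0467
    stage_mix: np.ndarray = field(default_factory=lambda: _STAGE_MIX.copy())
    stage_shift: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        cross = np.asarray(self.cross_matrix, dtype=float)
        if cross.shape != (N_NODES, N_NODES):
            raise SpecError("cross_matrix must be 11x11")
        if np.any(np.abs(np.diag(cross)) > 0):
            raise SpecError("cross_matrix diagonal must be zero "
                            "(autoregression lives in auto_coeffs)")
        if not (0 <= self.mcar_rate < 1):
            raise SpecError("mcar_rate must be in [0, 1)")
        mix = np.asarray(self.stage_mix, dtype=float)
        if mix.shape != (4,) or abs(mix.sum() - 1) > 1e-8:
            raise SpecError("stage_mix must be 4 probabilities summing to 1")
        if self.stage_shift is not None:
            shift = np.asarray(self.stage_shift, dtype=float)
            if shift.shape != (N_NODES, N_NODES):
                raise SpecError("stage_shift must be 11x11")
        eigvals = np.linalg.eigvalsh(self.t1_correlation())
        if eigvals.min() <= 1e-10:
            raise SpecError("implied T1 correlation matrix is not positive "
                            "definite")

    def t1_correlation(self) -> np.ndarray:
        """Block-exchangeable latent T1 correlation (DA block, FCR block)."""
        w, b = self.within_construct_corr, self.between_construct_corr
        corr = np.full((N_NODES, N_NODES), b)
        corr[:4, :4] = w
        corr[4:, 4:] = w
        np.fill_diagonal(corr, 1.0)
        return corr

    def structural_matrix(self, advanced: bool = False) -> np.ndarray:
        """auto (diagonal) + cross matrix for the requested subgroup."""
        cross = np.asarray(self.cross_matrix, dtype=float)
        if advanced and self.stage_shift is not None:
            cross = np.asarray(self.stage_shift, dtype=float)
        return np.diag(np.asarray(self.auto_coeffs, dtype=float)) + cross


def default_spec(**overrides) -> SyntheticSpec:
    """The package's reference study conditions (published descriptives,
    cohort mix and dropout rate; sparse strong-positive cross structure)."""
    return SyntheticSpec(**overrides)


@dataclass
class SyntheticCohort:
    """A generated dataset plus the standardized ground truth that produced
    it (the exact estimand of the node-wise regressions on z-scores)."""

    data: PanelDataset
    truth: np.ndarray
    truth_advanced: np.ndarray | None
    spec: SyntheticSpec

    def truth_for(self, group: str) -> np.ndarray:
        if group == "advanced" and self.truth_advanced is not None:
            return self.truth_advanced
        return self.truth


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age_spec = _TABLE1["age"]
    age = rng.normal(age_spec["mean"], age_spec["sd"], size=n)
    age = np.clip(age, 18.0, 90.0)
    cov = {"age": age}
    for name, (levels, probs) in _CATEGORICALS.items():
        cov[name] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cov)


def _total_sd(spec: SyntheticSpec, B: np.ndarray, noise: np.ndarray,
              effects: np.ndarray) -> np.ndarray:
    corr = spec.t1_correlation()
    explained = np.einsum("ij,ik,kj->j", B, corr, B)
    return np.sqrt(explained + (effects ** 2).sum(axis=0) + noise ** 2)


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a cohort from the spec; deterministic given ``spec.seed``.

    Applies ``stage_shift`` (when set) to subjects in stages III/IV, so a
    homogeneous cohort is simply a spec with ``stage_shift=None``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    corr = spec.t1_correlation()
    L = np.linalg.cholesky(corr)
    Z1 = rng.standard_normal((n, N_NODES)) @ L.T

    stage = rng.choice(STAGES, size=n, p=np.asarray(spec.stage_mix, float))
    advanced = np.isin(stage, ADVANCED_STAGES)

    cov = _covariates(rng, n)
    effect_names = [c for c in spec.covariate_effects if c in cov.columns]
    E = (
        np.array([spec.covariate_effects[c] for c in effect_names])
        if effect_names
        else np.zeros((0, N_NODES))
    )
    if E.size:
        Zc = np.column_stack(
            [
                (cov[c] - cov[c].mean()) / cov[c].std(ddof=0)
                for c in effect_names
            ]
        )
    else:
        Zc = np.zeros((n, 0))

    B_early = spec.structural_matrix(advanced=False)
    B_adv = spec.structural_matrix(advanced=True)

    if spec.noise_sd is None:
        noise = np.zeros(N_NODES)
        for B in {id(B_early): B_early, id(B_adv): B_adv}.values():
            explained = np.einsum("ij,ik,kj->j", B, corr, B)
            explained = explained + (E ** 2).sum(axis=0)
            if np.any(explained >= 1.0):
                raise SpecError(
                    "structural coefficients explain >= 100% of a T2 "
                    "variance; supply noise_sd explicitly"
                )
            noise = np.maximum(noise, np.sqrt(1.0 - explained))
        # per-group noise differs only if structures differ; use each group's
        noise_early = np.sqrt(
            1.0 - np.einsum("ij,ik,kj->j", B_early, corr, B_early)
            - (E ** 2).sum(axis=0)
        )
        noise_adv = np.sqrt(
            1.0 - np.einsum("ij,ik,kj->j", B_adv, corr, B_adv)
            - (E ** 2).sum(axis=0)
        )
    else:
        noise_early = noise_adv = np.asarray(spec.noise_sd, dtype=float)

    eps = rng.standard_normal((n, N_NODES))
    T2_std = np.empty((n, N_NODES))
    for mask, B, noise in (
        (~advanced, B_early, noise_early),
        (advanced, B_adv, noise_adv),
    ):
        if not mask.any():
            continue
        T2_std[mask] = (
            Z1[mask] @ B + Zc[mask] @ E + eps[mask] * noise
        )

    s_early = _total_sd(spec, B_early, noise_early, E)
    s_adv = _total_sd(spec, B_adv, noise_adv, E)
    scale = np.where(advanced[:, None], s_adv[None, :], s_early[None, :])

    t1_raw = np.clip(
        spec.t1_means[None, :] + spec.t1_sds[None, :] * Z1, 0.0, None
    )
    t2_raw = np.clip(
        spec.t2_means[None, :] + spec.t2_sds[None, :] * T2_std / scale,
        0.0,
        None,
    )

    dropout = rng.random(n) < spec.mcar_rate
    t2_raw[dropout] = np.nan

    values = pd.DataFrame(
        np.column_stack([t1_raw, t2_raw]),
        columns=[t1_column(c) for c in NODE_CODES]
        + [t2_column(c) for c in NODE_CODES],
    )
    data = PanelDataset(
        values,
        cov,
        pd.Series(stage, name="stage"),
        meta={"seed": spec.seed, "synthetic": True},
    )
    truth = B_early / s_early[None, :]
    truth_adv = (
        B_adv / s_adv[None, :] if spec.stage_shift is not None else None
    )
    return SyntheticCohort(data, truth, truth_adv, spec)


def stage_stratified(spec: SyntheticSpec) -> SyntheticCohort:
    """Cohort whose advanced-stage (III/IV) subjects follow the
    ``stage_shift`` cross-lagged structure; early-stage subjects follow
    ``cross_matrix``.  Identical to :func:`generate` when no shift is set."""
    return generate(spec)


def dichotomize_t2(data: PanelDataset) -> PanelDataset:
    """Median-split every T2 variable (0/1), for the logistic reading of
    the estimator; T1 variables and covariates are untouched."""
    values = data.values.copy()
    for code in NODE_CODES:
        col = t2_column(code)
        med = values[col].median()
        values[col] = (values[col] > med).astype(float).where(
            values[col].notna()
        )
    return PanelDataset(values, data.covariates.copy(), data.stage.copy(),
                        dict(data.meta))
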