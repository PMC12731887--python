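import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

import clpn
from clpn import synthetic as syn
from clpn.labels import NODE_CODES

hyp_settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def table3_network() -> clpn.CLPNetwork:
    return clpn.fixture_network()


@pytest.fixture(scope="session")
def default_cohort() -> syn.SyntheticCohort:
    """A reference-condition cohort at the study's analysed sample size."""
    return syn.generate(syn.default_spec(n=426, seed=11))


@pytest.fixture(scope="session")
def small_complete_cohort() -> clpn.PanelDataset:
    """Complete-case cohort small enough for repeated estimation."""
    cohort = syn.generate(syn.default_spec(n=240, seed=3, mcar_rate=0.0))
    return cohort.data


@pytest.fixture(scope="session")
def fast_settings() -> clpn.EstimationSettings:
    """Lighter CV settings for resampling-heavy tests."""
    return clpn.EstimationSettings(n_folds=5, n_lambdas=30, seed=0)


def null_spec(n: int, seed: int, **kw) -> syn.SyntheticSpec:
    """Spec with no temporal structure at all (pure noise T2)."""
    base = dict(
        n=n,
        seed=seed,
        cross_matrix=np.zeros((11, 11)),
        auto_coeffs=np.zeros(11),
        covariate_effects={},
        noise_sd=np.ones(11),
        mcar_rate=0.0,
    )
    base.update(kw)
    return syn.SyntheticSpec(**base)


def make_panel(values: np.ndarray, stage=None) -> clpn.PanelDataset:
    """PanelDataset from a raw (n, 22) array, no covariates."""
    values = np.asarray(values, dtype=float)
    cols = [f"{c}_T1" for c in NODE_CODES] + [f"{c}_T2" for c in NODE_CODES]
    df = pd.DataFrame(values, columns=cols)
    if stage is None:
        stage = pd.Series(["I"] * len(df))
    return clpn.PanelDataset(df, pd.DataFrame(index=df.index),
                             pd.Series(stage))
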