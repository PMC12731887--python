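import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import clpn
from clpn import synthetic as syn
from clpn._solver import cd_path, lasso_at
from clpn.estimator import EstimationSettings, fit_node
from clpn.exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from clpn.labels import NODE_CODES, NODES
from clpn.network import CLPNetwork, edge_census, strip_autoregressive, \
    to_odds_ratios
from conftest import make_panel, null_spec
from oracles import ista_lasso, ols, sklearn_lasso


def _toy(n=120, p=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.linspace(0.5, -0.3, p)
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestSolver:
    def test_zero_penalty_equals_least_squares(self):
        X, y = _toy(seed=1)
        np.testing.assert_allclose(lasso_at(X, y, 0.0), ols(X, y),
                                   atol=1e-6)

    @pytest.mark.parametrize("lam", [0.005, 0.05, 0.3])
    def test_matches_independent_coordinate_descent(self, lam):
        X, y = _toy(seed=2)
        np.testing.assert_allclose(
            lasso_at(X, y, lam), sklearn_lasso(X, y, lam), atol=1e-6
        )

    @pytest.mark.parametrize("lam", [0.01, 0.1])
    def test_matches_proximal_gradient_oracle(self, lam):
        X, y = _toy(seed=3)
        np.testing.assert_allclose(
            lasso_at(X, y, lam), ista_lasso(X, y, lam), atol=1e-6
        )

    def test_infinite_penalty_gives_zero_vector(self):
        X, y = _toy()
        assert np.all(lasso_at(X, y, np.inf) == 0)

    def test_support_monotone_along_path(self):
        X, y = _toy(n=200, p=8, seed=4)
        path = np.geomspace(1.0, 1e-4, 80)
        B = cd_path(X.T @ X, X.T @ y, len(y), path, 1e-10, 100_000)
        nnz = (np.abs(B) > 1e-9).sum(axis=1)
        # descending penalty: support can only grow (up to solver jitter
        # of truly-zero refits, which does not occur on this toy)
        assert np.all(np.diff(nnz) >= 0)


class TestFitNode:
    def test_forced_infinite_penalty_zeroes_all_lagged_coefficients(
        self, small_complete_cohort
    ):
        X = small_complete_cohort.t1().to_numpy()
        y = small_complete_cohort.values["D1_T2"].to_numpy()
        fit = fit_node(y, X, None, EstimationSettings(),
                       fixed_lambda=np.inf)
        assert np.all(fit.coefficients == 0)

    def test_zero_penalty_matches_closed_form_ols(
        self, small_complete_cohort
    ):
        X = small_complete_cohort.t1().to_numpy()
        y = small_complete_cohort.values["F2_T2"].to_numpy()
        fit = fit_node(y, X, None, EstimationSettings(), fixed_lambda=0.0)
        Xz = (X - X.mean(0)) / X.std(0)
        yz = (y - y.mean()) / y.std()
        np.testing.assert_allclose(fit.coefficients, ols(Xz, yz),
                                   atol=1e-6)

    def test_covariate_adjustment_recovers_planted_age_effect(self):
        cohort = syn.generate(syn.default_spec(n=8000, seed=17,
                                               mcar_rate=0.0))
        net = clpn.estimate_clpn(cohort.data, EstimationSettings(seed=0))
        age_effect = net.covariate_coeffs.loc["age", "D1"]
        assert age_effect == pytest.approx(0.05, abs=0.05)

    def test_constant_outcome_degenerate(self, small_complete_cohort):
        X = small_complete_cohort.t1().to_numpy()
        y = np.ones(len(X))
        with pytest.raises(DegenerateDataError):
            fit_node(y, X, None, EstimationSettings())

    def test_too_few_subjects(self):
        X = np.random.default_rng(0).standard_normal((10, 11))
        y = np.random.default_rng(1).standard_normal(10)
        with pytest.raises(InsufficientDataError):
            fit_node(y, X, None, EstimationSettings())


class TestEstimateClpn:
    def test_missing_values_rejected(self):
        cohort = syn.generate(syn.default_spec(n=200, seed=1,
                                               mcar_rate=0.3))
        with pytest.raises(ValidationError, match="listwise"):
            clpn.estimate_clpn(cohort.data)

    def test_deterministic_given_settings_seed(self, small_complete_cohort):
        s = EstimationSettings(seed=5)
        a = clpn.estimate_clpn(small_complete_cohort, s)
        b = clpn.estimate_clpn(small_complete_cohort, s)
        np.testing.assert_array_equal(a.coeff, b.coeff)
        np.testing.assert_array_equal(a.lambda_per_node, b.lambda_per_node)

    def test_or_matrix_is_exponential_of_coefficients(
        self, small_complete_cohort
    ):
        net = clpn.estimate_clpn(small_complete_cohort,
                                 EstimationSettings(seed=0))
        np.testing.assert_allclose(net.or_matrix, np.exp(net.coeff),
                                   atol=1e-12)
        assert np.all((net.coeff == 0) == (net.or_matrix == 1))

    def test_null_cohort_is_sparse(self):
        """With no temporal structure, the CV-min fit retains few spurious
        cross-lagged edges and the one-SE fit none."""
        d = syn.generate(null_spec(n=426, seed=2)).data
        off = ~np.eye(11, dtype=bool)
        net_min = clpn.estimate_clpn(d, EstimationSettings(seed=0))
        assert (np.abs(net_min.coeff[off]) < 1e-9).mean() >= 0.80
        net_1se = clpn.estimate_clpn(
            d, EstimationSettings(seed=0, lambda_rule="1se")
        )
        assert (np.abs(net_1se.coeff[off]) < 1e-9).mean() >= 0.95

    def test_sign_pattern_of_large_truth_recovered_at_large_n(self):
        cohort = syn.generate(syn.default_spec(n=10_000, seed=23,
                                               mcar_rate=0.0))
        net = clpn.estimate_clpn(cohort.data, EstimationSettings(seed=0))
        truth = cohort.truth.copy()
        np.fill_diagonal(truth, 0.0)
        big = np.abs(truth) >= 0.15
        est = net.coeff.copy()
        np.fill_diagonal(est, 0.0)
        assert np.all(np.sign(est[big]) == np.sign(truth[big]))

    def test_relabeling_equivariance(self, small_complete_cohort):
        """Permuting the node order of the input data permutes the
        estimated adjacency identically."""
        perm = np.random.default_rng(0).permutation(11)
        codes = [NODE_CODES[i] for i in perm]
        vals = small_complete_cohort.values.copy()
        renamed = vals[[f"{c}_T1" for c in codes]
                       + [f"{c}_T2" for c in codes]]
        renamed.columns = [f"{c}_T1" for c in NODE_CODES] + [
            f"{c}_T2" for c in NODE_CODES
        ]
        permuted = make_panel(renamed.to_numpy())
        base = clpn.estimate_clpn(
            make_panel(small_complete_cohort.values.to_numpy()),
            EstimationSettings(seed=0),
        )
        swapped = clpn.estimate_clpn(permuted, EstimationSettings(seed=0))
        np.testing.assert_allclose(
            swapped.coeff, base.coeff[np.ix_(perm, perm)], atol=1e-6
        )

    def test_logistic_mode_runs_and_reports_odds_ratios(
        self, small_complete_cohort
    ):
        net = clpn.estimate_clpn(
            small_complete_cohort,
            EstimationSettings(mode="logistic", n_folds=5, n_lambdas=15,
                              seed=0),
        )
        assert np.isfinite(net.coeff).all()
        np.testing.assert_allclose(net.or_matrix, np.exp(net.coeff))
        assert net.meta["mode"] == "logistic"


class TestTransforms:
    def test_exponentiation_examples(self):
        assert to_odds_ratios(np.array(0.0)) == 1.0
        assert to_odds_ratios(np.log(1.332)) == pytest.approx(1.332)

    @given(
        st.lists(st.floats(-2, 2), min_size=4, max_size=4).map(np.array)
    )
    def test_log_inverts_exponentiation(self, coeffs):
        np.testing.assert_allclose(
            np.log(to_odds_ratios(coeffs)), coeffs, atol=1e-12
        )

    def test_strip_autoregressive_on_fixture_is_identity(
        self, table3_network
    ):
        stripped = strip_autoregressive(table3_network)
        np.testing.assert_array_equal(stripped.coeff, table3_network.coeff)

    def test_strip_autoregressive_zeroes_diagonal_and_is_idempotent(self):
        coeff = np.random.default_rng(0).normal(size=(11, 11))
        net = CLPNetwork(NODES, coeff)
        once = strip_autoregressive(net)
        assert np.all(np.diag(once.coeff) == 0)
        off = ~np.eye(11, dtype=bool)
        np.testing.assert_array_equal(once.coeff[off], coeff[off])
        twice = strip_autoregressive(once)
        np.testing.assert_array_equal(once.coeff, twice.coeff)


class TestEdgeCensus:
    def test_fixture_census(self, table3_network):
        census = edge_census(table3_network)
        assert census.n_nonzero_cross == 57
        assert census.n_positive == 31
        assert census.positive_share == pytest.approx(31 / 57)
        assert census.mean_or_auto is None  # printed diagonal is all 1.000

    def test_empty_network_flags_undefined_shares(self):
        census = edge_census(CLPNetwork(NODES, np.zeros((11, 11))))
        assert census.n_nonzero_cross == 0
        assert census.positive_share is None
        assert census.mean_or_cross is None

    def test_two_up_two_down(self):
        coeff = np.zeros((11, 11))
        coeff[0, 1] = coeff[0, 2] = 0.2
        coeff[1, 2] = coeff[1, 3] = -0.2
        census = edge_census(CLPNetwork(NODES, coeff))
        assert census.n_nonzero_cross == 4
        assert census.positive_share == 0.5


def test_network_json_round_trip(tmp_path, small_complete_cohort):
    net = clpn.estimate_clpn(small_complete_cohort,
                             EstimationSettings(seed=0))
    path = tmp_path / "net.json"
    net.to_json(path)
    again = CLPNetwork.from_json(path)
    np.testing.assert_allclose(again.coeff, net.coeff)
    assert again.codes == net.codes
    pd.testing.assert_frame_equal(again.covariate_coeffs,
                                  net.covariate_coeffs)
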