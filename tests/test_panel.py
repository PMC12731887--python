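import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import clpn
from clpn.exceptions import (
    DomainError,
    EmptyDataError,
    MappingError,
    SchemaError,
    ValidationError,
)
from clpn.labels import NODE_CODES
from clpn.panel import DEFAULT_SCHEMA, cronbach_alpha, score_items
from conftest import make_panel
from oracles import row_sums_by_subscale, spearman_brown_alpha


def _csv_bytes(df: pd.DataFrame) -> io.StringIO:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


def _minimal_frame(n=3) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    data = {"subject_id": range(n), "stage": ["I"] * n}
    for c in NODE_CODES:
        data[f"{c}_T1"] = rng.uniform(0, 5, n).round(2)
        data[f"{c}_T2"] = rng.uniform(0, 5, n).round(2)
    return pd.DataFrame(data)


class TestReadPanel:
    def test_round_trip_small_csv(self):
        data = clpn.read_panel(_csv_bytes(_minimal_frame(3)))
        assert data.subjects == 3
        assert not data.missing_mask.any().any()

    def test_missing_required_column_names_it(self):
        df = _minimal_frame().drop(columns=["F7_T2"])
        with pytest.raises(SchemaError, match="F7_T2"):
            clpn.read_panel(_csv_bytes(df))

    def test_duplicate_subject_id_rejected(self):
        df = _minimal_frame(3)
        df["subject_id"] = [1, 1, 2]
        with pytest.raises(ValidationError, match="duplicate"):
            clpn.read_panel(_csv_bytes(df))

    def test_unparseable_cell_becomes_missing(self):
        df = _minimal_frame(3).astype({"D1_T2": object})
        df.loc[1, "D1_T2"] = "not-a-number"
        data = clpn.read_panel(_csv_bytes(df))
        assert data.missing_mask.loc[1, "D1_T2"]
        assert data.missing_mask.to_numpy().sum() == 1

    def test_generated_cohort_round_trips_through_csv(self, tmp_path):
        from clpn import synthetic as syn

        cohort = syn.generate(syn.default_spec(n=450, seed=1))
        path = tmp_path / "cohort.csv"
        cohort.data.to_csv(path)
        again = clpn.read_panel(path)
        assert again.subjects == 450
        pd.testing.assert_frame_equal(
            again.values.reset_index(drop=True), cohort.data.values
        )

    def test_negative_scores_rejected(self):
        df = _minimal_frame(3)
        df.loc[0, "D1_T1"] = -1.0
        with pytest.raises(ValidationError, match="non-negative"):
            clpn.read_panel(_csv_bytes(df))


class TestScoring:
    def _items(self, n, n_items, rng):
        cols = {}
        item_map = {}
        codes = ["D1", "D2", "F1"]
        for i in range(n_items):
            name = f"item{i}"
            item_map[name] = codes[i % len(codes)]
            cols[f"{name}_T1"] = rng.integers(0, 5, n)
            cols[f"{name}_T2"] = rng.integers(0, 5, n)
        return pd.DataFrame(cols), item_map

    def test_all_zero_items_give_zero_subscales(self):
        items, item_map = self._items(4, 6, np.random.default_rng(0))
        items[:] = 0
        data = clpn.score_subscales(items, item_map)
        assert (data.values.to_numpy() == 0).all()

    def test_single_item_response_lands_in_its_subscale(self):
        items = pd.DataFrame(
            {"a_T1": [1.0, 0.0], "b_T1": [0.0, 0.0],
             "a_T2": [0.0, 0.0], "b_T2": [0.0, 0.0]}
        )
        data = clpn.score_subscales(items, {"a": "D2", "b": "D3"})
        assert data.values.loc[0, "D2_T1"] == 1.0
        assert data.values.drop(columns="D2_T1").to_numpy().sum() == 0

    def test_scores_match_brute_force_row_sums(self):
        rng = np.random.default_rng(42)
        items, item_map = self._items(25, 9, rng)
        data = clpn.score_subscales(items, item_map)
        t1 = items[[c for c in items if c.endswith("_T1")]]
        t1 = t1.rename(columns=lambda c: c[:-3])
        expected = row_sums_by_subscale(t1, item_map, NODE_CODES)
        for code, vals in expected.items():
            np.testing.assert_allclose(
                data.values[f"{code}_T1"].to_numpy(), vals
            )

    def test_unmapped_item_raises(self):
        items = pd.DataFrame({"a_T1": [1], "a_T2": [1], "b_T1": [1],
                              "b_T2": [1]})
        with pytest.raises(MappingError, match="b"):
            clpn.score_subscales(items, {"a": "D1"})

    def test_score_items_rejects_unknown_subscale(self):
        items = pd.DataFrame({"a": [1]})
        with pytest.raises(MappingError):
            score_items(items, {"a": "D9"})


class TestDaPresent:
    @pytest.mark.parametrize(
        "score,expected",
        [(7.0, True), (6.99, False), (8.25, True), (0.0, False)],
    )
    def test_screening_cutoff_at_seven(self, score, expected):
        assert clpn.da_present(score) is expected

    def test_negative_score_rejected(self):
        with pytest.raises(DomainError):
            clpn.da_present(-0.5)

    def test_vectorized(self):
        np.testing.assert_array_equal(
            clpn.da_present([6.0, 7.0, 10.0]), [False, True, True]
        )


class TestListwise:
    def test_study_dropout_pattern_gives_stated_retention(self):
        # 450 recruited, 24 lost the entire follow-up wave
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 5, size=(450, 22))
        vals[:24, 11:] = np.nan
        result = clpn.listwise_complete(make_panel(vals))
        assert result.n_retained == 426
        assert result.n_dropped == 24
        assert round(result.retention_pct, 2) == 94.67

    def test_identity_on_complete_data(self, small_complete_cohort):
        result = clpn.listwise_complete(small_complete_cohort)
        assert result.n_retained == result.n_input
        pd.testing.assert_frame_equal(
            result.data.values, small_complete_cohort.values
        )

    def test_idempotent_and_counts_partition(self):
        from clpn import synthetic as syn

        cohort = syn.generate(syn.default_spec(n=450, seed=7,
                                               mcar_rate=0.0467))
        r1 = clpn.listwise_complete(cohort.data)
        assert r1.n_retained + r1.n_dropped == 450
        # retained count equals rows with fully observed follow-up
        expected = int((~cohort.data.missing_mask.any(axis=1)).sum())
        assert r1.n_retained == expected
        r2 = clpn.listwise_complete(r1.data)
        assert r2.n_retained == r1.n_retained

    def test_all_missing_raises(self):
        vals = np.full((5, 22), np.nan)
        vals[:, :11] = 1.0
        with pytest.raises(EmptyDataError):
            clpn.listwise_complete(make_panel(vals))


class TestDescriptives:
    def test_constant_column_and_closed_form_sd(self):
        vals = np.ones((2, 22))
        vals[:, 0] = [0.0, 2.0]  # D1_T1 takes values {0, 2}
        desc = clpn.descriptives(make_panel(vals))
        assert desc.loc["D1", "t1_mean"] == 1.0
        assert desc.loc["D1", "t1_sd"] == pytest.approx(np.sqrt(2))
        assert desc.loc["D2", "t1_sd"] == 0.0

    def test_calibrated_cohort_reproduces_target_means(self):
        from clpn import synthetic as syn

        cohort = syn.generate(syn.default_spec(n=10_000, seed=5,
                                               mcar_rate=0.0))
        desc = clpn.descriptives(cohort.data)
        assert abs(desc.loc["D1", "t1_mean"] - 3.30) < 0.1

    def test_matches_independent_scoring_route(self):
        rng = np.random.default_rng(1)
        items, item_map = TestScoring()._items(30, 12, rng)
        data = clpn.score_subscales(items, item_map)
        desc = clpn.descriptives(data)
        t1 = items[[c for c in items if c.endswith("_T1")]]
        t1 = t1.rename(columns=lambda c: c[:-3])
        sums = row_sums_by_subscale(t1, item_map, NODE_CODES)
        for code, vals in sums.items():
            assert desc.loc[code, "t1_mean"] == pytest.approx(vals.mean())
            assert desc.loc[code, "t1_sd"] == pytest.approx(
                vals.std(ddof=1)
            )


class TestCronbachAlpha:
    @given(
        k=st.integers(2, 8),
        rho=st.floats(0.05, 0.9),
        seed=st.integers(0, 10_000),
    )
    def test_matches_spearman_brown_on_exchangeable_items(self, k, rho,
                                                          seed):
        # construct items whose *sample* covariance is exactly exchangeable
        rng = np.random.default_rng(seed)
        n = 50
        raw = rng.standard_normal((n, k))
        raw -= raw.mean(axis=0)
        cov = np.cov(raw.T, ddof=1)
        white = raw @ np.linalg.inv(np.linalg.cholesky(cov)).T
        target = np.full((k, k), rho)
        np.fill_diagonal(target, 1.0)
        items = pd.DataFrame(white @ np.linalg.cholesky(target).T)
        alpha = cronbach_alpha(items)
        assert alpha == pytest.approx(spearman_brown_alpha(k, rho),
                                      abs=1e-9)

    def test_duplicated_items_give_alpha_one(self):
        col = np.random.default_rng(0).normal(size=40)
        items = pd.DataFrame({f"i{j}": col for j in range(4)})
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_give_alpha_near_zero(self):
        rng = np.random.default_rng(9)
        items = pd.DataFrame(rng.standard_normal((20_000, 5)))
        assert abs(cronbach_alpha(items)) < 0.05

    def test_single_item_rejected(self):
        with pytest.raises(DomainError):
            cronbach_alpha(pd.DataFrame({"a": [1, 2, 3]}))


def test_default_schema_covers_all_nodes():
    assert set(DEFAULT_SCHEMA["t1"]) == set(NODE_CODES)
    assert set(DEFAULT_SCHEMA["t2"]) == set(NODE_CODES)
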