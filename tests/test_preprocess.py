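import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from xtissue.core_io import XTissueError
from xtissue.preprocess import (
    ResidualizationSpec,
    collapse_duplicate_symbols,
    flag_pca_outliers,
    intersect_genes,
    propensity_match_1to1,
    quantile_normalize,
    residualize_expression,
)

from conftest import make_dataset


class TestQuantileNormalize:
    def test_two_columns_hand_computed(self):
        m = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_idempotent(self, rng):
        m = rng.standard_normal((50, 6))
        once = quantile_normalize(m)
        np.testing.assert_allclose(quantile_normalize(once), once, atol=1e-12)

    def test_ties_get_mean_of_tied_positions(self):
        m = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(m)
        # reference is [5.5, 10.5, 17.5]; tied pair in column 0 -> mean(5.5, 10.5)
        np.testing.assert_allclose(out[:, 0], [8.0, 8.0, 17.5])

    def test_single_column_warns_and_passes_through(self, caplog):
        m = np.array([[1.0], [2.0]])
        with caplog.at_level("WARNING", logger="xtissue.preprocess"):
            out = quantile_normalize(m)
        np.testing.assert_array_equal(out, m)
        assert any("single column" in r.message for r in caplog.records)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            (20, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_rank_order_preserved_and_column_means_equal(self, m):
        out = quantile_normalize(m)
        for j in range(m.shape[1]):
            # weak ordering preserved within each column
            order = np.argsort(m[:, j], kind="stable")
            assert np.all(np.diff(out[order, j]) >= -1e-12)
        assert np.ptp(out.mean(axis=0)) < 1e-9


class TestCollapseAndIntersect:
    def test_duplicate_rows_averaged_in_first_occurrence_order(self):
        ds = make_dataset(
            [[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]], genes=["GAPDH", "ACTB", "GAPDH"]
        )
        out = collapse_duplicate_symbols(ds)
        assert out.gene_symbols == ["GAPDH", "ACTB"]
        np.testing.assert_allclose(out.matrix[0], [2.0, 2.0])

    def test_no_duplicates_is_identity(self):
        ds = make_dataset(np.ones((3, 2)))
        assert collapse_duplicate_symbols(ds) is ds

    def test_three_duplicates_mean(self):
        ds = make_dataset([[0.0, 0], [0, 0], [6, 6]], genes=["A", "A", "A"])
        out = collapse_duplicate_symbols(ds)
        np.testing.assert_allclose(out.matrix, [[2.0, 2.0]])

    def test_intersection_sorted_common_genes(self):
        d1 = make_dataset(np.arange(6.0).reshape(3, 2), genes=["A", "B", "C"])
        d2 = make_dataset(np.arange(6.0).reshape(3, 2), genes=["B", "C", "D"])
        o1, o2 = intersect_genes([d1, d2])
        assert o1.gene_symbols == o2.gene_symbols == ["B", "C"]

    def test_three_datasets_common_subset(self, rng):
        genes = [f"G{i}" for i in range(20)]
        shared = genes[:5]
        ds = [
            make_dataset(
                rng.standard_normal((10, 2)), genes=shared + genes[5 + 5 * k : 10 + 5 * k]
            )
            for k in range(3)
        ]
        outs = intersect_genes(ds)
        assert all(o.gene_symbols == sorted(shared) for o in outs)

    def test_empty_intersection_errors(self):
        d1 = make_dataset(np.ones((1, 2)), genes=["A"])
        d2 = make_dataset(np.ones((1, 2)), genes=["B"])
        with pytest.raises(XTissueError, match="empty"):
            intersect_genes([d1, d2])


class TestPcaOutliers:
    def test_no_flags_on_iid_data(self, rng):
        ds = make_dataset(rng.standard_normal((40, 30)))
        assert flag_pca_outliers(ds, sd_threshold=6.0) == []

    def test_planted_outlier_recovered(self, rng):
        m = rng.standard_normal((40, 30))
        direction = rng.standard_normal(40)
        direction /= np.linalg.norm(direction)
        m[:, 7] += 30.0 * direction
        ds = make_dataset(m)
        assert flag_pca_outliers(ds, sd_threshold=4.0) == ["s7"]

    def test_zero_threshold_flags_everything(self, rng):
        ds = make_dataset(rng.standard_normal((20, 10)))
        assert len(flag_pca_outliers(ds, sd_threshold=0.0)) == 10

    def test_zero_variance_warns_and_flags_nothing(self, caplog):
        ds = make_dataset(np.ones((5, 4)))
        with caplog.at_level("WARNING", logger="xtissue.preprocess"):
            assert flag_pca_outliers(ds) == []


class TestResidualize:
    def test_residuals_orthogonal_to_age(self, rng):
        age = rng.uniform(20, 80, 30)
        expr = 2.0 * age + 0.001 * rng.standard_normal(30)
        ds = make_dataset(expr[None, :], age=age)
        out = residualize_expression(ds, ResidualizationSpec(("age",)))
        assert abs(np.corrcoef(out.matrix[0], age)[0, 1]) < 1e-8

    def test_empty_spec_is_mean_centering(self, rng):
        ds = make_dataset(rng.standard_normal((5, 12)) + 7.0)
        out = residualize_expression(ds, ResidualizationSpec(()))
        np.testing.assert_allclose(
            out.matrix, ds.matrix - ds.matrix.mean(axis=1, keepdims=True)
        )

    def test_matches_normal_equations_solve(self, rng):
        n = 40
        age = rng.uniform(20, 80, n)
        sex = rng.choice(["male", "female"], n)
        pmi = rng.uniform(4, 30, n)
        expr = rng.standard_normal((6, n))
        ds = make_dataset(expr, age=age, sex=sex, pmi=pmi)
        spec = ResidualizationSpec(("sex", "age", "age_squared", "pmi"))
        out = residualize_expression(ds, spec)
        # independent direct solve
        D = np.column_stack(
            [
                np.ones(n),
                (sex == "male").astype(float),
                age,
                (age - age.mean()) ** 2,
                pmi,
            ]
        )
        beta = np.linalg.solve(D.T @ D, D.T @ expr.T)
        np.testing.assert_allclose(out.matrix, (expr.T - D @ beta).T, atol=1e-8)

    def test_orthogonal_to_all_numeric_design_columns(self, rng):
        n = 30
        age = rng.uniform(20, 80, n)
        pmi = rng.uniform(4, 30, n)
        ds = make_dataset(rng.standard_normal((8, n)), age=age, pmi=pmi)
        out = residualize_expression(
            ds, ResidualizationSpec(("age", "age_squared", "pmi"))
        )
        for cov in (age, (age - age.mean()) ** 2, pmi):
            r = np.abs([np.corrcoef(row, cov)[0, 1] for row in out.matrix])
            assert r.max() < 1e-8

    def test_collinear_design_dropped_with_warning(self, rng, caplog):
        n = 20
        age = rng.uniform(20, 80, n)
        ds = make_dataset(rng.standard_normal((3, n)), age=age, pmi=age)
        with caplog.at_level("WARNING", logger="xtissue.preprocess"):
            residualize_expression(ds, ResidualizationSpec(("age", "pmi")))
        assert any("rank-deficient" in r.message for r in caplog.records)

    def test_missing_covariate_value_errors(self, rng):
        ds = make_dataset(
            np.ones((2, 4)), age=[40.0, np.nan, 50.0, 60.0]
        )
        with pytest.raises(XTissueError, match="age"):
            residualize_expression(ds, ResidualizationSpec(("age",)))

    def test_permutation_equivariance(self, rng):
        n = 24
        age = rng.uniform(20, 80, n)
        ds = make_dataset(rng.standard_normal((5, n)), age=age)
        out = residualize_expression(ds, ResidualizationSpec(("age",)))
        perm = rng.permutation(n)
        ids = [ds.sample_ids[i] for i in perm]
        out_perm = residualize_expression(
            ds.subset_samples(ids), ResidualizationSpec(("age",))
        )
        np.testing.assert_allclose(out_perm.matrix, out.matrix[:, perm], atol=1e-10)


def _meta(diag, **cols):
    ids = [f"s{i}" for i in range(len(diag))]
    return pd.DataFrame({"diagnosis": diag, **cols}, index=pd.Index(ids, name="sample_id"))


class TestPropensityMatching:
    def test_identical_covariates_all_matched_zero_smd(self, rng):
        n_case, n_ctrl = 6, 10
        age = np.full(n_case + n_ctrl, 50.0)
        meta = _meta(
            ["case"] * n_case + ["control"] * n_ctrl,
            age=age, sex=["male"] * (n_case + n_ctrl), pmi=np.full(n_case + n_ctrl, 12.0),
        )
        res = propensity_match_1to1(meta)
        assert len(res.matched_pairs) == n_case
        assert (res.balance["smd_after"] <= 1e-12).all()

    def test_one_to_one_pair_count(self, rng):
        meta = _meta(
            ["case"] * 5 + ["control"] * 20,
            age=rng.uniform(30, 70, 25),
            sex=rng.choice(["male", "female"], 25),
            pmi=rng.uniform(5, 25, 25),
        )
        res = propensity_match_1to1(meta)
        assert len(res.matched_pairs) == 5
        ids = [s for p in res.matched_pairs for s in p]
        assert len(set(ids)) == 10

    def test_age_matched_controls_preferred(self, rng):
        # 5 controls share case ages exactly; 15 are 30 years older
        case_ages = np.array([40.0, 45.0, 50.0, 55.0, 60.0])
        ctrl_ages = np.concatenate([case_ages, case_ages.repeat(3) + 30.0])
        meta = _meta(
            ["case"] * 5 + ["control"] * 20,
            age=np.concatenate([case_ages, ctrl_ages]),
            sex=["male"] * 25,
            pmi=np.full(25, 10.0),
        )
        res = propensity_match_1to1(meta)
        matched_ctrl_ages = sorted(meta.loc[c, "age"] for _, c in res.matched_pairs)
        assert matched_ctrl_ages == sorted(case_ages)

    def test_smd_does_not_increase(self, rng):
        meta = _meta(
            ["case"] * 10 + ["control"] * 40,
            age=np.concatenate([rng.normal(45, 5, 10), rng.normal(55, 10, 40)]),
            sex=rng.choice(["male", "female"], 50),
            pmi=rng.uniform(5, 25, 50),
        )
        res = propensity_match_1to1(meta)
        assert (
            res.balance["smd_after"].mean()
            <= res.balance["smd_before"].mean() + 1e-12
        )

    def test_fewer_controls_than_cases_errors(self):
        meta = _meta(["case"] * 4 + ["control"] * 2, age=np.arange(6.0),
                     sex=["male"] * 6, pmi=np.ones(6))
        with pytest.raises(XTissueError, match="swap roles"):
            propensity_match_1to1(meta)
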