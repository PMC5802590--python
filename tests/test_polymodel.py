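import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xtissue.core_io import PipelineConfig, XTissueError
from xtissue.polymodel import (
    ScadModel,
    BaggedEnsemble,
    _scad_univariate,
    bagged_train,
    cv_l1_binomial,
    fit_penalized_binomial,
    fit_scad_binomial_cv,
    iterative_select,
    oob_scores,
    predict_scores,
    rank_genes_by_correlation,
    residualize_outcome,
    scad_threshold,
)

from conftest import make_dataset


def newton_logistic_mle(X, y, iters=100):
    """Independent Newton-Raphson solver for the unpenalized binomial MLE."""
    X1 = np.column_stack([np.ones(len(y)), X])
    b = np.zeros(X1.shape[1])
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-X1 @ b))
        W = p * (1 - p)
        H = X1.T @ (X1 * W[:, None])
        g = X1.T @ (y - p)
        step = np.linalg.solve(H, g)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return b[0], b[1:]


class TestRankGenes:
    def test_perfect_gene_found(self, rng):
        n = 60
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 21))
        X[:, 13] = y
        symbols = [f"G{i:02d}" for i in range(21)]
        assert rank_genes_by_correlation(X, symbols, y, 1) == ["G13"]

    def test_planted_correlation_ladder(self, rng):
        n = 5000
        y = rng.standard_normal(n)
        target_r = np.linspace(0.9, 0.0, 10)
        X = np.empty((n, 10))
        for i, r in enumerate(target_r):
            X[:, i] = r * y + math.sqrt(max(1 - r * r, 1e-12)) * rng.standard_normal(n)
        symbols = [f"G{i}" for i in range(10)]
        top3 = rank_genes_by_correlation(X, symbols, y, 3)
        assert top3 == ["G0", "G1", "G2"]

    def test_ties_broken_by_symbol_order(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        col = np.array([1.0, 2.0, 1.0, 2.0])
        X = np.column_stack([col, col, col])
        assert rank_genes_by_correlation(X, ["Zz", "Aa", "Mm"], y, 2) == ["Aa", "Mm"]

    def test_constant_outcome_errors(self):
        with pytest.raises(XTissueError, match="constant"):
            rank_genes_by_correlation(np.ones((5, 2)), ["A", "B"], np.ones(5), 1)

    def test_zero_variance_gene_gets_zero_correlation(self, rng):
        y = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), y])
        assert rank_genes_by_correlation(X, ["FLAT", "LIVE"], y, 1) == ["LIVE"]


class TestCvL1:
    def test_planted_predictor_recovered(self, rng):
        n = 100
        X = rng.standard_normal((n, 21))
        eta = 3.0 * X[:, 5]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        symbols = [f"G{i}" for i in range(21)]
        sel = cv_l1_binomial(X, symbols, y, folds=5, seed=3)
        assert "G5" in sel

    def test_matches_reference_l1_solver(self, rng):
        # cross-check coefficients against liblinear at a fixed lambda
        from sklearn.linear_model import LogisticRegression

        n, p = 200, 8
        X = rng.standard_normal((n, p))
        eta = 1.5 * X[:, 0] - 1.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        lam = 0.05
        from xtissue.polymodel import _binomial_cd_path, _standardize

        Xs, mu, sd = _standardize(X)
        betas, b0s, _ = _binomial_cd_path(
            Xs, y, np.array([lam]), penalty="l1", tol=1e-9
        )
        ref = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=1.0 / (n * lam), tol=1e-10,
            max_iter=5000, intercept_scaling=100.0,
        ).fit(Xs, y)
        # liblinear penalizes its (rescaled) intercept, so agreement is
        # close but not exact
        np.testing.assert_allclose(betas[0], ref.coef_.ravel(), atol=2e-3)
        assert set(np.flatnonzero(betas[0])) == set(np.flatnonzero(ref.coef_.ravel()))

    def test_huge_lambda_grid_triggers_fallback(self, rng, caplog):
        n = 80
        X = rng.standard_normal((n, 5))
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * X[:, 0]))).astype(float)
        with caplog.at_level("WARNING", logger="xtissue.polymodel"):
            sel = cv_l1_binomial(
                X, list("ABCDE"), y, folds=4,
                lambda_grid=np.array([1e6, 1e5]), seed=0,
            )
        assert sel == []
        assert any("no nonzero" in r.message for r in caplog.records)

    def test_duplicate_gene_sparsity(self, rng):
        # exact duplicates: at a strong penalty the L1 solution keeps <= 1
        n = 150
        g = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * g))).astype(float)
        X = np.column_stack([g, g, rng.standard_normal(n)])
        from xtissue.polymodel import _binomial_cd_path, _standardize

        Xs, _, _ = _standardize(X)
        betas, _, _ = _binomial_cd_path(Xs, y, np.array([0.08]), penalty="l1")
        assert int(np.sum(betas[0][:2] != 0)) <= 1


class TestResidualizeOutcome:
    def test_deviance_residual_hand_value(self):
        # y=(0,1) with fitted p=(0.5,0.5): residuals -/+ sqrt(2 ln 2)
        y = np.array([0.0, 1.0])
        X = np.zeros((2, 1))  # no information: fit gives p = 0.5
        res = residualize_outcome(y, X)
        expect = math.sqrt(2 * math.log(2))
        np.testing.assert_allclose(res, [-expect, expect], atol=1e-6)

    def test_perfect_predictor_residuals_tiny(self, rng):
        n = 40
        y = rng.integers(0, 2, n).astype(float)
        X = (2 * y - 1)[:, None]
        res = residualize_outcome(y, X)
        assert np.max(np.abs(res)) < 0.01

    def test_uninformative_predictors_near_null_residuals(self, rng):
        n = 200
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 2))
        res = residualize_outcome(y, X)
        p0 = y.mean()
        null = np.sign(y - p0) * np.sqrt(
            -2 * (y * np.log(p0) + (1 - y) * np.log(1 - p0))
        )
        assert np.corrcoef(res, null)[0, 1] > 0.95

    def test_pearson_kind(self, rng):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        res = residualize_outcome(y, np.zeros((4, 1)), kind="pearson")
        np.testing.assert_allclose(np.abs(res), np.ones(4), atol=1e-6)


class TestScadThreshold:
    @pytest.mark.parametrize(
        "z,lam,expected",
        [
            (0.5, 1.0, 0.0),
            (5.0, 1.0, 5.0),
            (3.0, 1.0, (2.7 * 3 - 3.7) / 1.7),
            (-3.0, 1.0, -(2.7 * 3 - 3.7) / 1.7),
        ],
    )
    def test_branch_values(self, z, lam, expected):
        assert scad_threshold(z, lam, 3.7) == pytest.approx(expected, abs=1e-12)

    def test_invalid_a_errors(self):
        with pytest.raises(XTissueError):
            scad_threshold(1.0, 1.0, a=2.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-20, 20), st.floats(0.01, 3.0))
    def test_odd_and_identity_beyond_a_lambda(self, z, lam):
        a = 3.7
        out = scad_threshold(z, lam, a)
        assert out == pytest.approx(-scad_threshold(-z, lam, a), abs=1e-12)
        if abs(z) > a * lam:
            assert out == pytest.approx(z, abs=1e-12)

    def test_continuity_at_region_boundaries(self):
        for lam in (0.5, 1.0, 2.0):
            for edge in (2 * lam, 3.7 * lam):
                lo = scad_threshold(edge - 1e-9, lam)
                hi = scad_threshold(edge + 1e-9, lam)
                assert abs(lo - hi) < 1e-6

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(0.01, 2.0))
    def test_univariate_solver_matches_threshold_at_unit_curvature(self, z, lam):
        # orthonormal design (unit curvature) one-step solution
        assert _scad_univariate(z, 1.0, lam, 3.7) == pytest.approx(
            scad_threshold(z, lam, 3.7), abs=1e-10
        )


class TestScadFit:
    def test_lambda_zero_matches_independent_newton(self, rng):
        n, p = 150, 5
        X = rng.standard_normal((n, p))
        eta = X @ np.array([0.8, -0.5, 0.3, 0.0, 0.2])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        coefs, intercept, conv = fit_penalized_binomial(
            X, y, lam=0.0, tol=1e-10, max_iter=5000
        )
        b0_ref, b_ref = newton_logistic_mle(X, y)
        assert conv
        np.testing.assert_allclose(coefs, b_ref, atol=1e-4)
        assert intercept == pytest.approx(b0_ref, abs=1e-4)

    def test_full_shrinkage_above_max_lambda(self, rng):
        n = 120
        X = rng.standard_normal((n, 4))
        y = (rng.random(n) < 0.3).astype(float)
        if y.mean() in (0, 1):
            y[0] = 1 - y[0]
        cfg = PipelineConfig(lambda_grid=np.array([50.0, 20.0]), cv_folds=3)
        model = fit_scad_binomial_cv(X, list("ABCD"), y, cfg, seed=0)
        assert np.all(model.coefficients == 0)
        assert model.intercept == pytest.approx(
            math.log(y.mean() / (1 - y.mean())), abs=1e-5
        )

    def test_cv_selects_sparse_informative_model(self, rng):
        n = 200
        X = rng.standard_normal((n, 10))
        eta = 2.0 * X[:, 0] - 1.5 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cfg = PipelineConfig(lambda_grid=np.geomspace(0.5, 1e-3, 12), cv_folds=5)
        model = fit_scad_binomial_cv(X, [f"G{i}" for i in range(10)], y, cfg, seed=1)
        nz = {g for g, c in zip(model.genes, model.coefficients) if c != 0}
        assert {"G0", "G1"} <= nz


class TestIterativeSelect:
    def test_single_round_equals_rank_then_l1(self, rng, small_config):
        n = 100
        X = rng.standard_normal((n, 50))
        eta = 2.5 * X[:, 7]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        symbols = [f"G{i:02d}" for i in range(50)]
        cfg = small_config
        cfg.m_rounds = 1
        state = iterative_select(X, symbols, y, cfg, seed=5)
        ranked = rank_genes_by_correlation(X, symbols, y, n // 10)
        idx = [symbols.index(s) for s in ranked]
        direct = cv_l1_binomial(
            X[:, idx], ranked, y, folds=cfg.cv_folds,
            lambda_grid=cfg.lambda_grid, seed=5 + 1,
        )
        assert state.all_selected == direct
        assert state.round == 1

    def test_predictor_budget_212_samples(self, rng):
        # two rounds at n = floor(212/10) = 21 genes per round keeps the
        # predictor union under 50
        n = 212
        X = rng.standard_normal((n, 400))
        planted = rng.choice(400, 20, replace=False)
        eta = X[:, planted] @ rng.normal(0.6, 0.1, 20)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cfg = PipelineConfig(
            lambda_grid=np.geomspace(0.5, 1e-3, 12), cv_folds=5, m_rounds=2
        )
        state = iterative_select(X, [f"G{i}" for i in range(400)], y, cfg, seed=0)
        total = len(state.all_selected)
        assert 0 < total < 50

    def test_rounds_are_disjoint_and_both_signals_found(self, rng):
        n = 200
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        eta = 2.2 * z1 + 2.2 * z2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([z1, z2, rng.standard_normal((n, 48))])
        symbols = ["SIG1", "SIG2"] + [f"N{i}" for i in range(48)]
        cfg = PipelineConfig(
            lambda_grid=np.geomspace(0.5, 1e-3, 12), cv_folds=5, m_rounds=2
        )
        state = iterative_select(X, symbols, y, cfg, seed=2)
        sel = state.all_selected
        assert len(sel) == len(set(sel))  # disjoint across rounds
        assert {"SIG1", "SIG2"} <= set(sel)


class TestBagging:
    def _cohorts(self, rng, n_cohorts=2, n_genes=60, cases=12, ctrls=12):
        out = []
        for c in range(n_cohorts):
            diag = ["case"] * cases + ["control"] * ctrls
            m = rng.standard_normal((n_genes, cases + ctrls))
            m[0, :cases] += 1.5  # informative first gene
            out.append(
                make_dataset(
                    m, genes=[f"G{i:02d}" for i in range(n_genes)],
                    samples=[f"c{c}s{j}" for j in range(cases + ctrls)],
                    diagnosis=diag, name=f"cohort{c}",
                )
            )
        return out

    def test_single_bag_prediction_equals_model(self, rng, small_config):
        cohorts = self._cohorts(rng)
        genes = cohorts[0].gene_symbols
        ens = bagged_train(cohorts, genes, small_config, n_bags=1, seed=3)
        assert len(ens.models) == 1
        scores = predict_scores(ens, cohorts[0])
        m = ens.models[0]
        idx = cohorts[0].gene_index(m.genes)
        np.testing.assert_allclose(
            scores, m.linear_predictor(cohorts[0].matrix[idx].T)
        )

    def test_same_seed_reproduces_ensemble(self, rng, small_config):
        cohorts = self._cohorts(rng)
        genes = cohorts[0].gene_symbols
        e1 = bagged_train(cohorts, genes, small_config, n_bags=3, seed=11)
        e2 = bagged_train(cohorts, genes, small_config, n_bags=3, seed=11)
        assert e1.bag_indices == e2.bag_indices
        for m1, m2 in zip(e1.models, e2.models):
            assert m1.genes == m2.genes
            np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
            assert m1.intercept == m2.intercept

    def test_bag_sizes_two_thirds_stratified_per_cohort(self, rng, small_config):
        cohorts = self._cohorts(rng, cases=12, ctrls=15)
        genes = cohorts[0].gene_symbols
        ens = bagged_train(cohorts, genes, small_config, n_bags=2, seed=0)
        for bag in ens.bag_indices:
            for c in cohorts:
                in_bag = [q for q in bag if q.startswith(f"{c.name}:")]
                diag = c.metadata["diagnosis"]
                picked = diag.loc[[q.split(":", 1)[1] for q in in_bag]]
                assert (picked == "case").sum() == math.ceil(2 / 3 * 12)
                assert (picked == "control").sum() == math.ceil(2 / 3 * 15)

    def test_oob_scores_never_use_in_bag_samples(self, rng, small_config):
        cohorts = self._cohorts(rng)
        genes = cohorts[0].gene_symbols
        ens = bagged_train(cohorts, genes, small_config, n_bags=4, seed=2)
        for b in range(len(ens.models)):
            assert set(ens.oob_ids(b)).isdisjoint(ens.bag_indices[b])
        ids, scores, y = oob_scores(ens, cohorts)
        assert len(ids) == len(scores) == len(y)
        assert set(ids) <= set(ens.all_sample_ids)

    def test_serialization_roundtrip(self, rng, small_config):
        cohorts = self._cohorts(rng)
        ens = bagged_train(cohorts, cohorts[0].gene_symbols, small_config,
                           n_bags=2, seed=1)
        back = BaggedEnsemble.from_dict(ens.to_dict())
        np.testing.assert_allclose(
            predict_scores(back, cohorts[0]), predict_scores(ens, cohorts[0])
        )


class TestPredictScores:
    def _dataset(self, rng, genes):
        return make_dataset(rng.standard_normal((len(genes), 8)), genes=genes)

    def test_identical_models_equal_single_model(self, rng):
        genes = ["A", "B"]
        ds = self._dataset(rng, genes)
        m = ScadModel(genes=genes, coefficients=[0.5, -1.0], intercept=0.3, lam=0.1)
        ens = BaggedEnsemble(models=[m, m, m], bag_indices=[[], [], []],
                             all_sample_ids=[])
        np.testing.assert_allclose(
            predict_scores(ens, ds), m.linear_predictor(ds.matrix.T)
        )

    def test_zero_coefficients_give_constant_intercept(self, rng):
        genes = ["A"]
        ds = self._dataset(rng, genes)
        m = ScadModel(genes=genes, coefficients=[0.0], intercept=1.25, lam=1.0)
        ens = BaggedEnsemble(models=[m], bag_indices=[[]], all_sample_ids=[])
        np.testing.assert_allclose(predict_scores(ens, ds), 1.25)

    def test_opposite_models_cancel(self, rng):
        genes = ["A", "B"]
        ds = self._dataset(rng, genes)
        m1 = ScadModel(genes=genes, coefficients=[1.0, -2.0], intercept=0.0, lam=0.1)
        m2 = ScadModel(genes=genes, coefficients=[-1.0, 2.0], intercept=0.0, lam=0.1)
        ens = BaggedEnsemble(models=[m1, m2], bag_indices=[[], []],
                             all_sample_ids=[])
        np.testing.assert_allclose(predict_scores(ens, ds), 0.0, atol=1e-12)

    def test_missing_gene_errors_with_symbols(self, rng):
        ds = self._dataset(rng, ["A"])
        m = ScadModel(genes=["A", "MISSING1"], coefficients=[1.0, 1.0],
                      intercept=0.0, lam=0.1)
        ens = BaggedEnsemble(models=[m], bag_indices=[[]], all_sample_ids=[])
        with pytest.raises(XTissueError, match="MISSING1"):
            predict_scores(ens, ds)
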