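"""Constrained log-contrast outcome model: OLS, penalties, heredity."""

import numpy as np
import pytest
from scipy.optimize import minimize

from microdisparity import simulate
from microdisparity.logcontrast import (build_design, default_lambda_grid,
                                        fit_constrained_ols, fit_penalized,
                                        select_tuning, sparse_group_prox,
                                        zero_sum_basis)

from conftest import make_dataset


def _random_dataset(rng, n=60, J=4, K=1, sigma=0.5):
    M = rng.dirichlet(rng.uniform(0.5, 3, J), size=n)
    R = rng.permutation(np.repeat([1, 0], n // 2))
    X = rng.normal(size=(n, K))
    aM = rng.normal(size=J)
    aM -= aM.mean()
    aC = rng.normal(size=J)
    aC -= aC.mean()
    Y = (1.0 + 0.7 * R + X @ rng.normal(size=K) + np.log(M) @ aM
         + (np.log(M) @ aC) * R + sigma * rng.normal(size=n))
    return make_dataset(M, R, Y, X), aM, aC


class TestDesign:
    def test_column_count_and_constraints(self):
        rng = np.random.default_rng(0)
        ds, _, _ = _random_dataset(rng, n=10, J=3, K=1)
        d = build_design(ds)
        assert d.X_full.shape[1] == 1 + 1 + 1 + 3 + 3
        assert d.basis.shape == (3, 2)
        # basis is orthonormal and spans the zero-sum subspace
        np.testing.assert_allclose(d.basis.T @ d.basis, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(d.basis.sum(axis=0), 0.0, atol=1e-12)

    def test_all_comparison_group_zeroes_interaction_block(self):
        rng = np.random.default_rng(1)
        M = rng.dirichlet(np.ones(3), size=8)
        ds = make_dataset(M, np.zeros(8, dtype=int), rng.normal(size=8))
        d = build_design(ds)
        assert np.all(d.X_full[:, d.slices["interaction"]] == 0)

    def test_log_block_matches_elementwise_log(self):
        rng = np.random.default_rng(2)
        ds, _, _ = _random_dataset(rng, n=12, J=4, K=1)
        d = build_design(ds)
        np.testing.assert_allclose(d.X_full[:, d.slices["main"]],
                                   np.log(ds.composition.values))


class TestConstrainedOls:
    def test_j2_equals_log_ratio_ols(self):
        # with J=2 the zero-sum constraint makes aM' log M = aM1 log(M1/M2)
        rng = np.random.default_rng(3)
        n = 200
        M = rng.dirichlet([2.0, 3.0], size=n)
        R = np.repeat([1, 0], n // 2)
        Y = 0.5 + 0.4 * R + 0.8 * np.log(M[:, 0] / M[:, 1]) \
            + 0.3 * rng.normal(size=n)
        ds = make_dataset(M, R, Y)
        fit = fit_constrained_ols(ds)
        # independent oracle: plain OLS of Y on [1, R, log-ratio, R*log-ratio]
        lr = np.log(M[:, 0] / M[:, 1])
        D = np.column_stack([np.ones(n), R, lr, R * lr])
        beta = np.linalg.lstsq(D, Y, rcond=None)[0]
        assert fit.params.taxon_main[0] == pytest.approx(beta[2], abs=1e-8)
        assert fit.params.taxon_main[1] == pytest.approx(-beta[2], abs=1e-8)
        assert fit.params.exposure_coef == pytest.approx(beta[1], abs=1e-8)

    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(4)
        ds, aM, aC = _random_dataset(rng, n=80, J=5, K=2, sigma=0.0)
        fit = fit_constrained_ols(ds)
        np.testing.assert_allclose(fit.params.taxon_main, aM, atol=1e-8)
        np.testing.assert_allclose(fit.params.taxon_interaction, aC, atol=1e-8)

    def test_recovery_within_three_se(self):
        cfg = simulate.default_scenario(n_per_group=1000, n_taxa=6,
                                        n_covariates=1, n_mediators=2, seed=5)
        data = simulate.generate_dataset(cfg, seed=5)
        fit = fit_constrained_ols(data)
        cov = fit.covariance_full()
        K = 1
        se_aM = np.sqrt(np.diag(cov)[2 + K:2 + K + 6])
        assert np.all(np.abs(fit.params.taxon_main
                             - cfg.outcome_params.taxon_main) < 3.5 * se_aM)
        assert fit.params.exposure_coef == pytest.approx(
            cfg.outcome_params.exposure_coef,
            abs=3.5 * np.sqrt(cov[1 + K, 1 + K]))

    def test_zero_sum_constraints_hold(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            ds, _, _ = _random_dataset(rng)
            fit = fit_constrained_ols(ds)
            assert abs(fit.params.taxon_main.sum()) < 1e-8
            assert abs(fit.params.taxon_interaction.sum()) < 1e-8

    def test_prediction_scale_invariance(self):
        # multiplying a subject's raw abundances by a constant before
        # closure leaves log-contrast predictions unchanged
        rng = np.random.default_rng(7)
        ds, _, _ = _random_dataset(rng)
        fit = fit_constrained_ols(ds)
        pred = fit.params.predict(ds)
        scaled = ds.composition.values * rng.uniform(0.5, 2.0, size=(ds.n_subjects, 1))
        scaled /= scaled.sum(axis=1, keepdims=True)
        ds2 = make_dataset(scaled, ds.frame.exposure, ds.frame.outcome,
                           ds.frame.covariates)
        np.testing.assert_allclose(fit.params.predict(ds2), pred, atol=1e-10)


class TestSparseGroupProx:
    def test_matches_generic_solver(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            v = rng.normal(0, 2, size=2)
            lg, l1 = rng.uniform(0, 1.5, size=2)
            got = sparse_group_prox(v, lg, l1)

            def objective(z):
                return (0.5 * np.sum((z - v) ** 2)
                        + lg * np.linalg.norm(z) + l1 * abs(z[1]))

            best = min(
                (minimize(objective, x0, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12})
                 for x0 in ([0.0, 0.0], v, got)),
                key=lambda r: r.fun)
            assert objective(got) <= best.fun + 1e-8


class TestPenalized:
    def test_zero_penalty_limit_equals_ols(self):
        rng = np.random.default_rng(9)
        ds, _, _ = _random_dataset(rng)
        ols = fit_constrained_ols(ds)
        pen = fit_penalized(ds, 0.0, 0.0)
        np.testing.assert_allclose(pen.params.taxon_main,
                                   ols.params.taxon_main, atol=1e-6)
        np.testing.assert_allclose(pen.params.taxon_interaction,
                                   ols.params.taxon_interaction, atol=1e-6)

    def test_large_penalty_shrinks_everything(self):
        rng = np.random.default_rng(10)
        ds, _, _ = _random_dataset(rng)
        pen = fit_penalized(ds, 1e4, 1e4)
        assert pen.selected_taxa == []
        assert np.all(pen.params.taxon_main == 0)
        assert np.all(pen.params.taxon_interaction == 0)

    def test_heredity_and_zero_sum_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ds, _, _ = _random_dataset(rng, n=50, J=6, K=1)
            lg, l1 = rng.uniform(0.01, 0.5, size=2)
            pen = fit_penalized(ds, lambda_l1=l1, lambda_group=lg)
            aM, aC = pen.params.taxon_main, pen.params.taxon_interaction
            assert not np.any((aM == 0) & (aC != 0))  # heredity
            assert abs(aM.sum()) < 1e-8
            assert abs(aC.sum()) < 1e-8
            assert set(pen.selected_taxa) == {
                t for t, m, c in zip(ds.composition.taxon_ids, aM, aC)
                if m != 0 or c != 0}

    def test_sparse_truth_recovered_at_oracle_lambdas(self):
        # 3 of 20 taxa active; an oracle choice on a small grid should
        # recover the true support with few false positives
        hits = 0
        n_rep = 15
        grid = [(lg, lg / 10) for lg in np.geomspace(0.01, 0.5, 8)]
        for s in range(n_rep):
            cfg = simulate.default_scenario(n_per_group=250, n_taxa=20,
                                            n_covariates=1, n_mediators=3,
                                            seed=12)
            data = simulate.generate_dataset(cfg, seed=3000 + s)
            true_set = {f"taxon_{j:02d}" for j in range(3)}
            best = None
            for lg, l1 in grid:
                pen = fit_penalized(data, lambda_l1=l1, lambda_group=lg)
                sel = set(pen.selected_taxa)
                score = (len(true_set & sel), -len(sel - true_set))
                if best is None or score > best:
                    best = score
                    if score[0] == 3 and -score[1] <= 2:
                        break
            hits += best[0] == 3 and -best[1] <= 2
        assert hits >= int(0.8 * n_rep)


class TestSelectTuning:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(13)
        ds, _, _ = _random_dataset(rng)
        rep = select_tuning(ds, grid=[(0.05, 0.01)], criterion="bic")
        assert (rep.lambda_group, rep.lambda_l1) == (0.05, 0.01)

    def test_null_truth_selects_near_empty_model(self):
        # no taxon signal at all: BIC should pick an (almost) empty model
        near_empty = 0
        n_rep = 25
        for s in range(n_rep):
            cfg = simulate.null_scenario(n_per_group=60, n_taxa=8,
                                         alpha_m=0.0, seed=100 + s)
            data = simulate.generate_dataset(cfg)
            rep = select_tuning(data, criterion="bic")
            near_empty += rep.n_selected <= 1
        assert near_empty >= int(0.9 * n_rep)

    def test_bic_model_size_monotone_along_group_path(self):
        rng = np.random.default_rng(14)
        ds, _, _ = _random_dataset(rng, n=80, J=6, K=1)
        sizes = [fit_penalized(ds, 0.0, lg).n_selected
                 for lg in np.geomspace(1e-4, 10, 12)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_cv5_runs_and_is_seeded(self):
        rng = np.random.default_rng(15)
        ds, _, _ = _random_dataset(rng, n=60, J=4, K=1)
        grid = [(0.01, 0.0), (0.3, 0.05)]
        a = select_tuning(ds, grid=grid, criterion="cv5", seed=3)
        b = select_tuning(ds, grid=grid, criterion="cv5", seed=3)
        assert (a.lambda_group, a.lambda_l1) == (b.lambda_group, b.lambda_l1)


def test_zero_sum_basis_properties():
    for J in (2, 5, 9):
        U = zero_sum_basis(J)
        np.testing.assert_allclose(U.T @ U, np.eye(J - 1), atol=1e-12)
        np.testing.assert_allclose(U.sum(axis=0), 0.0, atol=1e-12)
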