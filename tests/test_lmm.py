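"""REML engine: designs, criterion, fitting, BLUPs, parameter counts."""

import numpy as np
import pytest
import statsmodels.api as sm

from floa.basis import BasisSystem, BSplineSpec, eval_basis
from floa.datasets import DifferenceCurves
from floa.grid import FrameGrid
from floa.lmm import (ErrorSpec, FLoAModel, ParamMap, RandomLevelSpec,
                      VarianceParams, blup, build_designs,
                      count_variance_parameters, fit_reml,
                      marginal_covariance, psi_parameter_subtotal,
                      reml_criterion, reml_value_and_grad)
from floa.synthetic import SimConfig, simulate_differences, truth_params

LEVELS = ("subject", "session", "replicate")


def _study_designs(seed=3, **kw):
    cfg = SimConfig(seed=seed, **kw)
    diffs, truth = simulate_differences(cfg)
    Z = truth["basis"]
    levels = [RandomLevelSpec(lv, Z, "diagonal") for lv in LEVELS]
    return cfg, diffs, truth, build_designs(diffs, Z, levels)


def _truth_varparams(truth, cfg):
    return VarianceParams(psi=truth["psi"], sigma2=truth["sigma2"],
                          phi=truth["phi"], theta=truth["theta"])


class TestBuildDesigns:
    def test_study_dimensions(self):
        _, _, _, d = _study_designs()
        assert len(d.subjects) == 9
        assert all(len(d.y[s]) == 2 * 3 * 101 for s in d.subjects)
        assert d.n_obs == 9 * 606 == 5454
        assert d.balanced and d.m_sessions == 2 and d.n_replicates == 3

    def test_random_effect_group_counts(self, study_fit):
        _, _, _, model = study_fit
        assert len(model.blups["subject"]) == 9
        assert len(model.blups["session"]) == 18
        assert len(model.blups["replicate"]) == 54

    def test_degenerate_single_subject_flagged(self):
        grid = FrameGrid(n_frames=5, t_min=0, t_max=4)
        ones = BasisSystem(np.ones((5, 1)), kind="bspline", grid=grid)
        dc = DifferenceCurves({("S1", "ses1", "rep1"): np.zeros(5)}, grid)
        levels = [RandomLevelSpec("subject", ones, "diagonal"),
                  RandomLevelSpec("session", ones, "diagonal")]
        with pytest.warns(UserWarning, match="unidentifiable"):
            d = build_designs(dc, ones, levels)
        assert d.flags

    def test_mismatched_grid_rejected(self):
        _, diffs, truth, _ = _study_designs()
        wrong = eval_basis(FrameGrid(n_frames=51, t_min=0, t_max=100),
                           BSplineSpec(3, 3, False))
        with pytest.raises(ValueError, match="grid"):
            build_designs(diffs, wrong, [])


class TestMarginalCovariance:
    def test_zero_random_effects_iid_gives_scaled_identity(self):
        _, _, truth, d = _study_designs()
        q = truth["basis"].n_basis
        params = VarianceParams(
            psi={lv: np.zeros((q, q)) for lv in LEVELS}, sigma2=2.0)
        V = marginal_covariance(params, d, d.subjects[0])
        np.testing.assert_allclose(V, 2.0 * np.eye(606), atol=1e-12)

    def test_subject_level_couples_all_curves_equally(self):
        _, _, truth, d = _study_designs()
        Z = truth["basis"].matrix
        q = Z.shape[1]
        psi1 = np.diag(np.random.default_rng(0).uniform(0.5, 2.0, q))
        params = VarianceParams(
            psi={"subject": psi1, "session": np.zeros((q, q)),
                 "replicate": np.zeros((q, q))}, sigma2=1.0)
        V = marginal_covariance(params, d, d.subjects[0])
        block = Z @ psi1 @ Z.T
        nf = 101
        for a in range(6):
            for b in range(6):
                expected = block + (1.0 * np.eye(nf) if a == b else 0.0)
                np.testing.assert_allclose(
                    V[a * nf:(a + 1) * nf, b * nf:(b + 1) * nf], expected,
                    atol=1e-10)

    def test_matches_monte_carlo_subject_blocks(self):
        # brute-force oracle: empirical covariance of simulated stacks
        from floa.arma import simulate_arma_noise
        cfg = SimConfig(n_frames=7, truth_n_inner_knots=1, n_sessions=2,
                        n_replicates=2, seed=9)
        truth = truth_params(cfg)
        Zm = truth["basis"].matrix
        q, nf, m, r = Zm.shape[1], 7, 2, 2
        rng = np.random.default_rng(1)
        n = 60_000
        sd = {lv: np.sqrt(np.diag(mm)) for lv, mm in truth["psi"].items()}
        us = rng.normal(size=(n, 1, 1, q)) * sd["subject"]
        uj = rng.normal(size=(n, m, 1, q)) * sd["session"]
        uk = rng.normal(size=(n, m, r, q)) * sd["replicate"]
        eps = simulate_arma_noise(truth["phi"], truth["theta"],
                                  truth["sigma2"], (n * m * r, nf),
                                  rng).reshape(n, m, r, nf)
        Y = (np.einsum("nmrq,fq->nmrf", us + uj + uk, Zm)
             + eps).reshape(n, m * r * nf)
        emp = np.cov(Y.T)

        diffs = {(f"S{i}", f"s{j}", f"r{k}"): np.zeros(nf)
                 for i in range(2) for j in range(m) for k in range(r)}
        d = build_designs(
            DifferenceCurves(diffs, cfg.grid), truth["basis"],
            [RandomLevelSpec(lv, truth["basis"], "diagonal")
             for lv in LEVELS])
        V = marginal_covariance(_truth_varparams(truth, cfg), d, "S0")
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V ** 2) / n)
        assert np.abs((emp - V) / se).max() < 5.0

    def test_psd_over_random_feasible_params(self):
        _, _, truth, d = _study_designs(n_frames=21, truth_n_inner_knots=1)
        levels = d.levels
        pmap = ParamMap(levels, ErrorSpec("arma", 2, 1))
        rng = np.random.default_rng(2)
        for _ in range(5):
            params = pmap.unpack(rng.normal(0, 1.0, pmap.n_params))
            V = marginal_covariance(params, d, d.subjects[0])
            np.linalg.cholesky(V + 1e-10 * np.eye(V.shape[0]))


class TestRemlCriterion:
    def test_matches_statsmodels_random_intercept(self, random_intercept_toy):
        dc, ones = random_intercept_toy
        Y = dc.to_matrix()
        n_groups, n_obs = Y.shape
        md = sm.MixedLM(Y.ravel(), np.ones((Y.size, 1)),
                        np.repeat(np.arange(n_groups), n_obs))
        fit = md.fit(reml=True)
        tau2 = float(np.asarray(fit.cov_re)[0, 0])
        params = VarianceParams(psi={"subject": np.array([[tau2]])},
                                sigma2=float(fit.scale))
        d = build_designs(dc, ones,
                          [RandomLevelSpec("subject", ones, "diagonal")])
        assert reml_criterion(params, d) == pytest.approx(fit.llf, abs=1e-6)

    def test_zero_random_effects_closed_form(self):
        rng = np.random.default_rng(4)
        grid = FrameGrid(n_frames=20, t_min=0, t_max=19)
        X = np.column_stack([np.ones(20), np.linspace(0, 1, 20)])
        basis = BasisSystem(X, kind="bspline", grid=grid)
        curves = {(f"S{i}", "s", "r"): X @ [1.0, 2.0]
                  + rng.normal(0, 1.0, 20) for i in range(6)}
        dc = DifferenceCurves(curves, grid)
        d = build_designs(dc, basis, [])
        sigma2 = 1.3
        params = VarianceParams(psi={}, sigma2=sigma2)
        got = reml_criterion(params, d)
        # closed form for V = sigma2 * I
        Y = np.concatenate([d.y[s] for s in d.subjects])
        Xs = np.tile(X, (6, 1))
        beta = np.linalg.lstsq(Xs, Y, rcond=None)[0]
        rss = float(np.sum((Y - Xs @ beta) ** 2))
        N, p = Y.size, 2
        expected = -0.5 * ((N - p) * np.log(sigma2)
                           + np.linalg.slogdet(Xs.T @ Xs)[1]
                           + rss / sigma2 + (N - p) * np.log(2 * np.pi))
        assert got == pytest.approx(expected, abs=1e-8)

    def test_balanced_and_dense_paths_agree(self):
        cfg, diffs, truth, d = _study_designs()
        params = _truth_varparams(truth, cfg)
        ll_fast = reml_criterion(params, d)
        d.balanced = False
        ll_dense = reml_criterion(params, d)
        assert ll_fast == pytest.approx(ll_dense, abs=1e-6)

    def test_shift_invariance_with_intercept_spanning_basis(self):
        rng = np.random.default_rng(5)
        grid = FrameGrid(n_frames=15, t_min=0, t_max=14)
        basis = eval_basis(grid, BSplineSpec(3, 1, True))  # spans constants
        curves = {(f"S{i}", "s", f"r{k}"): rng.normal(size=15)
                  for i in range(4) for k in range(2)}
        dc = DifferenceCurves(curves, grid)
        levels = [RandomLevelSpec("subject", basis, "diagonal")]
        d = build_designs(dc, basis, levels)
        q = basis.n_basis
        params = VarianceParams(psi={"subject": 0.5 * np.eye(q)}, sigma2=1.0)
        ll = reml_criterion(params, d)
        shifted = DifferenceCurves(
            {k: v + 7.0 for k, v in curves.items()}, grid)
        d2 = build_designs(shifted, basis, levels)
        assert reml_criterion(params, d2) == pytest.approx(ll, abs=1e-6)

    def test_rotation_invariance_diagonal_vs_unstructured(self):
        rng = np.random.default_rng(6)
        grid = FrameGrid(n_frames=9, t_min=0, t_max=8)
        Q = np.linalg.qr(rng.normal(size=(9, 2)))[0]
        R = np.linalg.qr(rng.normal(size=(2, 2)))[0]
        base = BasisSystem(Q, kind="eigen", grid=grid)
        rotated = BasisSystem(Q @ R, kind="eigen", grid=grid)
        curves = {(f"S{i}", "s", "r"): rng.normal(size=9) for i in range(5)}
        dc = DifferenceCurves(curves, grid)
        psi = np.diag([2.0, 0.7])
        pa = VarianceParams(psi={"subject": psi}, sigma2=0.4)
        pb = VarianceParams(psi={"subject": R.T @ psi @ R}, sigma2=0.4)
        da = build_designs(dc, base,
                           [RandomLevelSpec("subject", base, "diagonal")])
        db = build_designs(dc, base,
                           [RandomLevelSpec("subject", rotated,
                                            "unstructured")])
        assert reml_criterion(pa, da) == pytest.approx(
            reml_criterion(pb, db), abs=1e-8)

    def test_singular_covariance_returns_neg_inf(self):
        _, _, truth, d = _study_designs(n_frames=21, truth_n_inner_knots=1)
        q = truth["basis"].n_basis
        params = VarianceParams(
            psi={lv: np.zeros((q, q)) for lv in LEVELS}, sigma2=0.0)
        assert reml_criterion(params, d) == -np.inf


class TestAnalyticGradient:
    @pytest.mark.parametrize("cov", ["diagonal", "unstructured"])
    def test_matches_finite_differences(self, cov):
        cfg, diffs, truth, _ = _study_designs(n_frames=21,
                                              truth_n_inner_knots=1)
        Z = truth["basis"]
        levels = [RandomLevelSpec(lv, Z, cov) for lv in LEVELS]
        d = build_designs(diffs, Z, levels)
        pmap = ParamMap(levels, ErrorSpec("arma", 2, 1))
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, pmap.n_params)
        _, g = reml_value_and_grad(x, pmap, d)
        for i in rng.choice(pmap.n_params, 6, replace=False):
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (-reml_criterion(pmap.unpack(xp), d)
                  + reml_criterion(pmap.unpack(xm), d)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=2e-3, abs=1e-5)


class TestFitReml:
    def test_random_intercept_matches_anova_closed_form(
            self, random_intercept_toy):
        dc, ones = random_intercept_toy
        model = fit_reml(dc, ones,
                         [RandomLevelSpec("subject", ones, "diagonal")],
                         ErrorSpec("iid"), n_starts=1, ftol=1e-13,
                         gtol=1e-9)
        Y = dc.to_matrix()
        n_groups, n_obs = Y.shape
        gm = Y.mean(axis=1)
        msw = ((Y - gm[:, None]) ** 2).sum() / (n_groups * (n_obs - 1))
        msb = n_obs * ((gm - gm.mean()) ** 2).sum() / (n_groups - 1)
        assert model.params.sigma2 == pytest.approx(msw, rel=1e-6)
        assert model.params.psi["subject"][0, 0] == pytest.approx(
            (msb - msw) / n_obs, rel=1e-6)
        assert model.beta[0] == pytest.approx(Y.mean(), rel=1e-9)

    def test_profiled_beta_is_gls_solution(self, study_fit):
        _, _, _, model = study_fit
        d = model.fit_meta["designs"]
        X = d.X
        lhs = np.zeros((X.shape[1], X.shape[1]))
        rhs = np.zeros(X.shape[1])
        for s in d.subjects:
            V = marginal_covariance(model.params, d, s)
            Xs = np.tile(X, (len(d.curve_keys[s]), 1))
            Vi_X = np.linalg.solve(V, Xs)
            lhs += Xs.T @ Vi_X
            rhs += Vi_X.T @ d.y[s]
        np.testing.assert_allclose(lhs @ model.beta, rhs,
                                   rtol=1e-6, atol=1e-6)

    def test_deterministic_given_seed(self):
        cfg, diffs, truth, _ = _study_designs(n_frames=21,
                                              truth_n_inner_knots=1)
        Z = truth["basis"]
        levels = [RandomLevelSpec(lv, Z, "diagonal") for lv in LEVELS]
        m1 = fit_reml(diffs, Z, levels, ErrorSpec("iid"), n_starts=2, seed=7)
        m2 = fit_reml(diffs, Z, levels, ErrorSpec("iid"), n_starts=2, seed=7)
        assert m1.reml_loglik == m2.reml_loglik
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_zero_truth_level_shrinks_to_boundary(self):
        cfg = SimConfig(seed=8, psi_diag={"subject": 4.0, "session": 0.0,
                                          "replicate": 0.5})
        diffs, truth = simulate_differences(cfg)
        Z = truth["basis"]
        levels = [RandomLevelSpec(lv, Z, "diagonal") for lv in LEVELS]
        model = fit_reml(diffs, Z, levels, ErrorSpec("arma", 2, 1),
                         n_starts=1)
        sess_curve_var = float(np.mean(np.einsum(
            "fq,qr,fr->f", Z.matrix, model.params.psi["session"], Z.matrix)))
        assert sess_curve_var <= 0.05 * model.params.sigma2


class TestBlup:
    def test_vanishing_psi_shrinks_blups_to_zero(self):
        cfg, diffs, truth, d = _study_designs(n_frames=21,
                                              truth_n_inner_knots=1)
        q = truth["basis"].n_basis
        params = VarianceParams(
            psi={"subject": 1e-12 * np.eye(q), "session": np.eye(q),
                 "replicate": np.eye(q)},
            sigma2=truth["sigma2"], phi=truth["phi"], theta=truth["theta"])
        model = FLoAModel(beta=truth["beta"], params=params,
                          fixed_basis=truth["basis"], levels=d.levels,
                          error_spec=ErrorSpec("arma", 2, 1))
        b = blup(model, d)
        for v in b["subject"].values():
            assert np.abs(v).max() < 1e-9

    def test_noiseless_data_recovers_generating_coefficients(self):
        rng = np.random.default_rng(9)
        grid = FrameGrid(n_frames=31, t_min=0, t_max=30)
        Z = eval_basis(grid, BSplineSpec(3, 1, False))
        q = Z.n_basis
        beta = rng.normal(0, 3, q)
        u = {f"S{i}": rng.normal(0, 2, q) for i in range(6)}
        curves = {(s, "ses1", f"rep{k}"): Z.matrix @ (beta + u[s])
                  for s in u for k in (1, 2)}
        dc = DifferenceCurves(curves, grid)
        levels = [RandomLevelSpec("subject", Z, "diagonal")]
        d = build_designs(dc, Z, levels)
        params = VarianceParams(psi={"subject": 4.0 * np.eye(q)},
                                sigma2=1e-10)
        model = FLoAModel(beta=beta, params=params, fixed_basis=Z,
                          levels=levels, error_spec=ErrorSpec("iid"))
        b = blup(model, d)
        for s, coef in u.items():
            np.testing.assert_allclose(b["subject"][s], coef, atol=1e-4)

    def test_subject_blups_average_near_zero_on_balanced_data(
            self, study_fit):
        _, _, truth, model = study_fit
        curves = np.array([spec.basis.matrix @ v
                           for spec in model.levels
                           if spec.level == "subject"
                           for v in model.blups["subject"].values()])
        mean_curve = curves.mean(axis=0)
        subject_sd = np.sqrt(np.mean(curves ** 2))
        assert np.sqrt(np.mean(mean_curve ** 2)) < 0.5 * subject_sd


class TestParameterCounts:
    def test_unstructured_q12_needs_78(self):
        basis = eval_basis(FrameGrid(), BSplineSpec(3, 9, False))
        level = RandomLevelSpec("subject", basis, "unstructured")
        assert level.q == 12
        assert psi_parameter_subtotal([level]) == 78

    def test_three_unstructured_levels_need_234(self):
        basis = eval_basis(FrameGrid(), BSplineSpec(3, 9, False))
        levels = [RandomLevelSpec(lv, basis, "unstructured")
                  for lv in LEVELS]
        assert psi_parameter_subtotal(levels) == 234

    def test_diagonal_and_arma_totals(self):
        basis = eval_basis(FrameGrid(), BSplineSpec(3, 9, False))
        one = [RandomLevelSpec("subject", basis, "diagonal")]
        assert psi_parameter_subtotal(one) == 12
        three = [RandomLevelSpec(lv, basis, "diagonal") for lv in LEVELS]
        assert count_variance_parameters(
            three, ErrorSpec("arma", 2, 1)) == 36 + 1 + 3
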