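"""Tests for the group-LASSO / group-MCP path solver."""

import numpy as np
import pytest

from grpisis.design import GroupedDesign, Response
from grpisis.errors import DegenerateFitError, InputError
from grpisis.penalized import (
    PenaltySpec,
    fit_group_penalized,
    kkt_violation,
    lambda_max,
    select_by_information_criterion,
    solve_path,
)

from conftest import make_design


def _signal_response(rng, design, cols=(0,), betas=(1.0,), noise=0.2, cov_beta=0.4):
    y = np.zeros(design.n)
    for c, b in zip(cols, betas):
        y += b * design.matrix[:, c]
    if cov_beta and design.covariate_columns:
        y += cov_beta * design.matrix[:, design.covariate_columns[0]]
    if noise:
        y += rng.normal(0, noise, design.n)
    return Response(y)


@pytest.fixture
def strong_fixture(rng):
    design = make_design(rng, n=80, group_sizes=(4, 3, 5, 2))
    y = _signal_response(rng, design, cols=(0, 4), betas=(1.2, 0.8))
    return design, y


class TestLambdaMax:
    def test_all_blocks_zero_at_lambda_max(self, strong_fixture):
        design, y = strong_fixture
        spec = PenaltySpec()
        lm = lambda_max(design, y, spec)
        pt = fit_group_penalized(design, y, spec, lm)
        assert pt.active_groups == []
        pt = fit_group_penalized(design, y, spec, 1.01 * lm)
        assert pt.active_groups == []

    def test_strong_signal_active_below_lambda_max(self, strong_fixture):
        design, y = strong_fixture
        spec = PenaltySpec()
        lm = lambda_max(design, y, spec)
        pt = fit_group_penalized(design, y, spec, 0.5 * lm)
        assert len(pt.active_groups) >= 1

    def test_single_group_matches_hand_computation(self, rng):
        # 5 samples, one 2-SNP group, no covariates
        X = rng.binomial(2, 0.5, size=(5, 2)).astype(float)
        design = GroupedDesign(
            matrix=X, column_ids=["a", "b"], sample_ids=list("vwxyz"),
            group_of={0: "G", 1: "G"}, group_ids=["G"], covariate_columns=[],
        )
        y = Response(np.array([1.0, 3.0, 2.0, 5.0, 4.0]))
        spec = PenaltySpec()
        n = 5
        yc = y.values - y.values.mean()
        Xc = X - X.mean(axis=0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        Q = U[:, s > 1e-10] * np.sqrt(n)
        expected = np.linalg.norm(Q.T @ yc) / (n * np.sqrt(2))
        assert lambda_max(design, y, spec) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_response_rejected(self, small_design):
        with pytest.raises(DegenerateFitError):
            lambda_max(small_design, Response(np.ones(small_design.n)), PenaltySpec())


class TestFitGroupPenalized:
    def test_covariates_unpenalized_at_lambda_max(self, strong_fixture):
        design, y = strong_fixture
        spec = PenaltySpec()
        lm = lambda_max(design, y, spec)
        pt = fit_group_penalized(design, y, spec, lm)
        # with all blocks zero, covariate coefficients are their OLS values
        cov = design.covariate_columns
        A = np.column_stack([np.ones(design.n), design.matrix[:, cov]])
        theta = np.linalg.lstsq(A, y.values, rcond=None)[0]
        assert pt.coefficients[cov] == pytest.approx(theta[1:], rel=1e-6)

    def test_block_soft_threshold_closed_form(self, rng):
        """Single orthonormalized group: solver equals the closed form."""
        n = 40
        X = rng.normal(size=(n, 3))
        X = np.clip(X - X.min(), 0, 2)
        design = GroupedDesign(
            matrix=X, column_ids=["a", "b", "c"], sample_ids=[f"s{i}" for i in range(n)],
            group_of={0: "G", 1: "G", 2: "G"}, group_ids=["G"], covariate_columns=[],
        )
        y = Response(X[:, 0] - 0.5 * X[:, 2] + rng.normal(0, 0.3, n))
        spec = PenaltySpec()
        yc = y.values - y.values.mean()
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        Q = U * np.sqrt(n)
        z = Q.T @ yc / n
        w = np.sqrt(3)
        lam = 0.6 * np.linalg.norm(z) / w
        shrink = max(0.0, 1.0 - lam * w / np.linalg.norm(z))
        beta_expected = shrink * z
        pt = fit_group_penalized(design, y, spec, lam)
        assert np.allclose(pt.beta_std["G"], beta_expected, atol=1e-6)

    def test_kkt_conditions_on_random_fixtures(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            design = make_design(rng, n=60, group_sizes=(3, 4, 2, 5))
            y = _signal_response(rng, design, cols=(0, 7), betas=(1.0, 0.7), noise=0.4)
            spec = PenaltySpec()
            lm = lambda_max(design, y, spec)
            for frac in (0.8, 0.4, 0.1, 0.02):
                pt = fit_group_penalized(design, y, spec, frac * lm)
                assert kkt_violation(design, y, spec, pt) < 1e-5

    def test_rank_deficient_group_handled(self, rng):
        n = 40
        x = rng.binomial(2, 0.4, size=n).astype(float)
        X = np.column_stack([x, x, rng.binomial(2, 0.3, size=n).astype(float)])
        design = GroupedDesign(
            matrix=X, column_ids=["a", "a2", "b"], sample_ids=[f"s{i}" for i in range(n)],
            group_of={0: "G1", 1: "G1", 2: "G2"}, group_ids=["G1", "G2"],
            covariate_columns=[],
        )
        y = Response(x + rng.normal(0, 0.2, n))
        spec = PenaltySpec()
        pt = fit_group_penalized(design, y, spec, 0.05 * lambda_max(design, y, spec))
        assert "G1" in pt.active_groups
        # duplicated columns share the minimum-norm coefficient
        assert pt.coefficients[0] == pytest.approx(pt.coefficients[1], rel=1e-8)


class TestSolvePath:
    def test_first_point_empty_and_rss_monotone(self, strong_fixture):
        design, y = strong_fixture
        path = solve_path(design, y, PenaltySpec())
        assert path.points[0].active_groups == []
        rss = [pt.rss for pt in path.points]
        assert all(a >= b - 1e-8 for a, b in zip(rss, rss[1:]))

    def test_pure_noise_path_rarely_activates(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            design = make_design(rng, n=80, group_sizes=tuple([3] * 15))
            y = Response(rng.normal(size=80))
            path = solve_path(design, y, PenaltySpec())
            assert path.points[0].active_groups == []
            # just below lambda_max only a handful of noise groups activate
            assert len(path.points[3].active_groups) <= 5

    def test_mcp_large_gamma_limits_to_lasso(self, strong_fixture):
        design, y = strong_fixture
        lasso = solve_path(design, y, PenaltySpec(penalty="group-lasso"))
        grid = np.array([pt.lam for pt in lasso.points])
        mcp = solve_path(
            design, y,
            PenaltySpec(penalty="group-mcp", gamma=1e6, lambda_grid=grid),
        )
        for a, b in zip(lasso.points, mcp.points):
            assert np.allclose(a.coefficients, b.coefficients, atol=1e-4)

    def test_original_scale_coefficients_reproduce_fit(self, strong_fixture):
        design, y = strong_fixture
        path = solve_path(design, y, PenaltySpec())
        pt = path.points[50]
        fitted = design.matrix @ pt.coefficients + pt.intercept
        assert np.sum((y.values - fitted) ** 2) == pytest.approx(pt.rss, rel=1e-8)


class TestInformationCriterion:
    def test_single_point_path_returned(self, strong_fixture):
        design, y = strong_fixture
        spec = PenaltySpec(n_lambda=1)
        path = solve_path(design, y, spec)
        assert select_by_information_criterion(path, "BIC", design.n) is path.points[0]

    def test_bic_never_denser_than_aic(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            design = make_design(rng, n=70, group_sizes=(3, 4, 2, 5, 3))
            y = _signal_response(rng, design, cols=(0, 7), betas=(0.8, 0.5), noise=0.6)
            path = solve_path(design, y, PenaltySpec())
            a = select_by_information_criterion(path, "AIC", design.n)
            b = select_by_information_criterion(path, "BIC", design.n)
            assert b.df_est <= a.df_est

    def test_three_causal_genes_recovered_with_mcp_bic(self, rng):
        design = make_design(rng, n=100, group_sizes=(3, 3, 3, 3, 3, 3, 3, 3))
        y = _signal_response(rng, design, cols=(0, 3, 6), betas=(1.5, 1.2, 1.0),
                             noise=0.0)
        path = solve_path(design, y, PenaltySpec(penalty="group-mcp"))
        pt = select_by_information_criterion(path, "BIC", design.n)
        assert sorted(pt.active_groups) == ["G1", "G2", "G3"]

    def test_invalid_criterion_rejected(self, strong_fixture):
        design, y = strong_fixture
        path = solve_path(design, y, PenaltySpec(n_lambda=2))
        with pytest.raises(InputError):
            select_by_information_criterion(path, "DIC", design.n)


def test_group_lasso_objective_matches_proximal_gradient_oracle(rng):
    """Independent solver check: proximal gradient descent on the same
    objective (penalty on the groupwise-orthonormalized block norms) reaches
    the same optimum as block coordinate descent (2 groups, 20 samples)."""
    n = 20
    design = make_design(rng, n=n, group_sizes=(3, 2), n_cov=0)
    y = _signal_response(rng, design, cols=(0,), betas=(1.0,), noise=0.3, cov_beta=0.0)
    spec = PenaltySpec()
    lm = lambda_max(design, y, spec)
    lam = 0.3 * lm
    pt = fit_group_penalized(design, y, spec, lam)

    # reproduce the orthonormalized blocks independently
    yc = y.values - y.values.mean()
    blocks, ws = [], []
    for g in design.group_ids:
        Xg = design.matrix[:, design.groups[g]]
        Xg = Xg - Xg.mean(axis=0)
        U, s, _ = np.linalg.svd(Xg, full_matrices=False)
        blocks.append(U[:, s > 1e-10 * s[0]] * np.sqrt(n))
        ws.append(np.sqrt(len(design.groups[g])))
    Xstd = np.column_stack(blocks)
    slices = []
    start = 0
    for B in blocks:
        slices.append(slice(start, start + B.shape[1]))
        start += B.shape[1]

    L = np.linalg.norm(Xstd, 2) ** 2 / n
    beta = np.zeros(Xstd.shape[1])
    for _ in range(200_000):
        grad = -Xstd.T @ (yc - Xstd @ beta) / n
        b = beta - grad / L
        for sl, w in zip(slices, ws):
            nb = np.linalg.norm(b[sl])
            b[sl] = 0.0 if nb <= lam * w / L else (1 - lam * w / (L * nb)) * b[sl]
        if np.max(np.abs(b - beta)) < 1e-13:
            beta = b
            break
        beta = b

    def objective(bvec):
        pen = sum(lam * w * np.linalg.norm(bvec[sl]) for sl, w in zip(slices, ws))
        return np.sum((yc - Xstd @ bvec) ** 2) / (2 * n) + pen

    mine = np.concatenate([pt.beta_std[g] for g in design.group_ids])
    assert objective(mine) == pytest.approx(objective(beta), abs=1e-6)
    assert np.allclose(mine, beta, atol=1e-4)
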