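"""Spatial LME engine: GLS/REML oracles, t-test, adjusted r, pooled model."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from plaqueprog import (
    adjusted_r,
    exp_correlation_matrix,
    fit_pooled,
    fit_single,
    sample_spatial_gaussian,
    wald_t_test,
)
from plaqueprog.spatial_lme import (
    DegeneratePredictorError,
    DuplicateCoordinateError,
    LmeFitResult,
    phi_to_range,
    range_to_phi,
)


def dense_gls(coords, x, y, phi):
    """Brute-force GLS at fixed phi with explicitly inverted covariance."""
    R = exp_correlation_matrix(coords, phi)
    Rinv = np.linalg.inv(R)
    X = np.column_stack([np.ones(len(y)), x])
    return np.linalg.solve(X.T @ Rinv @ X, X.T @ Rinv @ y)


def dense_reml_loglik(coords, x, y, phi, sigma2, beta):
    """Non-profiled restricted log-likelihood with explicit inverses."""
    n, p = len(y), 2
    V = sigma2 * exp_correlation_matrix(coords, phi)
    Vinv = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    resid = y - X @ beta
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_m = np.linalg.slogdet(X.T @ Vinv @ X)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + logdet_v
        + logdet_m
        + resid @ Vinv @ resid
    )


class TestExpCorrelationMatrix:
    def test_single_node(self):
        assert np.array_equal(exp_correlation_matrix([[0, 0, 0]], 0.5), [[1.0]])

    def test_two_nodes_closed_form(self):
        R = exp_correlation_matrix([[0, 0, 0], [2, 0, 0]], 0.5)
        assert R[0, 1] == pytest.approx(0.25, abs=1e-15)
        assert R[0, 0] == R[1, 1] == 1.0

    def test_positive_definite_random_nodes(self, rng):
        coords = rng.uniform(0, 5, (20, 3))
        R = exp_correlation_matrix(coords, 0.9)
        assert np.linalg.eigvalsh(R).min() > 0
        assert np.allclose(R, R.T)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(DuplicateCoordinateError):
            exp_correlation_matrix([[0, 0, 0], [0, 0, 0]], 0.5)

    def test_phi_range_mapping_roundtrip(self):
        for phi in (0.1, 0.5, 0.9):
            assert range_to_phi(phi_to_range(phi)) == pytest.approx(phi, rel=1e-12)


class TestFitSingle:
    def test_noiseless_exact_interpolation(self, rng):
        coords = rng.uniform(0, 10, (30, 3))
        x = rng.normal(50, 10, 30)
        y = 2.0 + 0.5 * x
        fit = fit_single(coords, x, y)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-8)
        assert fit.beta1 == pytest.approx(0.5, abs=1e-8)

    def test_independence_limit_equals_ols(self, rng):
        coords = rng.uniform(0, 10, (40, 3))
        x = rng.normal(0, 1, 40)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.5, 40)
        X = np.column_stack([np.ones(40), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_single(coords, x, y, phi=0.0)
        assert fit.beta1 == pytest.approx(beta_ols[1], abs=1e-10)
        # with independent errors the estimated-phi fit lands near OLS as
        # well, limited by the flat likelihood in phi at this sample size
        fit_est = fit_single(coords * 50.0, x, y)
        assert fit_est.beta1 == pytest.approx(beta_ols[1], rel=0.05)

    def test_gls_matches_dense_inverse_oracle(self, rng):
        coords = rng.uniform(0, 6, (25, 3))
        x = rng.normal(0, 1, 25)
        y = 0.5 + 0.2 * x + sample_spatial_gaussian(coords, 0.6, 0.3, rng)
        fit = fit_single(coords, x, y, phi=0.6)
        beta = dense_gls(coords, x, y, 0.6)
        assert fit.beta0 == pytest.approx(beta[0], abs=1e-8)
        assert fit.beta1 == pytest.approx(beta[1], abs=1e-8)

    def test_reml_loglik_matches_dense_oracle(self, spatial_dataset):
        coords, x, y = spatial_dataset
        coords, x, y = coords[:40], x[:40], y[:40]
        fit = fit_single(coords, x, y)
        oracle = dense_reml_loglik(
            coords, x, y, fit.phi, fit.sigma2, np.array([fit.beta0, fit.beta1])
        )
        assert fit.reml_loglik == pytest.approx(oracle, abs=1e-8)

    def test_reml_optimum_dominates_phi_grid(self, rng):
        coords = rng.uniform(0, 8, (40, 3))
        x = rng.normal(0, 1, 40)
        y = 0.1 + 0.2 * x + sample_spatial_gaussian(coords, 0.7, 0.2, rng)
        fit = fit_single(coords, x, y)
        for phi in np.linspace(0.001, 0.999, 50):
            grid_fit = fit_single(coords, x, y, phi=phi)
            assert fit.reml_loglik >= grid_fit.reml_loglik - 1e-6

    def test_constant_predictor_rejected(self, rng):
        coords = rng.uniform(0, 10, (20, 3))
        with pytest.raises(DegeneratePredictorError):
            fit_single(coords, np.ones(20), rng.normal(0, 1, 20))

    def test_too_few_nodes_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            fit_single(rng.uniform(0, 5, (5, 3)), rng.normal(0, 1, 5),
                       rng.normal(0, 1, 5))


class TestFitPooled:
    def _blocks(self, rng, K=3, n=40, tau=0.1):
        parts = []
        for _ in range(K):
            c = rng.uniform(0, 10, (n, 3))
            x = rng.normal(0, 1, n)
            b = rng.normal(0, tau)
            y = 0.1 + 0.3 * x + b + sample_spatial_gaussian(c, 0.7, 0.1, rng)
            parts.append((c, x, y))
        return parts

    def test_single_patient_falls_back_to_single_model(self, rng):
        parts = self._blocks(rng, K=1, tau=0.0)
        with pytest.warns(UserWarning, match="single patient"):
            pooled = fit_pooled(parts)
        single = fit_single(*parts[0])
        assert pooled.beta1 == pytest.approx(single.beta1, abs=1e-6)
        assert pooled.p_value == pytest.approx(single.p_value, abs=1e-6)

    def test_patient_order_invariance(self, rng):
        parts = self._blocks(rng)
        a = fit_pooled(parts)
        b = fit_pooled(parts[::-1])
        # the restricted likelihood is symmetric in the blocks; agreement is
        # limited only by the optimizer's stopping tolerance
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-4)
        assert a.reml_loglik == pytest.approx(b.reml_loglik, abs=1e-5)
        assert a.tau2 == pytest.approx(b.tau2, rel=1e-2, abs=1e-6)

    def test_profiled_reml_matches_dense_block_oracle(self, rng):
        """Profiled block likelihood equals the explicit-inverse construction."""
        from plaqueprog.spatial_lme import _pooled_negloglik, _prepare_blocks

        parts = self._blocks(rng, K=2, n=15)
        blocks = _prepare_blocks(parts, "PWS")
        theta = np.log([0.3, 2.0, 5.0])  # gamma, rho_1, rho_2
        value, aux = _pooled_negloglik(theta, blocks)
        beta, q, M, n_total = aux

        # oracle: assemble the full block-diagonal W and invert it densely
        gamma = 0.3
        Ws = []
        for (c, x, y), rho in zip(parts, (2.0, 5.0)):
            from scipy.spatial.distance import pdist, squareform

            D = squareform(pdist(np.asarray(c)))
            Ws.append(np.exp(-D / rho) + gamma)
        from scipy.linalg import block_diag

        W = block_diag(*Ws)
        Winv = np.linalg.inv(W)
        X = np.vstack([np.column_stack([np.ones(len(y)), x]) for (c, x, y) in parts])
        Y = np.concatenate([y for (c, x, y) in parts])
        beta_o = np.linalg.solve(X.T @ Winv @ X, X.T @ Winv @ Y)
        resid = Y - X @ beta_o
        q_o = resid @ Winv @ resid
        n, p = len(Y), 2
        sigma2_o = q_o / (n - p)
        _, ld_w = np.linalg.slogdet(W)
        _, ld_m = np.linalg.slogdet(X.T @ Winv @ X)
        loglik_o = -0.5 * (
            (n - p) * (np.log(2 * np.pi) + np.log(sigma2_o) + 1) + ld_w + ld_m
        )
        assert beta == pytest.approx(beta_o, abs=1e-8)
        assert q == pytest.approx(q_o, rel=1e-8)
        assert -value == pytest.approx(loglik_o, abs=1e-8)

    def test_df_convention(self, rng):
        parts = self._blocks(rng, K=3, n=40)
        fit = fit_pooled(parts)
        assert fit.df == 120 - 3 - 1
        single = fit_single(*parts[0])
        assert single.df == 38


class TestWaldAndAdjustedR:
    def _stub(self, beta1, se, df):
        t = beta1 / se if se > 0 else float("nan")
        return LmeFitResult(
            beta0=0.0, beta1=beta1, se_beta1=se, t_stat=t,
            p_value=np.nan, sigma2=1.0, reml_loglik=0.0, n_obs=df + 2, df=df,
        )

    def test_zero_slope_p_one(self):
        assert wald_t_test(self._stub(0.0, 1.0, 100)) == 1.0

    def test_frozen_t_value(self):
        # |t| = 1.96 with 1000 df: two-sided p just above 0.05
        assert wald_t_test(self._stub(1.96, 1.0, 1000)) == pytest.approx(
            0.0503, abs=5e-4
        )

    def test_p_monotone_in_t(self):
        ps = [wald_t_test(self._stub(t, 1.0, 50)) for t in (0.5, 1.0, 2.0, 4.0)]
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_se_rejected(self):
        with pytest.raises(ValueError):
            wald_t_test(self._stub(1.0, 0.0, 10))

    def test_adjusted_r_slope_zero_and_identity(self, rng):
        x = rng.normal(0, 1, 50)
        assert adjusted_r(0.0, x, x + 1) == 0.0
        assert adjusted_r(1.0, x, x) == pytest.approx(1.0)

    def test_adjusted_r_equals_pearson_under_independence(self, rng):
        coords = rng.uniform(0, 10, (60, 3))
        x = rng.normal(0, 1, 60)
        y = 0.2 + 0.5 * x + rng.normal(0, 0.7, 60)
        fit = fit_single(coords, x, y, phi=0.0)
        pearson = np.corrcoef(x, y)[0, 1]
        assert fit.r_adj == pytest.approx(pearson, abs=1e-10)

    def test_sign_matches_slope(self, spatial_dataset):
        coords, x, y = spatial_dataset
        for response in (y, -y):
            fit = fit_single(coords, x, response)
            assert np.sign(fit.r_adj) == np.sign(fit.beta1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            adjusted_r(1.0, np.ones(10), np.arange(10.0))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_cross_check_against_nlme_gls(tmp_path, rng):
    """Independent mixed-model software agrees on beta1 within 1%.

    nlme::gls with corExp fits the same exponential-variogram GLS by REML;
    its range parameter is rho = -1/log(phi).
    """
    n = 80
    coords = rng.uniform(0, 12, (n, 3))
    x = rng.normal(50, 10, n)
    y = 0.1 + 0.004 * x + sample_spatial_gaussian(coords, 0.7, 0.04, rng)
    fit = fit_single(coords, x, y)

    csv = tmp_path / "d.csv"
    np.savetxt(
        csv,
        np.column_stack([y, x, coords]),
        delimiter=",",
        header="y,x,xc,yc,zc",
        comments="",
    )
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        library(nlme)
        d <- read.csv("{csv}")
        m <- gls(y ~ x, data = d,
                 correlation = corExp(form = ~ xc + yc + zc),
                 method = "REML")
        cat(sprintf("%.10g %.10g\\n", coef(m)[["x"]],
            coef(m$modelStruct$corStruct, unconstrained = FALSE)[["range"]]))
    """))
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)],
        capture_output=True, text=True, timeout=300,
    )
    assert out.returncode == 0, out.stderr
    beta1_r, range_r = map(float, out.stdout.split())
    assert fit.beta1 == pytest.approx(beta1_r, rel=0.01)
    assert phi_to_range(fit.phi) == pytest.approx(range_r, rel=0.05)
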