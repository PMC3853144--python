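"""REML fitting of spatial linear mixed-effects models for plaque progression.

Single-patient model (one scan pair):

    y_ij = beta0 + beta1 * x_ij + e_ij,

with y the wall thickness increase (WTI, mm) at node i of slice j and x
the baseline stress there.  The error vector is jointly Gaussian, mean
zero, with an exponential isotropic variogram: corr(e_a, e_b) = phi**s,
s the 3D Euclidean distance (mm) between the two nodes, phi in (0, 1).

Pooled per-period model across the K patients observed in a period:

    y_ijk = beta0 + beta1 * x_ijk + b_k + e_ijk,

with a Gaussian patient random intercept b_k ~ N(0, tau2) and a
patient-specific correlation parameter phi_k; patients are independent,
so the marginal covariance is block-diagonal with blocks

    V_k = sigma2 * R_k(phi_k) + tau2 * 1 1'.

Both models are fitted by restricted maximum likelihood (REML) with
beta and sigma2 profiled out; phi is optimised through the range
rho = -1/log(phi) on a log scale (R = exp(-D/rho)), which is far better
conditioned than phi itself near 0 or 1.  The slope is tested with a
Wald t-test (H0: beta1 = 0), and the dependence-adjusted correlation
coefficient

    r = beta1_hat * sqrt(var(x) / var(y))

plays the role of Pearson's r under spatial dependence (it reduces to
Pearson's r exactly when the errors are independent, because beta1_hat
is then the ordinary least-squares slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats
from scipy.spatial.distance import pdist, squareform

from plaqueprog.vessel_geometry import MatchedPairDataset, extract_regression_arrays

LOG_RHO_BOUNDS = (math.log(1e-3), math.log(1e4))  # range rho in mm
LOG_GAMMA_BOUNDS = (math.log(1e-8), math.log(1e3))  # gamma = tau2/sigma2
_GRID_POINTS = 13

ALPHA_DEFAULT = 0.05


class DegeneratePredictorError(ValueError):
    """The predictor is constant; the slope is unidentifiable."""


class DuplicateCoordinateError(ValueError):
    """Coincident node coordinates make the correlation matrix singular."""


@dataclass
class LmeFitResult:
    """One fitted spatial LME model.

    Units: beta0 in mm, beta1 in mm per predictor unit, sigma2/tau2 in
    mm^2; phi is the correlation at 1 mm distance.  ``phi_k`` is filled
    by the pooled fit (per-patient), ``phi`` by the single fit.
    """

    beta0: float
    beta1: float
    se_beta1: float
    t_stat: float
    p_value: float
    sigma2: float
    reml_loglik: float
    n_obs: int
    df: int
    r_adj: float = float("nan")
    phi: float | None = None
    phi_k: dict[str, float] | None = None
    tau2: float | None = None
    converged: bool = True
    model: str = "single"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "model", "beta0", "beta1", "se_beta1", "t_stat", "p_value",
            "sigma2", "tau2", "phi", "phi_k", "r_adj", "reml_loglik",
            "n_obs", "df", "converged",
        )}
        return d


def phi_to_range(phi: float) -> float:
    """Correlation-at-1mm -> exponential range rho = -1/log(phi), mm."""
    if not (0 < phi < 1):
        raise ValueError("phi must lie strictly between 0 and 1")
    return -1.0 / math.log(phi)


def range_to_phi(rho: float) -> float:
    return math.exp(-1.0 / rho)


def exp_correlation_matrix(coords: np.ndarray, phi: float) -> np.ndarray:
    """R_ij = phi**s_ij with s the Euclidean distance in mm.

    Symmetric with unit diagonal; positive definite for distinct points.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if not (0 < phi < 1):
        raise ValueError("phi must lie strictly between 0 and 1")
    dist = _distance_matrix(coords)
    return phi**dist


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords, float))
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    dist = squareform(pdist(coords))
    off = dist[np.triu_indices_from(dist, k=1)]
    if off.size and off.min() < 1e-9:
        raise DuplicateCoordinateError(
            "coincident node coordinates (distance < 1e-9 mm); "
            "deduplicate or apply a small jitter"
        )
    return dist


def _whiten(dist: np.ndarray, log_rho: float, X: np.ndarray, y: np.ndarray):
    """Cholesky-whiten X and y under R = exp(-D/rho); returns parts + logdet R."""
    if log_rho is None:  # independence limit: R = I
        return X, y, 0.0
    rho = math.exp(log_rho)
    R = np.exp(-dist / rho)
    try:
        L = linalg.cholesky(R, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise DuplicateCoordinateError(f"correlation matrix not PD: {exc}") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return Xw, yw, logdet


def _profile_beta(Xw: np.ndarray, yw: np.ndarray):
    """GLS beta, residual quadratic form and log|X' R^-1 X| from whitened parts."""
    M = Xw.T @ Xw
    v = Xw.T @ yw
    beta = np.linalg.solve(M, v)
    resid = yw - Xw @ beta
    q = float(resid @ resid)
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        raise DegeneratePredictorError("X' R^-1 X is singular")
    return beta, q, logdet_m, M


def _reml_value(n: int, p: int, q: float, logdet_r: float, logdet_m: float) -> float:
    """Restricted log-likelihood with sigma2 profiled at q/(n-p)."""
    sigma2 = q / (n - p)
    return -0.5 * (
        (n - p) * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
        + logdet_r
        + logdet_m
    )


def fit_single(
    coords: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    phi: float | None = None,
) -> LmeFitResult:
    """REML fit of the single-patient spatial model.

    ``phi=None`` estimates the correlation parameter; a fixed value in
    (0, 1) skips estimation, and ``phi=0.0`` fits with independent
    errors (ordinary least squares — the independence limit).
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 nodes, got {n}")
    if np.ptp(x) < 1e-12:
        raise DegeneratePredictorError("constant predictor: slope unidentifiable")
    dist = _distance_matrix(coords)
    X = np.column_stack([np.ones(n), x])
    p = 2

    def negloglik(log_rho: float) -> float:
        Xw, yw, logdet_r = _whiten(dist, log_rho, X, y)
        _, q, logdet_m, _ = _profile_beta(Xw, yw)
        return -_reml_value(n, p, q, logdet_r, logdet_m)

    converged = True
    if phi is None:
        log_rho, converged = _optimize_1d(negloglik)
        phi_hat = range_to_phi(math.exp(log_rho))
    elif phi == 0.0:
        log_rho = None
        phi_hat = 0.0
    else:
        log_rho = math.log(phi_to_range(phi))
        phi_hat = float(phi)

    Xw, yw, logdet_r = _whiten(dist, log_rho, X, y)
    beta, q, logdet_m, M = _profile_beta(Xw, yw)
    sigma2 = q / (n - p)
    cov_beta = sigma2 * np.linalg.inv(M)
    se1 = math.sqrt(cov_beta[1, 1])
    df = n - 2
    t_stat = beta[1] / se1
    p_value = 2.0 * stats.t.sf(abs(t_stat), df)
    loglik = _reml_value(n, p, q, logdet_r, logdet_m)

    fit = LmeFitResult(
        beta0=float(beta[0]), beta1=float(beta[1]), se_beta1=se1,
        t_stat=float(t_stat), p_value=float(p_value), sigma2=float(sigma2),
        reml_loglik=float(loglik), n_obs=n, df=df, phi=phi_hat,
        converged=converged, model="single",
    )
    fit.r_adj = adjusted_r(fit, x, y)
    return fit


def _optimize_1d(negloglik) -> tuple[float, bool]:
    """Deterministic coarse grid + bounded refinement over log rho."""
    lo, hi = LOG_RHO_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = [negloglik(g) for g in grid]
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(
        negloglik, bounds=(a, b), method="bounded",
        options={"xatol": 1e-6},
    )
    if res.success and res.fun <= vals[k]:
        return float(res.x), True
    return float(grid[k]), bool(res.success)


@dataclass
class _Block:
    """Whitening workspace for one patient's data block."""

    label: str
    dist: np.ndarray
    X: np.ndarray
    y: np.ndarray


def _prepare_blocks(datasets, predictor) -> list[_Block]:
    blocks = []
    for i, item in enumerate(datasets):
        if isinstance(item, MatchedPairDataset):
            arrays = extract_regression_arrays(item, predictor)
            if arrays.degenerate:
                raise DegeneratePredictorError(
                    f"constant predictor for patient {item.patient_id}"
                )
            label, (coords, x, y) = item.patient_id, arrays[:3]
        else:
            coords, x, y = item
            label = f"block{i}"
        coords = np.atleast_2d(np.asarray(coords, float))
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        X = np.column_stack([np.ones(len(y)), x])
        blocks.append(_Block(label=label, dist=_distance_matrix(coords), X=X, y=y))
    return blocks


def _pooled_negloglik(theta: np.ndarray, blocks: list[_Block]):
    """Negative restricted log-likelihood, sigma2 profiled out.

    theta = (log gamma, log rho_1 .. log rho_K) with gamma = tau2/sigma2;
    block covariance (up to sigma2): W_k = R_k(rho_k) + gamma * 1 1'.
    """
    gamma = math.exp(theta[0])
    n_total = sum(len(b.y) for b in blocks)
    p = 2
    M = np.zeros((p, p))
    v = np.zeros(p)
    yy = 0.0
    logdet_w = 0.0
    for k, b in enumerate(blocks):
        rho = math.exp(theta[1 + k])
        W = np.exp(-b.dist / rho) + gamma
        try:
            L = linalg.cholesky(W, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        Xw = linalg.solve_triangular(L, b.X, lower=True)
        yw = linalg.solve_triangular(L, b.y, lower=True)
        logdet_w += 2.0 * float(np.sum(np.log(np.diag(L))))
        M += Xw.T @ Xw
        v += Xw.T @ yw
        yy += float(yw @ yw)
    beta = np.linalg.solve(M, v)
    q = yy - float(v @ beta)
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0 or q <= 0:
        return np.inf, None
    value = -_reml_value(n_total, p, q, logdet_w, logdet_m)
    aux = (beta, q, M, n_total)
    return value, aux


def fit_pooled(
    datasets: Sequence,
    predictor: str = "PWS",
) -> LmeFitResult:
    """REML fit of the pooled per-period model over >= 2 patients.

    ``datasets`` is one entry per patient: a :class:`MatchedPairDataset`
    (with the named predictor painted) or a raw ``(coords, x, y)``
    triple.  A single entry falls back to :func:`fit_single`.
    """
    blocks = _prepare_blocks(datasets, predictor)
    if len(blocks) == 1:
        import warnings

        warnings.warn("single patient: falling back to the single-patient model")
        return _fit_single_from_block(blocks[0])
    K = len(blocks)

    def objective(theta):
        return _pooled_negloglik(theta, blocks)[0]

    starts = [
        np.concatenate([[math.log(0.1)], np.full(K, math.log(1.0))]),
        np.concatenate([[math.log(0.01)], np.full(K, math.log(10.0))]),
        np.concatenate([[math.log(1.0)], np.full(K, math.log(0.3))]),
    ]
    bounds = [LOG_GAMMA_BOUNDS] + [LOG_RHO_BOUNDS] * K
    best = None
    converged = False
    for s in starts:
        res = optimize.minimize(
            objective, s, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    theta = best.x
    value, aux = _pooled_negloglik(theta, blocks)
    beta, q, M, n_total = aux
    p = 2
    sigma2 = q / (n_total - p)
    gamma = math.exp(theta[0])
    tau2 = gamma * sigma2
    cov_beta = sigma2 * np.linalg.inv(M)
    se1 = math.sqrt(cov_beta[1, 1])
    df = n_total - K - 1
    t_stat = beta[1] / se1
    p_value = 2.0 * stats.t.sf(abs(t_stat), df)
    phi_k = {
        b.label: range_to_phi(math.exp(theta[1 + k])) for k, b in enumerate(blocks)
    }
    x_all = np.concatenate([b.X[:, 1] for b in blocks])
    y_all = np.concatenate([b.y for b in blocks])
    fit = LmeFitResult(
        beta0=float(beta[0]), beta1=float(beta[1]), se_beta1=se1,
        t_stat=float(t_stat), p_value=float(p_value), sigma2=float(sigma2),
        tau2=float(tau2), reml_loglik=float(-value), n_obs=n_total, df=df,
        phi_k=phi_k, converged=converged, model="pooled",
    )
    fit.r_adj = adjusted_r(fit, x_all, y_all)
    return fit


def _fit_single_from_block(b: _Block) -> LmeFitResult:
    n = len(b.y)
    p = 2

    def negloglik(log_rho):
        Xw, yw, logdet_r = _whiten(b.dist, log_rho, b.X, b.y)
        _, q, logdet_m, _ = _profile_beta(Xw, yw)
        return -_reml_value(n, p, q, logdet_r, logdet_m)

    log_rho, converged = _optimize_1d(negloglik)
    Xw, yw, logdet_r = _whiten(b.dist, log_rho, b.X, b.y)
    beta, q, logdet_m, M = _profile_beta(Xw, yw)
    sigma2 = q / (n - p)
    se1 = math.sqrt(sigma2 * np.linalg.inv(M)[1, 1])
    df = n - 2
    t_stat = beta[1] / se1
    fit = LmeFitResult(
        beta0=float(beta[0]), beta1=float(beta[1]), se_beta1=se1,
        t_stat=float(t_stat), p_value=float(2.0 * stats.t.sf(abs(t_stat), df)),
        sigma2=float(sigma2), reml_loglik=float(_reml_value(n, p, q, logdet_r, logdet_m)),
        n_obs=n, df=df, phi=range_to_phi(math.exp(log_rho)),
        converged=converged, model="single",
    )
    fit.r_adj = adjusted_r(fit, b.X[:, 1], b.y)
    return fit


def wald_t_test(fit: LmeFitResult) -> float:
    """Two-sided p-value for H0: beta1 = 0 from the fitted model."""
    if not (fit.se_beta1 > 0):
        raise ValueError("degenerate standard error")
    t = fit.beta1 / fit.se_beta1
    return float(2.0 * stats.t.sf(abs(t), fit.df))


def adjusted_r(fit: LmeFitResult | float, x: np.ndarray, y: np.ndarray) -> float:
    """Dependence-adjusted correlation r = beta1 * sqrt(var(x)/var(y)).

    Plain sample variances (ddof=1).  ``fit`` may be a fitted result or
    the slope itself.
    """
    beta1 = fit.beta1 if isinstance(fit, LmeFitResult) else float(fit)
    vx = float(np.var(np.asarray(x, float), ddof=1))
    vy = float(np.var(np.asarray(y, float), ddof=1))
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in x or y")
    return beta1 * math.sqrt(vx / vy)
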