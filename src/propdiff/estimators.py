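"""Four estimators of the average proportion difference in a two-sample design.

Implemented estimators, each returning a :class:`FitResult`:

``fit_linear``
    Ordinary least squares of the response on the binary group indicator.
``fit_beta_const``
    Maximum likelihood beta regression with a logit mean link and a single
    dispersion parameter on the identity scale.
``fit_beta_vardisp``
    Maximum likelihood beta regression with a logit mean link and a
    log-linked dispersion sub-model containing the group indicator.
``fit_fraclogit``
    Bernoulli quasi-likelihood with a logistic mean and robust
    (sandwich) covariance.

:func:`effect_from_fit` converts any converged fit into an estimate of
``delta = E(Y|x=1) - E(Y|x=0)`` with a delta-method standard error and a
Wald test at the fixed 1.96 critical value.

Because the design contains a single binary covariate, all likelihoods
reduce to per-group sufficient statistics; the optimizers below exploit
this, making each likelihood evaluation O(1) after one pass over the
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import digamma, expit, gammaln, logit

from .generators import TwoSampleData

__all__ = [
    "FitResult",
    "EffectEstimate",
    "fit_linear",
    "fit_beta_const",
    "fit_beta_vardisp",
    "fit_fraclogit",
    "effect_from_fit",
    "beta_const_loglik",
    "beta_vardisp_loglik",
]

MODEL_TAGS = ("linear", "beta_const", "beta_vardisp", "fraclogit")

#: fixed two-sided critical value used at alpha = 0.05
WALD_CRITICAL = 1.96

_PHI_MIN = 1e-6


@dataclass
class FitResult:
    """A fitted model: coefficients, covariance and diagnostics.

    ``coef`` ordering by ``model_tag``:

    * ``linear``:        (beta0, beta1, sigma2)
    * ``beta_const``:    (beta0, beta1, phi)
    * ``beta_vardisp``:  (beta0, beta1, gamma0, gamma1)
    * ``fraclogit``:     (beta0, beta1)
    """

    model_tag: str
    coef: np.ndarray
    cov: np.ndarray
    objective: float
    converged: bool
    n_iter: int = 0
    degenerate: bool = False
    message: str = ""


@dataclass
class EffectEstimate:
    """Average-difference estimate with Wald inference."""

    delta_hat: float
    se: float
    wald: float
    reject: bool


def _require_two_groups(data: TwoSampleData) -> None:
    if data.n0 == 0 or data.n1 == 0:
        raise ValueError("both groups must be non-empty")


# ---------------------------------------------------------------------------
# Linear regression (closed form)
# ---------------------------------------------------------------------------


def fit_linear(data: TwoSampleData) -> FitResult:
    """OLS of y on the group indicator.

    ``beta0`` is the group-0 sample mean and ``beta1`` the difference of
    group sample means.  The coefficient covariance is the usual OLS one
    with ``sigma2 = RSS / (n - 2)``.
    """
    _require_two_groups(data)
    y0, y1 = data.group(0), data.group(1)
    n0, n1 = y0.size, y1.size
    n = n0 + n1
    m0, m1 = y0.mean(), y1.mean()
    b0, b1 = m0, m1 - m0
    rss = float(np.sum((y0 - m0) ** 2) + np.sum((y1 - m1) ** 2))
    dof = n - 2
    sigma2 = rss / dof
    cov = np.zeros((3, 3))
    cov[0, 0] = sigma2 / n0
    cov[1, 1] = sigma2 * (1.0 / n0 + 1.0 / n1)
    cov[0, 1] = cov[1, 0] = -sigma2 / n0
    cov[2, 2] = 2.0 * sigma2**2 / dof
    sigma2_mle = rss / n
    if sigma2_mle > 0:
        objective = -0.5 * n * (math.log(2.0 * math.pi * sigma2_mle) + 1.0)
    else:
        objective = math.inf
    degenerate = rss == 0.0
    return FitResult(
        model_tag="linear",
        coef=np.array([b0, b1, sigma2]),
        cov=cov,
        objective=objective,
        converged=True,
        degenerate=degenerate,
        message="zero residual variance" if degenerate else "",
    )


# ---------------------------------------------------------------------------
# Beta regressions
# ---------------------------------------------------------------------------


@dataclass
class _GroupStats:
    """Per-group sufficient statistics for the beta likelihoods."""

    n: np.ndarray          # (2,) group sizes
    mean: np.ndarray       # (2,) sample means
    var: np.ndarray        # (2,) sample variances (ddof=1 where possible)
    slog: np.ndarray       # (2,) sum log y
    slog1m: np.ndarray     # (2,) sum log(1-y)
    mlogit: np.ndarray     # (2,) mean logit y


def _group_stats(data: TwoSampleData) -> _GroupStats:
    _require_two_groups(data)
    n = np.empty(2)
    mean = np.empty(2)
    var = np.empty(2)
    slog = np.empty(2)
    slog1m = np.empty(2)
    mlogit = np.empty(2)
    for g in (0, 1):
        y = data.group(g)
        n[g] = y.size
        mean[g] = y.mean()
        var[g] = y.var(ddof=1) if y.size > 1 else 0.0
        slog[g] = np.sum(np.log(y))
        slog1m[g] = np.sum(np.log1p(-y))
        mlogit[g] = np.mean(logit(y))
    return _GroupStats(n, mean, var, slog, slog1m, mlogit)


def _beta_ll_groups(mu: np.ndarray, phi: np.ndarray, st: _GroupStats) -> float:
    p = mu * phi
    q = (1.0 - mu) * phi
    terms = (
        st.n * (gammaln(phi) - gammaln(p) - gammaln(q))
        + (p - 1.0) * st.slog
        + (q - 1.0) * st.slog1m
    )
    return float(np.sum(terms))


def _beta_grad_groups(
    mu: np.ndarray, phi: np.ndarray, st: _GroupStats
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group derivatives of the log-likelihood wrt (eta_g, phi_g)."""
    p = mu * phi
    q = (1.0 - mu) * phi
    dmu = phi * (-st.n * digamma(p) + st.n * digamma(q) + st.slog - st.slog1m)
    deta = dmu * mu * (1.0 - mu)
    dphi = (
        st.n * digamma(phi)
        - st.n * mu * digamma(p)
        - st.n * (1.0 - mu) * digamma(q)
        + mu * st.slog
        + (1.0 - mu) * st.slog1m
    )
    return deta, dphi


def _const_theta_to_groups(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b0, b1, phi = theta
    mu = expit(np.array([b0, b0 + b1]))
    return mu, np.array([phi, phi])


def _vardisp_theta_to_groups(
    theta: np.ndarray, group_disp: bool
) -> tuple[np.ndarray, np.ndarray]:
    if group_disp:
        b0, b1, g0, g1 = theta
        zeta = np.array([g0, g0 + g1])
    else:
        b0, b1, g0 = theta
        zeta = np.array([g0, g0])
    mu = expit(np.array([b0, b0 + b1]))
    return mu, np.exp(zeta)


def beta_const_loglik(theta, data: TwoSampleData) -> float:
    """Log-likelihood of the constant-dispersion model at (b0, b1, phi)."""
    st = _group_stats(data)
    mu, phi = _const_theta_to_groups(np.asarray(theta, dtype=float))
    return _beta_ll_groups(mu, phi, st)


def beta_vardisp_loglik(theta, data: TwoSampleData, group_disp: bool = True) -> float:
    """Log-likelihood of the variable-dispersion model at (b0, b1, g0[, g1])."""
    st = _group_stats(data)
    mu, phi = _vardisp_theta_to_groups(np.asarray(theta, dtype=float), group_disp)
    return _beta_ll_groups(mu, phi, st)


def _nll_and_grad_const(theta: np.ndarray, st: _GroupStats):
    mu, phi = _const_theta_to_groups(theta)
    if phi[0] <= 0:
        return np.inf, np.zeros(3)
    ll = _beta_ll_groups(mu, phi, st)
    deta, dphi = _beta_grad_groups(mu, phi, st)
    grad = np.array([deta[0] + deta[1], deta[1], dphi[0] + dphi[1]])
    return -ll, -grad


def _nll_and_grad_vardisp(theta: np.ndarray, st: _GroupStats, group_disp: bool):
    mu, phi = _vardisp_theta_to_groups(theta, group_disp)
    if not np.all(np.isfinite(phi)):
        return np.inf, np.zeros(theta.size)
    ll = _beta_ll_groups(mu, phi, st)
    deta, dphi = _beta_grad_groups(mu, phi, st)
    dzeta = dphi * phi  # log link
    if group_disp:
        grad = np.array([deta[0] + deta[1], deta[1], dzeta[0] + dzeta[1], dzeta[1]])
    else:
        grad = np.array([deta[0] + deta[1], deta[1], dzeta[0] + dzeta[1]])
    return -ll, -grad


def _numerical_hessian(grad_fn, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    k = theta.size
    hess = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = grad_fn(tp)
        gm = grad_fn(tm)
        hess[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (hess + hess.T)


def _mom_phi(mean: float, var: float) -> float:
    if var <= 0:
        return 1.0
    return max(mean * (1.0 - mean) / var - 1.0, 0.01)


# deterministic jitter directions for optimizer restarts
_JITTERS = (
    np.array([0.2, -0.2, 0.5, -0.5]),
    np.array([-0.5, 0.5, -1.0, 1.0]),
    np.array([1.0, -1.0, 1.5, -1.5]),
)


def _maximize_beta(fun_grad, theta0: np.ndarray, bounds, max_restarts: int = 3):
    """L-BFGS-B plus Newton polish; returns (theta, nll, n_iter, ok)."""

    def grad_only(theta):
        return fun_grad(theta)[1]

    best = None
    for attempt in range(max_restarts + 1):
        start = theta0.copy()
        if attempt > 0:
            start = start + _JITTERS[attempt - 1][: start.size]
            if bounds is not None:  # keep phi inside its bound
                for j, (lo, hi) in enumerate(bounds):
                    if lo is not None:
                        start[j] = max(start[j], lo + 0.1)
        res = optimize.minimize(
            fun_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
        )
        theta = res.x
        nll, grad = fun_grad(theta)
        n_iter = int(res.nit)
        # Newton polish: drive the score to machine-level zero.  Near the
        # optimum the objective sits on a floating-point plateau, so steps
        # are accepted on a relative tolerance and judged by score norm.
        for _ in range(25):
            if np.max(np.abs(grad)) < 1e-9:
                break
            hess = _numerical_hessian(grad_only, theta)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            plateau = 1e-9 * max(1.0, abs(nll))
            scale = 1.0
            for _ in range(30):
                cand = theta - scale * step
                if bounds is not None:
                    ok_b = all(
                        (lo is None or c > lo) and (hi is None or c < hi)
                        for c, (lo, hi) in zip(cand, bounds)
                    )
                    if not ok_b:
                        scale *= 0.5
                        continue
                cand_nll, cand_grad = fun_grad(cand)
                if (
                    np.isfinite(cand_nll)
                    and cand_nll <= nll + plateau
                    and (
                        cand_nll < nll - plateau
                        or np.max(np.abs(cand_grad)) < np.max(np.abs(grad))
                    )
                ):
                    theta, nll, grad = cand, cand_nll, cand_grad
                    break
                scale *= 0.5
            else:
                break
            n_iter += 1
        # score tolerance scales with the objective's floating-point noise
        gtol = 1e-6 * max(1.0, abs(nll) / 1e3)
        ok = bool(np.max(np.abs(grad)) < gtol and np.isfinite(nll))
        cand = (nll, theta, n_iter, ok)
        if best is None or cand[0] < best[0] - 1e-10 or (ok and not best[3]):
            best = cand
        if ok:
            break
    nll, theta, n_iter, ok = best
    return theta, nll, n_iter, ok


def _finish_beta_fit(model_tag, theta, nll, n_iter, ok, grad_only, lower_bounded):
    hess = _numerical_hessian(grad_only, theta)
    degenerate = False
    try:
        cov = np.linalg.inv(hess)
        cov = 0.5 * (cov + cov.T)
        if np.any(np.diag(cov) <= 0):
            ok = False
    except np.linalg.LinAlgError:
        cov = np.full((theta.size, theta.size), np.nan)
        ok = False
    if lower_bounded is not None and theta[lower_bounded] < 10 * _PHI_MIN:
        degenerate = True
    return FitResult(
        model_tag=model_tag,
        coef=theta,
        cov=cov,
        objective=-nll,
        converged=ok,
        n_iter=n_iter,
        degenerate=degenerate,
        message="" if ok else "optimizer failed to reach a stationary point",
    )


def fit_beta_const(data: TwoSampleData, start=None) -> FitResult:
    """ML fit of the constant-dispersion beta regression (logit mean link).

    Coefficients are ``(beta0, beta1, phi)`` with ``phi`` on the identity
    scale (positivity enforced by a bound).  The covariance is the
    inverse observed information at the optimum.
    """
    st = _group_stats(data)
    if start is None:
        b0 = st.mlogit[0]
        b1 = st.mlogit[1] - st.mlogit[0]
        phi0 = _mom_phi(st.mean[0], st.var[0])
        phi1 = _mom_phi(st.mean[1], st.var[1])
        start = np.array([b0, b1, 0.5 * (phi0 + phi1)])
    theta0 = np.asarray(start, dtype=float)
    bounds = [(None, None), (None, None), (_PHI_MIN, None)]

    def fun_grad(theta):
        return _nll_and_grad_const(theta, st)

    theta, nll, n_iter, ok = _maximize_beta(fun_grad, theta0, bounds)
    return _finish_beta_fit(
        "beta_const", theta, nll, n_iter, ok, lambda t: fun_grad(t)[1], lower_bounded=2
    )


def fit_beta_vardisp(
    data: TwoSampleData, start=None, dispersion_covariate: bool = True
) -> FitResult:
    """ML fit of the variable-dispersion beta regression.

    Logit mean link; log dispersion link with linear predictor
    ``gamma0 + gamma1*x`` (set ``dispersion_covariate=False`` for an
    intercept-only dispersion sub-model, which reproduces
    :func:`fit_beta_const` under reparameterization).
    """
    st = _group_stats(data)
    if start is None:
        b0 = st.mlogit[0]
        b1 = st.mlogit[1] - st.mlogit[0]
        phi0 = _mom_phi(st.mean[0], st.var[0])
        phi1 = _mom_phi(st.mean[1], st.var[1])
        if dispersion_covariate:
            start = np.array([b0, b1, np.log(phi0), np.log(phi1) - np.log(phi0)])
        else:
            start = np.array([b0, b1, 0.5 * (np.log(phi0) + np.log(phi1))])
    theta0 = np.asarray(start, dtype=float)

    def fun_grad(theta):
        return _nll_and_grad_vardisp(theta, st, dispersion_covariate)

    theta, nll, n_iter, ok = _maximize_beta(fun_grad, theta0, bounds=None)
    return _finish_beta_fit(
        "beta_vardisp", theta, nll, n_iter, ok, lambda t: fun_grad(t)[1], lower_bounded=None
    )


# ---------------------------------------------------------------------------
# Fractional logit
# ---------------------------------------------------------------------------


def fit_fraclogit(data: TwoSampleData) -> FitResult:
    """Bernoulli quasi-likelihood fit with a logistic mean.

    In the saturated two-sample design the quasi-score equations force
    the fitted group means to equal the sample means, so the maximizer
    is available in closed form.  The covariance is the robust sandwich
    ``A^{-1} M A^{-1}`` with ``A`` the expected (model-based) Hessian of
    the quasi-likelihood and ``M`` the outer product of the
    per-observation scores.
    """
    _require_two_groups(data)
    y0, y1 = data.group(0), data.group(1)
    n0, n1 = y0.size, y1.size
    m0, m1 = y0.mean(), y1.mean()
    b0 = float(logit(m0))
    b1 = float(logit(m1)) - b0
    # A = sum mu(1-mu) x x';  M = sum (y-mu)^2 x x'  (x = (1, group))
    w0 = n0 * m0 * (1.0 - m0)
    w1 = n1 * m1 * (1.0 - m1)
    a_mat = np.array([[w0 + w1, w1], [w1, w1]])
    s0 = float(np.sum((y0 - m0) ** 2))
    s1 = float(np.sum((y1 - m1) ** 2))
    m_mat = np.array([[s0 + s1, s1], [s1, s1]])
    a_inv = np.linalg.inv(a_mat)
    cov = a_inv @ m_mat @ a_inv
    objective = float(
        np.sum(y0 * math.log(m0) + (1.0 - y0) * math.log1p(-m0))
        + np.sum(y1 * math.log(m1) + (1.0 - y1) * math.log1p(-m1))
    )
    return FitResult(
        model_tag="fraclogit",
        coef=np.array([b0, b1]),
        cov=cov,
        objective=objective,
        converged=True,
    )


# ---------------------------------------------------------------------------
# Effect estimation (delta method)
# ---------------------------------------------------------------------------


def effect_from_fit(fit: FitResult, alpha: float = 0.05) -> EffectEstimate:
    """Average-difference estimate and Wald test from a converged fit.

    Linear model: ``delta = beta1`` with its OLS standard error.  Models
    with a logit mean link: ``delta = expit(b0+b1) - expit(b0)`` with a
    delta-method standard error.  Rejection uses ``|W| > 1.96`` at
    ``alpha = 0.05`` (the normal quantile for other levels).
    """
    if not fit.converged:
        raise ValueError("cannot compute inference from a non-converged fit")
    if alpha == 0.05:
        crit = WALD_CRITICAL
    else:
        from scipy.stats import norm

        crit = float(norm.ppf(1.0 - alpha / 2.0))
    if fit.model_tag == "linear":
        delta = float(fit.coef[1])
        var = float(fit.cov[1, 1])
    elif fit.model_tag in ("beta_const", "beta_vardisp", "fraclogit"):
        b0, b1 = fit.coef[0], fit.coef[1]
        mu0, mu1 = expit(b0), expit(b0 + b1)
        delta = float(mu1 - mu0)
        grad = np.zeros(fit.coef.size)
        grad[0] = mu1 * (1.0 - mu1) - mu0 * (1.0 - mu0)
        grad[1] = mu1 * (1.0 - mu1)
        var = float(grad @ fit.cov @ grad)
    else:
        raise ValueError(f"unknown model tag: {fit.model_tag!r}")
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        wald = math.inf if delta != 0.0 else 0.0
    else:
        wald = delta / se
    return EffectEstimate(delta_hat=delta, se=se, wald=wald, reject=bool(abs(wald) > crit))
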