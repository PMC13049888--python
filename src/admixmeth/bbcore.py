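"""Shared statistical kernels for count-based methylation modeling.

Everything downstream (ancestry scans, species contrasts, meQTL mapping)
rests on three primitives implemented here:

* a beta-binomial likelihood for methylated/total read counts,
  parameterized by mean ``mu`` and intraclass correlation ``phi`` so that
  ``phi = 0`` is exactly the binomial;
* a maximum-likelihood beta-binomial regression with logit link and a
  single per-site dispersion (a fixed-effects stand-in for the
  mixed-effects count models used in population epigenomics, with global
  ancestry and any caller-supplied covariates absorbing structure);
* empirical-null false discovery rate estimation that calibrates observed
  p-values against a pool of permutation p-values rather than against the
  theoretical uniform.

The beta-binomial mixing distribution is Beta(mu*(1-phi)/phi,
(1-mu)*(1-phi)/phi): a read-level success probability with mean ``mu``
and variance ``phi*mu*(1-mu)``, giving count variance
``n*mu*(1-mu)*(1 + (n-1)*phi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .exceptions import ConvergenceError, DataError, FitError, ParameterError

__all__ = [
    "BetaBinomFit",
    "EmpiricalNull",
    "betabinom_loglik",
    "fit_betabinom_glm",
    "lrt",
    "empirical_qvalues",
    "estimate_pi0",
]

# logit-scale mean is clipped to keep mu in an open interval
_ETA_CLIP = 30.0
_MU_EPS = 1e-12
# log-dispersion s = (1-phi)/phi is optimized on t = log(s) within these
# bounds; the upper bound is numerically indistinguishable from binomial
_T_BOUNDS = (-2.2, 25.0)


# ---------------------------------------------------------------------------
# likelihood kernel


def _bb_logpmf(k, n, mu, s):
    """Beta-binomial log-pmf with mean mu and precision s = (1-phi)/phi."""
    a = mu * s
    b = (1.0 - mu) * s
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.gammaln(k + a)
        + special.gammaln(n - k + b)
        - special.gammaln(n + s)
        - special.gammaln(a)
        - special.gammaln(b)
        + special.gammaln(s)
    )


def _binom_logpmf(k, n, mu):
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * np.log(mu)
        + (n - k) * np.log1p(-mu)
    )


def betabinom_loglik(meth, total, mu, phi):
    """Log-probability of ``meth`` methylated reads out of ``total``.

    Parameters
    ----------
    meth, total : int or array
        Methylated and total read counts, ``0 <= meth <= total``.
    mu : float
        Mean methylation probability, in (0, 1).
    phi : float
        Intraclass correlation (dispersion) in [0, 1). ``phi = 0`` is the
        exact binomial limit.

    Returns
    -------
    float or ndarray
        ``log P(meth | total, mu, phi)``; 0.0 when ``total`` is 0.
    """
    meth = np.asarray(meth)
    total = np.asarray(total)
    if np.any(meth < 0) or np.any(meth > total):
        raise DataError("require 0 <= meth <= total")
    mu = float(mu)
    phi = float(phi)
    if not (0.0 < mu < 1.0):
        raise ParameterError(f"mu must be in (0, 1), got {mu}")
    if not (0.0 <= phi < 1.0) or not np.isfinite(phi):
        raise ParameterError(f"phi must be in [0, 1), got {phi}")
    if phi == 0.0:
        out = _binom_logpmf(meth, total, mu)
    else:
        out = _bb_logpmf(meth, total, mu, (1.0 - phi) / phi)
    out = np.where(total == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# beta-binomial GLM


@dataclass
class BetaBinomFit:
    """Result of a beta-binomial regression on the logit scale.

    ``coefficients`` are logit-scale effect sizes aligned with the design
    matrix columns; ``pvalues`` are per-coefficient Wald tests.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    pvalues: np.ndarray
    phi: float
    log_likelihood: float
    converged: bool
    n_used: int
    design_columns: list = field(default_factory=list)

    def predict_mean(self, X):
        """Model-predicted mean methylation for design rows ``X``."""
        eta = np.clip(np.asarray(X, float) @ self.coefficients, -_ETA_CLIP, _ETA_CLIP)
        return special.expit(eta)


def _glm_nll_grad(params, X, k, n):
    """Negative log-likelihood and gradient over (beta, t=log s)."""
    beta = params[:-1]
    s = np.exp(params[-1])
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.clip(special.expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    a = mu * s
    b = (1.0 - mu) * s
    ll = np.sum(_bb_logpmf(k, n, mu, s))
    psi_ka = special.digamma(k + a)
    psi_a = special.digamma(a)
    psi_nkb = special.digamma(n - k + b)
    psi_b = special.digamma(b)
    dl_dmu = s * (psi_ka - psi_a - psi_nkb + psi_b)
    grad_beta = X.T @ (dl_dmu * mu * (1.0 - mu))
    dl_ds = np.sum(
        mu * (psi_ka - psi_a)
        + (1.0 - mu) * (psi_nkb - psi_b)
        - special.digamma(n + s)
        + special.digamma(s)
    )
    grad = np.concatenate([grad_beta, [dl_ds * s]])
    return -ll, -grad


def _binom_irls(X, k, n, max_iter=50, tol=1e-10):
    """Binomial logistic fit of meth/total by Newton-Raphson."""
    p = X.shape[1]
    beta = np.zeros(p)
    pooled = np.clip(k.sum() / max(n.sum(), 1), 1e-3, 1 - 1e-3)
    # start intercept-like columns at the pooled logit
    beta[0] = special.logit(pooled) if np.allclose(X[:, 0], 1.0) else 0.0
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.clip(special.expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        W = n * mu * (1.0 - mu)
        score = X.T @ (k - n * mu)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(p), score)
        except np.linalg.LinAlgError:
            break
        # halve the step until the likelihood does not decrease
        for _ in range(20):
            cand = beta + step
            eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.clip(special.expit(eta_c), _MU_EPS, 1.0 - _MU_EPS)
            ll = np.sum(k * np.log(mu_c) + (n - k) * np.log1p(-mu_c))
            if ll >= ll_old - 1e-12 or np.linalg.norm(step) < 1e-14:
                break
            step *= 0.5
        beta = cand
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.clip(special.expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    ll = np.sum(_binom_logpmf(k, n, mu))
    return beta, ll, mu


def fit_betabinom_glm(meth, total, design, design_columns=None):
    """Maximum-likelihood beta-binomial regression with logit link.

    Parameters
    ----------
    meth, total : array of int, shape (n_obs,)
        Methylated and total read counts per individual.
    design : array, shape (n_obs, n_coef)
        Design matrix; must include an intercept column and be full rank
        over the rows with nonzero total.
    design_columns : list of str, optional
        Column labels carried through to the fit object.

    Returns
    -------
    BetaBinomFit
        Coefficients (logit scale), Wald standard errors and p-values, a
        single per-site dispersion ``phi``, and an honest ``converged``
        flag (False on separation or optimizer failure).
    """
    meth = np.asarray(meth, float)
    total = np.asarray(total, float)
    X = np.asarray(design, float)
    if meth.shape != total.shape or meth.shape[0] != X.shape[0]:
        raise DataError("meth, total and design rows must align")
    if np.any(meth < 0) or np.any(meth > total):
        raise DataError("require 0 <= meth <= total")
    keep = total > 0
    if not np.any(keep):
        raise DataError("all totals are zero")
    k, n, Xr = meth[keep], total[keep], X[keep]
    n_used, p = Xr.shape
    if np.linalg.matrix_rank(Xr) < p:
        raise FitError("design matrix is rank-deficient on observed rows")
    if n_used <= p:
        raise FitError(f"only {n_used} observations for {p} coefficients")

    beta0, ll_binom, mu0 = _binom_irls(Xr, k, n)

    # method-of-moments start for the dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.sum((k - n * mu0) ** 2 / (n * mu0 * (1.0 - mu0)))
    overdisp = chi2 / max(n_used - p, 1)
    nbar = float(np.mean(n))
    phi0 = np.clip((overdisp - 1.0) / max(nbar - 1.0, 1.0), 1e-4, 0.5)
    t0 = np.clip(np.log((1.0 - phi0) / phi0), *_T_BOUNDS)

    bounds = [(None, None)] * p + [_T_BOUNDS]
    # the moment start can stall near the binomial boundary; a second start
    # at moderate dispersion guards nestedness of profile likelihoods
    t_starts = [t0] if abs(t0 - 5.0) < 1.0 else [t0, 5.0]
    res = None
    for t_start in t_starts:
        cand = optimize.minimize(
            _glm_nll_grad, np.concatenate([beta0, [t_start]]), args=(Xr, k, n),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    ll_bb = -res.fun
    use_binomial = not np.isfinite(ll_bb) or (ll_binom >= ll_bb - 1e-7)

    if use_binomial:
        beta, ll, phi = beta0, ll_binom, 0.0
        eta = np.clip(Xr @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.clip(special.expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        W = n * mu * (1.0 - mu)
        info = (Xr * W[:, None]).T @ Xr
        score = Xr.T @ (k - n * mu)
        ok = _stationary(info, score)
    else:
        beta = res.x[:-1]
        s = np.exp(res.x[-1])
        phi = 1.0 / (1.0 + s)
        if phi < 1e-9:
            phi = 0.0
        ll = ll_bb
        info_full = _numerical_information(res.x, Xr, k, n)
        info = info_full[:p, :p]
        # judge convergence by the size of the Newton step for beta (the
        # dispersion may legitimately sit on its boundary), not by the
        # optimizer's status flag
        _, grad = _glm_nll_grad(res.x, Xr, k, n)
        ok = _stationary(info, -grad[:p])
    se, pd_ok = _wald_se(info)
    separated = bool(np.max(np.abs(beta)) > 15.0)
    converged = bool(ok and pd_ok and not separated and np.all(np.isfinite(se)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return BetaBinomFit(
        coefficients=beta,
        standard_errors=se,
        pvalues=pvals,
        phi=float(phi),
        log_likelihood=float(ll),
        converged=converged,
        n_used=int(n_used),
        design_columns=list(design_columns) if design_columns is not None else [],
    )


def _numerical_information(params, X, k, n, eps=1e-5):
    """Observed information by finite differences of the analytic gradient."""
    m = len(params)
    H = np.zeros((m, m))
    for j in range(m):
        step = np.zeros(m)
        step[j] = eps * max(1.0, abs(params[j]))
        _, gp = _glm_nll_grad(params + step, X, k, n)
        _, gm = _glm_nll_grad(params - step, X, k, n)
        H[:, j] = (gp - gm) / (2.0 * step[j])
    return 0.5 * (H + H.T)


def _stationary(info, score, tol=1e-3):
    """Scale-invariant stationarity: the Newton step is negligibly small."""
    try:
        step = np.linalg.solve(info + 1e-12 * np.eye(info.shape[0]), score)
    except np.linalg.LinAlgError:
        return False
    return bool(np.all(np.isfinite(step)) and np.max(np.abs(step)) < tol)


def _wald_se(info):
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return np.full(info.shape[0], np.nan), False
        return np.sqrt(diag), True
    except np.linalg.LinAlgError:
        return np.full(info.shape[0], np.nan), False


def lrt(fit_null, fit_alt, df):
    """Likelihood-ratio p-value for nested beta-binomial fits.

    ``2 * (ll_alt - ll_null)`` is referred to a chi-square with ``df``
    degrees of freedom; the statistic is floored at 0.
    """
    if df < 1:
        raise ParameterError("df must be >= 1")
    ll0 = fit_null if np.isscalar(fit_null) else fit_null.log_likelihood
    ll1 = fit_alt if np.isscalar(fit_alt) else fit_alt.log_likelihood
    stat = 2.0 * (ll1 - ll0)
    if stat < -1e-4 * (1.0 + abs(ll0)) - 1e-6:
        raise ConvergenceError(
            f"alternative log-likelihood {ll1:.6g} below null {ll0:.6g}; "
            "refit before testing"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# empirical-null FDR


@dataclass
class EmpiricalNull:
    """Pooled permutation p-values used as the null reference."""

    p_permuted: np.ndarray
    n_permutations: int
    pi0: float = 1.0


def estimate_pi0(p_observed, lam=0.5):
    """Single-lambda estimate of the null fraction, capped at 1."""
    p = np.asarray(p_observed, float)
    if p.size == 0:
        raise ParameterError("no observed p-values")
    return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))


def empirical_qvalues(p_observed, p_permuted, n_permutations, lam=0.5, pi0=None):
    """q-values calibrated against a permutation-derived null.

    For a threshold ``t``, the estimated FDR is
    ``pi0 * (#{p_perm <= t} / n_permutations) / max(1, #{p_obs <= t})``:
    the permutation pool provides the expected number of null discoveries
    per permutation. The q-value of site ``i`` is the minimum FDR over
    thresholds ``t >= p_i``, which enforces monotonicity in ``p``.

    Parameters
    ----------
    p_observed : array
        Observed p-values, one per tested unit.
    p_permuted : array
        P-values pooled across all permutations.
    n_permutations : int
        Number of permutations contributing to the pool.
    pi0 : float, optional
        Override the single-lambda null-fraction estimate (e.g. 1.0 for
        a deliberately conservative analysis of a signal-enriched set).
    """
    p_obs = np.asarray(p_observed, float)
    p_perm = np.asarray(p_permuted, float)
    # fractional values arise when failed permutation fits are dropped and
    # the caller passes the realized per-test permutation count
    if n_permutations <= 0:
        raise ParameterError("n_permutations must be positive")
    if p_perm.size == 0:
        raise ParameterError("empty permutation pool")
    if p_obs.size == 0:
        return np.array([])
    if pi0 is None:
        pi0 = estimate_pi0(p_obs, lam=lam)
    order = np.argsort(p_obs, kind="mergesort")
    p_sorted = p_obs[order]
    perm_sorted = np.sort(p_perm)
    # thresholds are the observed p-values themselves
    n_le_obs = np.searchsorted(p_sorted, p_sorted, side="right")
    n_le_perm = np.searchsorted(perm_sorted, p_sorted, side="right")
    fdr = pi0 * (n_le_perm / n_permutations) / np.maximum(1, n_le_obs)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
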