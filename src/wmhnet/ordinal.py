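"""Maximum-likelihood proportional-odds (cumulative-logit) regression.

Model: P(Y <= j | x) = expit(theta_j - x.beta) with strictly increasing
cutpoints theta. A positive slope therefore means higher odds of a higher
grade. Cutpoints are parameterized as theta_1 = a_1,
theta_j = theta_{j-1} + softplus(a_j), optimized by quasi-Newton with an
analytic gradient; the covariance is the inverse observed information at
the optimum (numerical Hessian in the natural parameterization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "PropOddsFit",
    "EffectEstimate",
    "SeparationError",
    "ConvergenceError",
    "fit_proportional_odds",
    "extract_effect",
    "pseudo_r2",
]

_SEPARATION_LIMIT = 25.0


class SeparationError(RuntimeError):
    """The likelihood is unbounded along a slope direction (perfect separation)."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to converge within budget."""


@dataclass
class PropOddsFit:
    """Fitted proportional-odds model."""

    cutpoints: np.ndarray          # (K-1,) increasing
    beta: np.ndarray               # (p,) slopes
    beta_names: list[str]
    cov: np.ndarray                # covariance of (cutpoints, beta)
    loglik: float
    n: int
    levels: np.ndarray             # observed outcome levels, ascending
    converged: bool

    @property
    def n_params(self) -> int:
        return self.cutpoints.size + self.beta.size

    def beta_se(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.cov))
        return d[self.cutpoints.size:]

    def coef(self, term: str) -> tuple[float, float]:
        """(estimate, standard error) for a named slope."""
        if term not in self.beta_names:
            raise KeyError(f"term {term!r} not in fit ({self.beta_names})")
        i = self.beta_names.index(term)
        return float(self.beta[i]), float(self.beta_se()[i])


def _encode_outcome(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(np.asarray(y), return_inverse=True)
    return levels, codes


def _nll_natural(theta: np.ndarray, beta: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 K: int) -> float:
    eta = X @ beta
    up = np.where(codes < K - 1, theta[np.minimum(codes, K - 2)] - eta, np.inf)
    lo = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta, -np.inf)
    # P = expit(up) - expit(lo), computed stably
    p = special.expit(up) - special.expit(lo)
    p = np.clip(p, 1e-300, None)
    return -np.log(p).sum()


def _nll_grad_raw(raw: np.ndarray, X: np.ndarray, codes: np.ndarray, K: int):
    """Negative log-likelihood and gradient in the softplus parameterization."""
    p_dim = X.shape[1]
    a = raw[: K - 1]
    beta = raw[K - 1:]
    inc = np.concatenate([[a[0]], np.logaddexp(0.0, a[1:])])  # softplus
    theta = np.cumsum(inc)

    eta = X @ beta
    ju = np.minimum(codes, K - 2)
    jl = np.maximum(codes - 1, 0)
    has_up = codes < K - 1
    has_lo = codes > 0
    zu = np.where(has_up, theta[ju] - eta, np.inf)
    zl = np.where(has_lo, theta[jl] - eta, -np.inf)
    Fu = special.expit(zu)
    Fl = special.expit(zl)
    prob = np.clip(Fu - Fl, 1e-300, None)
    nll = -np.log(prob).sum()

    fu = np.where(has_up, Fu * (1.0 - Fu), 0.0)
    fl = np.where(has_lo, Fl * (1.0 - Fl), 0.0)
    # d nll / d theta_j: -(1/p) * (fu at j==ju) + (1/p) * (fl at j==jl)
    w_up = fu / prob
    w_lo = fl / prob
    g_theta = np.zeros(K - 1)
    np.add.at(g_theta, ju[has_up], -w_up[has_up])
    np.add.at(g_theta, jl[has_lo], w_lo[has_lo])
    # d nll / d beta = sum_i (fu - fl)/p * x_i
    g_beta = X.T @ ((fu - fl) / prob)

    # chain rule to raw cutpoint parameters
    tail = np.cumsum(g_theta[::-1])[::-1]  # tail[m] = sum_{j>=m} g_theta[j]
    g_a = np.empty(K - 1)
    g_a[0] = tail[0]
    if K > 2:
        g_a[1:] = special.expit(a[1:]) * tail[1:]
    return nll, np.concatenate([g_a, g_beta]), theta


def _newton_polish(raw: np.ndarray, X: np.ndarray, codes: np.ndarray, K: int,
                   gtol: float = 1e-10, max_iter: int = 25) -> np.ndarray:
    """Damped Newton refinement of the quasi-Newton solution."""
    raw = raw.copy()
    nll, grad, _ = _nll_grad_raw(raw, X, codes, K)
    for _ in range(max_iter):
        if np.abs(grad).max() < gtol:
            break
        hess = approx_hess1(raw, lambda r: _nll_grad_raw(r, X, codes, K)[0])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            trial = raw - scale * step
            t_nll, t_grad, _ = _nll_grad_raw(trial, X, codes, K)
            if t_nll <= nll + 1e-12:
                raw, nll, grad = trial, t_nll, t_grad
                break
            scale *= 0.5
        else:
            break
    return raw


def fit_proportional_odds(
    y: np.ndarray,
    X: np.ndarray,
    beta_names: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PropOddsFit:
    """Fit a cumulative-logit model by maximum likelihood.

    Parameters
    ----------
    y
        Ordinal outcome (any numeric coding); levels with zero observed
        counts are collapsed away with a warning.
    X
        n x p design matrix of slope columns (no intercept column; the
        cutpoints absorb location).

    Raises
    ------
    SeparationError
        if a slope diverges (|beta| > 25), indicating perfect separation.
    ConvergenceError
        on optimizer failure.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X disagree in length")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    levels, codes = _encode_outcome(y)
    K = levels.size
    if K < 2:
        raise ValueError("outcome must have >= 2 observed levels")
    full_span = int(np.ptp(levels)) + 1 if np.issubdtype(levels.dtype, np.integer) else K
    if full_span > K:
        warnings.warn(
            f"{full_span - K} outcome levels unobserved; grades collapsed",
            stacklevel=2,
        )
    n, p = X.shape
    if beta_names is None:
        beta_names = [f"x{i}" for i in range(p)]
    if len(beta_names) != p:
        raise ValueError("beta_names length does not match design columns")

    # init: intercept-only quantile cutpoints, zero slopes
    cum = np.cumsum(np.bincount(codes, minlength=K))[:-1] / n
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    theta0 = special.logit(cum)
    inc0 = np.diff(theta0, prepend=theta0[0])
    a0 = np.empty(K - 1)
    a0[0] = theta0[0]
    if K > 2:
        # inverse softplus of increments (floored away from 0)
        a0[1:] = np.log(np.expm1(np.clip(inc0[1:], 1e-6, None)))
    raw0 = np.concatenate([a0, np.zeros(p)])

    res = optimize.minimize(
        lambda r: _nll_grad_raw(r, X, codes, K)[:2],
        raw0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9, "maxcor": 25},
    )
    raw = _newton_polish(res.x, X, codes, K)
    nll, _, theta = _nll_grad_raw(raw, X, codes, K)
    beta = raw[K - 1:]
    if np.abs(beta).max(initial=0.0) > _SEPARATION_LIMIT:
        raise SeparationError(
            f"slope magnitude {np.abs(beta).max():.1f} exceeds {_SEPARATION_LIMIT}; "
            "likely perfect separation"
        )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise ConvergenceError(f"optimizer failed: {res.message}")
    if not res.success:
        raise ConvergenceError("optimizer hit iteration budget without converging")

    natural = np.concatenate([theta, beta])
    hess = approx_hess1(
        natural,
        lambda q: _nll_natural(q[: K - 1], q[K - 1:], X, codes, K),
    )
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return PropOddsFit(
        cutpoints=theta,
        beta=beta,
        beta_names=list(beta_names),
        cov=cov,
        loglik=-nll,
        n=n,
        levels=levels,
        converged=bool(res.success),
    )


@dataclass
class EffectEstimate:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    log_or: float
    se: float


def extract_effect(fit: PropOddsFit, term: str, ci_method: str = "wald",
                   alpha: float = 0.05) -> EffectEstimate:
    """Odds ratio, confidence interval and two-sided Wald p for one slope.

    ``ci_method='wald'`` uses exp(b +/- z * SE); ``'profile'`` inverts the
    likelihood-ratio statistic.
    """
    b, se = fit.coef(term)
    z = stats.norm.ppf(1 - alpha / 2)
    if se > 0:
        p = 2 * stats.norm.sf(abs(b) / se)
    else:
        p = 0.0 if b != 0 else 1.0
    if ci_method == "wald":
        lo, hi = b - z * se, b + z * se
    elif ci_method == "profile":
        lo, hi = _profile_ci(fit, term, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return EffectEstimate(
        or_estimate=float(np.exp(b)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=float(p),
        log_or=float(b),
        se=float(se),
    )


def profile_loglik(y: np.ndarray, X: np.ndarray, col: int, value: float,
                   beta_names: list[str]) -> float:
    """Maximized log-likelihood with slope ``col`` fixed at ``value``."""
    offset_col = X[:, col] * value
    rest = np.delete(X, col, axis=1)
    levels, codes = _encode_outcome(y)
    K = levels.size
    # refit with the slope held fixed: its contribution becomes an offset and
    # only the remaining slopes and cutpoints are optimized
    n, p = rest.shape

    def nll_raw(raw):
        a = raw[: K - 1]
        beta = raw[K - 1:]
        inc = np.concatenate([[a[0]], np.logaddexp(0.0, a[1:])])
        theta = np.cumsum(inc)
        eta = (rest @ beta if p else 0.0) + offset_col
        ju = np.minimum(codes, K - 2)
        jl = np.maximum(codes - 1, 0)
        zu = np.where(codes < K - 1, theta[ju] - eta, np.inf)
        zl = np.where(codes > 0, theta[jl] - eta, -np.inf)
        prob = np.clip(special.expit(zu) - special.expit(zl), 1e-300, None)
        return -np.log(prob).sum()

    cum = np.clip(np.cumsum(np.bincount(codes, minlength=K))[:-1] / n, 1e-6, 1 - 1e-6)
    theta0 = special.logit(cum)
    a0 = np.empty(K - 1)
    a0[0] = theta0[0]
    if K > 2:
        a0[1:] = np.log(np.expm1(np.clip(np.diff(theta0), 1e-6, None)))
    raw0 = np.concatenate([a0, np.zeros(p)])
    res = optimize.minimize(nll_raw, raw0, method="Nelder-Mead" if K - 1 + p <= 3
                            else "BFGS", options={"maxiter": 2000})
    return -res.fun


def _profile_ci(fit: PropOddsFit, term: str, alpha: float) -> tuple[float, float]:
    # requires the data to be re-attachable; stored on the fit by the caller
    data = getattr(fit, "_data", None)
    if data is None:
        raise ValueError("profile CI requires the fit to retain its data "
                         "(use fit_proportional_odds then attach _data)")
    y, X = data
    col = fit.beta_names.index(term)
    b, se = fit.coef(term)
    crit = stats.chi2.ppf(1 - alpha, df=1) / 2.0

    def dev(value):
        return (fit.loglik - profile_loglik(y, X, col, value, fit.beta_names)) - crit

    span = max(4 * se, 1.0)
    lo = _bracket_root(dev, b, b - span, going_down=True)
    hi = _bracket_root(dev, b, b + span, going_down=False)
    return lo, hi


def _bracket_root(f, start: float, guess: float, going_down: bool) -> float:
    a, b = start, guess
    fb = f(b)
    tries = 0
    while fb < 0 and tries < 20:
        b = b + (b - a)
        fb = f(b)
        tries += 1
    if fb < 0:
        return -np.inf if going_down else np.inf
    return optimize.brentq(f, min(a, b), max(a, b), xtol=1e-4)


def pseudo_r2(fit: PropOddsFit, null_fit: PropOddsFit, kind: str = "nagelkerke") -> float:
    """Likelihood-based R^2 of ``fit`` relative to an intercept-only fit.

    Nagelkerke (default) rescales Cox-Snell to [0, 1]; McFadden is
    1 - ll/ll0. The null fit must be nested in ``fit``.
    """
    ll, ll0, n = fit.loglik, null_fit.loglik, fit.n
    if fit.n != null_fit.n:
        raise ValueError("fits do not share an outcome (different n)")
    if ll0 > ll + 1e-8:
        raise ValueError("null log-likelihood exceeds full fit; nesting violated")
    ll = max(ll, ll0)  # clip tiny numerical inversions
    if kind == "mcfadden":
        return float(1.0 - ll / ll0) if ll0 != 0 else 0.0
    if kind == "nagelkerke":
        cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        denom = 1.0 - np.exp(2.0 * ll0 / n)
        return float(cox_snell / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown pseudo-R^2 kind {kind!r}")
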