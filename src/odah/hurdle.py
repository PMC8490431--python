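"""Poisson-Logit hurdle model: likelihoods, analytic derivatives, MLE.

The hurdle model is a two-part model for zero-inflated counts.  A Bernoulli
process with logit link decides whether an observation clears the hurdle
(``w_i = 1(y_i > 0)``, ``logit(pi_i) = X_i' beta``); positive counts then
follow a zero-truncated Poisson (ZTP) with log link
(``log(lambda_i) = Z_i' gamma``).  The joint log-likelihood separates as
``L(beta, gamma) = L1(beta) + L2(gamma)`` with a block-diagonal Hessian, so
the two coefficient vectors are information orthogonal and are estimated by
two independent Newton-Raphson maximizations with analytic derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datasets import HurdleDataset, add_intercept

__all__ = [
    "HurdleParams",
    "FitResult",
    "hurdle_logpmf",
    "logistic_loglik",
    "logistic_gradient",
    "logistic_hessian",
    "ztp_loglik",
    "ztp_gradient",
    "ztp_hessian",
    "fit_hurdle",
    "HurdleRegressor",
]


@dataclass
class HurdleParams:
    """Coefficient pair: ``beta`` (log-odds), ``gamma`` (log-rate)."""

    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.gamma = np.asarray(self.gamma, dtype=float).ravel()
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.gamma))):
            raise ValueError("coefficients must be finite")


@dataclass
class FitResult:
    """Maximum-likelihood fit of a single-site hurdle model."""

    params: HurdleParams
    beta_var: np.ndarray
    gamma_var: np.ndarray
    loglik_logistic: float
    loglik_ztp: float
    converged: bool
    n_iter: int
    converged_logistic: bool = True
    converged_ztp: bool = True
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Probability mass function


def hurdle_logpmf(y: int, pi: float, lam: float) -> float:
    """Log of the hurdle PMF: ``P(Y=0) = 1 - pi``; for y >= 1,
    ``P(Y=y) = pi * exp(-lam) lam^y / ((1 - exp(-lam)) y!)``.
    """
    if y < 0 or int(y) != y:
        raise ValueError("y must be a non-negative integer")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if y == 0:
        return float(np.log1p(-pi)) if pi < 1 else -np.inf
    if lam <= 0:
        raise ValueError("lam must be positive for y >= 1")
    if pi == 0:
        return -np.inf
    # log of the ZTP mass: -lam + y log lam - log(1 - e^{-lam}) - log y!
    log_ztp = -lam + y * np.log(lam) - np.log(-np.expm1(-lam)) - gammaln(y + 1)
    return float(np.log(pi) + log_ztp)


# ---------------------------------------------------------------------------
# Logistic component (zero vs. positive)


def _check_beta(beta: np.ndarray, data: HurdleDataset) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.p:
        raise ValueError(
            f"beta has length {beta.shape[0]}, X has {data.p} columns"
        )
    return beta


def logistic_loglik(beta: np.ndarray, data: HurdleDataset) -> float:
    """Bernoulli log-likelihood of the hurdle indicator under the logit link.

    ``sum_i [w_i X_i'beta - log(1 + exp(X_i'beta))]``, stable for large
    linear predictors via log-sum-exp.
    """
    beta = _check_beta(beta, data)
    eta = data.X @ beta
    return float(np.sum(data.w * eta - np.logaddexp(0.0, eta)))


def logistic_gradient(beta: np.ndarray, data: HurdleDataset) -> np.ndarray:
    """Score of the logistic component: ``X'(w - expit(X beta))``."""
    beta = _check_beta(beta, data)
    resid = data.w - expit(data.X @ beta)
    return data.X.T @ resid


def logistic_hessian(beta: np.ndarray, data: HurdleDataset) -> np.ndarray:
    """Hessian of the logistic component: ``-X' diag(p(1-p)) X``."""
    beta = _check_beta(beta, data)
    prob = expit(data.X @ beta)
    weight = prob * (1.0 - prob)
    return -(data.X * weight[:, None]).T @ data.X


# ---------------------------------------------------------------------------
# Zero-truncated Poisson component (magnitude given positive)


def _check_gamma(gamma: np.ndarray, data: HurdleDataset) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float).ravel()
    if gamma.shape[0] != data.q:
        raise ValueError(
            f"gamma has length {gamma.shape[0]}, Z has {data.q} columns"
        )
    if data.n_pos == 0:
        raise ValueError("no positive counts; zero-truncated component undefined")
    return gamma


def _trunc_correction(lam: np.ndarray) -> np.ndarray:
    """``lam * e^{-lam} / (1 - e^{-lam})``, stable over the full range.

    Written as ``lam e^{-lam} / (-expm1(-lam))`` so no catastrophic
    cancellation occurs as lam -> 0 (limit 1) or lam -> inf (limit 0).
    """
    lam = np.asarray(lam, dtype=float)
    return lam * np.exp(-lam) / (-np.expm1(-lam))


def _trunc_info(lam: np.ndarray) -> np.ndarray:
    """Per-observation ZTP information factor ``lam * (1 + t'(lam))`` with
    ``t(lam) = lam e^{-lam}/(1 - e^{-lam})``.

    For small lam the exact expression suffers 0/0 cancellation, so a
    second-order series ``lam (1/2 + lam/6)`` is used below 1e-4.
    """
    lam = np.asarray(lam, dtype=float)
    small = lam < 1e-4
    safe = np.where(small, 1.0, lam)
    s = -np.expm1(-safe)
    t = safe * np.exp(-safe) / s
    # t'(lam) = t * (1/lam - 1/s)
    exact = safe * (1.0 + t * (1.0 / safe - 1.0 / s))
    series = lam * (0.5 + lam / 6.0)
    return np.where(small, series, exact)


def ztp_loglik(gamma: np.ndarray, data: HurdleDataset) -> float:
    """ZTP log-likelihood over positive-count rows.

    ``sum_{y_i>0} [-lam_i + y_i Z_i'gamma - log(1 - e^{-lam_i}) - log(y_i!)]``
    with ``lam_i = exp(Z_i'gamma)``.  Includes the ``-log(y_i!)`` constant so
    reported values are true log-likelihoods.
    """
    gamma = _check_gamma(gamma, data)
    yp, Zp = data.positive_rows()
    eta = Zp @ gamma
    with np.errstate(over="ignore"):
        lam = np.exp(eta)
    if np.any(np.isinf(lam)):
        return -np.inf
    return float(
        np.sum(-lam + yp * eta - np.log(-np.expm1(-lam)) - gammaln(yp + 1))
    )


def ztp_gradient(gamma: np.ndarray, data: HurdleDataset) -> np.ndarray:
    """Score of the ZTP component:
    ``sum_{y_i>0} Z_i (y_i - lam_i - lam_i e^{-lam_i}/(1 - e^{-lam_i}))``.
    """
    gamma = _check_gamma(gamma, data)
    yp, Zp = data.positive_rows()
    lam = np.exp(Zp @ gamma)
    resid = yp - lam - _trunc_correction(lam)
    return Zp.T @ resid


def ztp_hessian(gamma: np.ndarray, data: HurdleDataset) -> np.ndarray:
    """Hessian of the ZTP component: ``-sum_{y_i>0} Z_i Z_i' v(lam_i)`` with
    ``v(lam) = lam (1 + t'(lam))`` the per-observation information factor.
    """
    gamma = _check_gamma(gamma, data)
    _, Zp = data.positive_rows()
    lam = np.exp(Zp @ gamma)
    v = _trunc_info(lam)
    return -(Zp * v[:, None]).T @ Zp


# ---------------------------------------------------------------------------
# Newton-Raphson maximization


def _check_full_rank(mat: np.ndarray, name: str) -> None:
    n, k = mat.shape
    _, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = np.where(diag <= tol)[0]
    if bad.size:
        raise ValueError(
            f"design matrix {name} is rank deficient; collinear columns: {bad.tolist()}"
        )


def _newton_maximize(
    x0: np.ndarray,
    loglik,
    gradient,
    hessian,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Maximize a concave log-likelihood by Newton-Raphson with step halving.

    Converged when ``max |gradient| < tol``.  Returns (argmax, Hessian at the
    argmax, converged flag, iterations used); reaching ``max_iter`` sets
    converged=False rather than raising.
    """
    x = np.array(x0, dtype=float)
    ll = loglik(x)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g = gradient(x)
        if np.max(np.abs(g)) < tol:
            return x, hessian(x), True, n_iter - 1
        H = hessian(x)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return x, H, False, n_iter
        # a vanishing Newton step means the likelihood is stationary to
        # machine precision even if a near-flat direction keeps the raw
        # gradient tolerance out of reach
        if np.max(np.abs(step)) < 1e-10 * (1.0 + np.max(np.abs(x))):
            return x, H, True, n_iter
        # step halving on non-increase of the objective
        scale = 1.0
        ll_cand = -np.inf
        for _ in range(40):
            cand = x + scale * step
            ll_cand = loglik(cand)
            if ll_cand >= ll and np.isfinite(ll_cand):
                break
            scale *= 0.5
        if ll_cand <= ll:
            # no representable improvement in any direction: if the predicted
            # quadratic gain g'H^{-1}g/2 is already below the floating-point
            # resolution of the objective, the maximizer is found even though
            # the raw gradient tolerance is unreachable
            expected_gain = 0.5 * float(g @ step)
            converged = 0.0 <= expected_gain < 1e-10 * (1.0 + abs(ll))
            best = cand if ll_cand == ll else x
            return best, hessian(best), converged, n_iter
        x = cand
        ll = ll_cand
    g = gradient(x)
    converged = bool(np.max(np.abs(g)) < tol)
    return x, hessian(x), converged, n_iter


def _covariance(hess: np.ndarray) -> np.ndarray:
    """Inverse of the negated Hessian (observed-information covariance)."""
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return np.full_like(hess, np.nan)
    return 0.5 * (cov + cov.T)


def fit_hurdle(
    data: HurdleDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Fit both hurdle components by independent Newton-Raphson maximization.

    Information orthogonality (block-diagonal joint Hessian) means the two
    separate maximizations lose nothing relative to a joint fit.  Degenerate
    cases are flagged, not raised: a logistic fit hitting the iteration cap
    (e.g. complete separation) or a ZTP component whose positive counts are
    all ones (MLE at the gamma0 -> -inf boundary) yields converged=False.
    """
    if data.n_pos == 0:
        raise ValueError("no positive counts; zero-truncated component undefined")
    if data.n_pos == data.n:
        raise ValueError("no zero counts; logistic component degenerate")
    _check_full_rank(data.X, "X")
    _check_full_rank(data.Z, "Z")

    flags: list[str] = []
    beta, Hb, conv_b, it_b = _newton_maximize(
        np.zeros(data.p),
        lambda b: logistic_loglik(b, data),
        lambda b: logistic_gradient(b, data),
        lambda b: logistic_hessian(b, data),
        tol=tol,
        max_iter=max_iter,
    )
    if not conv_b:
        flags.append("logistic_not_converged")

    yp, _ = data.positive_rows()
    if np.all(yp == 1):
        # ZTP likelihood sup is attained only as lambda -> 0; no finite MLE.
        gamma = np.zeros(data.q)
        Hg = ztp_hessian(gamma, data)
        conv_g, it_g = False, 0
        flags.append("ztp_boundary")
    else:
        gamma, Hg, conv_g, it_g = _newton_maximize(
            np.zeros(data.q),
            lambda g: ztp_loglik(g, data),
            lambda g: ztp_gradient(g, data),
            lambda g: ztp_hessian(g, data),
            tol=tol,
            max_iter=max_iter,
        )
        if not conv_g:
            flags.append("ztp_not_converged")

    params = HurdleParams(beta=beta, gamma=gamma)
    beta_var = _covariance(Hb) if conv_b else np.full((data.p, data.p), np.nan)
    gamma_var = _covariance(Hg) if conv_g else np.full((data.q, data.q), np.nan)
    return FitResult(
        params=params,
        beta_var=beta_var,
        gamma_var=gamma_var,
        loglik_logistic=logistic_loglik(beta, data),
        loglik_ztp=ztp_loglik(gamma, data),
        converged=conv_b and conv_g,
        n_iter=max(it_b, it_g),
        converged_logistic=conv_b,
        converged_ztp=conv_g,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator


class HurdleRegressor(RegressorMixin, BaseEstimator):
    """Poisson-Logit hurdle regression with a scikit-learn interface.

    Fits the two-part model ``logit P(y>0) = [1, x]'beta``,
    ``log E[y | y>0 part] = [1, x]'gamma`` (zero-truncated Poisson), using
    the same covariates in both components.

    Parameters
    ----------
    tol : float, default=1e-8
        Newton-Raphson convergence tolerance on the max-abs score.
    max_iter : int, default=100
        Iteration cap per component.

    Attributes
    ----------
    beta_ : ndarray of shape (n_features + 1,)
        Logistic coefficients; entry 0 is the intercept.
    gamma_ : ndarray of shape (n_features + 1,)
        Zero-truncated Poisson coefficients; entry 0 is the intercept.
    beta_cov_, gamma_cov_ : ndarray
        Observed-information covariance matrices.
    converged_ : bool
        Whether both component maximizations converged.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if np.any(y < 0) or np.any(np.mod(y, 1) != 0):
            raise ValueError("y must contain non-negative integer counts")
        data = HurdleDataset.from_covariates(y=y, covariates=X)
        result = fit_hurdle(data, tol=self.tol, max_iter=self.max_iter)
        self.n_features_in_ = X.shape[1]
        self.beta_ = result.params.beta
        self.gamma_ = result.params.gamma
        self.beta_cov_ = result.beta_var
        self.gamma_cov_ = result.gamma_var
        self.loglik_logistic_ = result.loglik_logistic
        self.loglik_ztp_ = result.loglik_ztp
        self.converged_ = result.converged
        self.n_iter_ = result.n_iter
        self.fit_result_ = result
        return self

    def predict_hurdle_proba(self, X) -> np.ndarray:
        """Probability of clearing the hurdle, ``P(y > 0 | x)``."""
        check_is_fitted(self, "beta_")
        X = check_array(X)
        return expit(add_intercept(X) @ self.beta_)

    def predict_positive_mean(self, X) -> np.ndarray:
        """Conditional mean given positivity, ``lam / (1 - e^{-lam})``."""
        check_is_fitted(self, "gamma_")
        X = check_array(X)
        lam = np.exp(add_intercept(X) @ self.gamma_)
        return lam / (-np.expm1(-lam))

    def predict(self, X) -> np.ndarray:
        """Expected count ``E[y | x] = P(y>0|x) * E[y | y>0, x]``."""
        return self.predict_hurdle_proba(X) * self.predict_positive_mean(X)
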