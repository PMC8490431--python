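"""One-shot distributed hurdle estimation (ODAH).

Round 1 (initialization): every site fits the hurdle model locally and sends
coefficient and variance estimates; the lead site combines them by
fixed-effects inverse-variance meta-analysis into initial estimates
(beta_bar, gamma_bar).  Alternatively the lead site's own MLEs initialize the
algorithm, saving a communication round.

Round 2 (surrogate-likelihood estimation): every site evaluates the analytic
first- and second-order gradients of both component log-likelihoods at the
initial estimates and sends them.  The lead site forms the surrogate

    Ltilde(theta) = L_lead(theta) + <g_N - g_lead, theta>
                    + 1/2 (theta - theta_bar)' (H_N - H_lead) (theta - theta_bar)

per component, where g_N, H_N are sample-size-weighted averages of the site
gradients/Hessians, and maximizes it.  Only aggregate quantities of fixed
dimension ever leave a site.

All per-site gradients are on the *average* log-likelihood scale: the
logistic component divides by the site's n, the zero-truncated Poisson (ZTP)
component by its positive-count n, so the cross-site combination is a literal
weighted average and the pooled covariance scale is restored by multiplying
the negated surrogate Hessian by the total (positive-count) sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_X_y

from .datasets import HurdleDataset
from .hurdle import (
    FitResult,
    HurdleParams,
    _covariance,
    _newton_maximize,
    logistic_gradient,
    logistic_hessian,
    logistic_loglik,
    ztp_gradient,
    ztp_hessian,
    ztp_loglik,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSummary",
    "InitialEstimates",
    "GradientPayload",
    "AggregatedGradients",
    "OdahResult",
    "summarize_fit",
    "meta_initialize",
    "lead_initialize",
    "compute_gradients",
    "aggregate_gradients",
    "surrogate_loglik",
    "odah_solve",
    "run_protocol",
    "DistributedHurdleRegressor",
]


@dataclass
class SiteSummary:
    """Round-1 message: one site's local estimates and diagonal variances."""

    site_id: str
    n: int
    n_pos: int
    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    beta_var_diag: np.ndarray
    gamma_var_diag: np.ndarray
    converged_logistic: bool = True
    converged_ztp: bool = True

    def __post_init__(self) -> None:
        for name in ("beta_hat", "gamma_hat", "beta_var_diag", "gamma_var_diag"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if self.n <= 0:
            raise ValueError("site sample size must be positive")


@dataclass
class InitialEstimates:
    """Broadcast initial values (beta_bar, gamma_bar) for round 2."""

    beta_bar: np.ndarray
    gamma_bar: np.ndarray
    source: str = "meta"

    def __post_init__(self) -> None:
        self.beta_bar = np.asarray(self.beta_bar, dtype=float).ravel()
        self.gamma_bar = np.asarray(self.gamma_bar, dtype=float).ravel()
        if self.source not in ("meta", "lead"):
            raise ValueError("source must be 'meta' or 'lead'")
        if not (
            np.all(np.isfinite(self.beta_bar)) and np.all(np.isfinite(self.gamma_bar))
        ):
            raise ValueError("initial estimates must be finite")


@dataclass
class GradientPayload:
    """Round-2 message: average-scale gradients/Hessians at the initial
    estimates.  ``grad1_ztp``/``hess_ztp`` are None for a site without
    positive counts (its ZTP likelihood is empty)."""

    site_id: str
    n: int
    n_pos: int
    evaluated_at: InitialEstimates
    grad1_logistic: np.ndarray
    hess_logistic: np.ndarray
    grad1_ztp: np.ndarray | None
    hess_ztp: np.ndarray | None

    def __post_init__(self) -> None:
        self.grad1_logistic = np.asarray(self.grad1_logistic, dtype=float).ravel()
        self.hess_logistic = np.asarray(self.hess_logistic, dtype=float)
        if self.grad1_ztp is not None:
            self.grad1_ztp = np.asarray(self.grad1_ztp, dtype=float).ravel()
            self.hess_ztp = np.asarray(self.hess_ztp, dtype=float)
        p = self.evaluated_at.beta_bar.shape[0]
        if self.grad1_logistic.shape != (p,) or self.hess_logistic.shape != (p, p):
            raise ValueError("logistic gradient dimensions inconsistent with init")
        if self.grad1_ztp is not None:
            q = self.evaluated_at.gamma_bar.shape[0]
            if self.grad1_ztp.shape != (q,) or self.hess_ztp.shape != (q, q):
                raise ValueError("ZTP gradient dimensions inconsistent with init")


@dataclass
class AggregatedGradients:
    """Weighted-average gradients/Hessians across all sites (lead included)."""

    evaluated_at: InitialEstimates
    n_total: int
    n_pos_total: int
    grad1_logistic: np.ndarray
    hess_logistic: np.ndarray
    grad1_ztp: np.ndarray
    hess_ztp: np.ndarray


@dataclass
class OdahResult:
    """Surrogate maximum-likelihood estimates and their covariances."""

    params: HurdleParams
    beta_var: np.ndarray
    gamma_var: np.ndarray
    initial: InitialEstimates
    surrogate_loglik_logistic: float
    surrogate_loglik_ztp: float
    n_total: int
    n_pos_total: int
    converged: bool = True


# ---------------------------------------------------------------------------
# Round 1


def summarize_fit(fit: FitResult, data: HurdleDataset) -> SiteSummary:
    """Package a local fit as the round-1 aggregate message."""
    return SiteSummary(
        site_id=data.site_id,
        n=data.n,
        n_pos=data.n_pos,
        beta_hat=fit.params.beta,
        gamma_hat=fit.params.gamma,
        beta_var_diag=np.diag(fit.beta_var),
        gamma_var_diag=np.diag(fit.gamma_var),
        converged_logistic=fit.converged_logistic,
        converged_ztp=fit.converged_ztp,
    )


def _meta_combine(
    estimates: list[np.ndarray], variances: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    est = np.vstack(estimates)
    var = np.vstack(variances)
    if np.any(~np.isfinite(var)) or np.any(var <= 0):
        raise ValueError("meta-analysis requires strictly positive finite variances")
    w = 1.0 / var
    return (est * w).sum(axis=0) / w.sum(axis=0), 1.0 / w.sum(axis=0)


def meta_initialize(summaries: list[SiteSummary]) -> InitialEstimates:
    """Fixed-effects inverse-variance meta-analysis of per-site estimates.

    Coordinate-wise: ``theta_bar_k = sum_j theta_hat_jk w_jk / sum_j w_jk``
    with ``w_jk = 1 / var_jk``.  Sites whose local fit did not converge for a
    component are excluded from that component's combination (with a logged
    warning); their gradients still enter round 2.
    """
    if not summaries:
        raise ValueError("at least one site summary required")
    p = summaries[0].beta_hat.shape[0]
    q = summaries[0].gamma_hat.shape[0]
    for s in summaries:
        if s.beta_hat.shape[0] != p or s.gamma_hat.shape[0] != q:
            raise ValueError("site summaries have mismatched dimensions")
    ok_b = [s for s in summaries if s.converged_logistic]
    ok_g = [s for s in summaries if s.converged_ztp]
    excluded = [s.site_id for s in summaries if not (s.converged_logistic and s.converged_ztp)]
    if excluded:
        logger.warning(
            "meta initialization excludes unconverged site fits: %s", excluded
        )
    if not ok_b:
        raise ValueError("no converged logistic fits to meta-analyze")
    if not ok_g:
        raise ValueError("no converged zero-truncated Poisson fits to meta-analyze")
    beta_bar, _ = _meta_combine(
        [s.beta_hat for s in ok_b], [s.beta_var_diag for s in ok_b]
    )
    gamma_bar, _ = _meta_combine(
        [s.gamma_hat for s in ok_g], [s.gamma_var_diag for s in ok_g]
    )
    return InitialEstimates(beta_bar=beta_bar, gamma_bar=gamma_bar, source="meta")


def lead_initialize(lead_fit: FitResult) -> InitialEstimates:
    """Use the lead site's MLEs as initial values (skips round 1)."""
    if not lead_fit.converged:
        raise ValueError("lead-site fit did not converge; cannot initialize")
    return InitialEstimates(
        beta_bar=lead_fit.params.beta,
        gamma_bar=lead_fit.params.gamma,
        source="lead",
    )


# ---------------------------------------------------------------------------
# Round 2


def compute_gradients(data: HurdleDataset, init: InitialEstimates) -> GradientPayload:
    """Evaluate average-scale gradients/Hessians at the initial estimates.

    Logistic blocks are divided by the site's n; ZTP blocks by its
    positive-count n (the ZTP likelihood only sums over positive rows).
    The payload carries no patient-level values.
    """
    p = init.beta_bar.shape[0]
    if data.n == 0:
        # an empty site carries zero aggregation weight either way
        g1, h1 = np.zeros(p), np.zeros((p, p))
    else:
        g1 = logistic_gradient(init.beta_bar, data) / data.n
        h1 = logistic_hessian(init.beta_bar, data) / data.n
    if data.n_pos > 0:
        g2 = ztp_gradient(init.gamma_bar, data) / data.n_pos
        h2 = ztp_hessian(init.gamma_bar, data) / data.n_pos
    else:
        g2 = h2 = None
    return GradientPayload(
        site_id=data.site_id,
        n=data.n,
        n_pos=data.n_pos,
        evaluated_at=init,
        grad1_logistic=g1,
        hess_logistic=h1,
        grad1_ztp=g2,
        hess_ztp=h2,
    )


def _same_init(a: InitialEstimates, b: InitialEstimates) -> bool:
    return np.array_equal(a.beta_bar, b.beta_bar) and np.array_equal(
        a.gamma_bar, b.gamma_bar
    )


def aggregate_gradients(payloads: list[GradientPayload]) -> AggregatedGradients:
    """Sample-size-weighted average of site gradients/Hessians.

    Logistic blocks use weights n_j / N; ZTP blocks use positive-count
    weights n_pos_j / N_pos, skipping sites without positive counts.
    """
    if not payloads:
        raise ValueError("at least one gradient payload required")
    init = payloads[0].evaluated_at
    for pl in payloads[1:]:
        if not _same_init(init, pl.evaluated_at):
            raise ValueError("gradient evaluation points differ")
    n_total = sum(pl.n for pl in payloads)
    n_pos_total = sum(pl.n_pos for pl in payloads)
    g1 = sum(pl.n * pl.grad1_logistic for pl in payloads) / n_total
    h1 = sum(pl.n * pl.hess_logistic for pl in payloads) / n_total
    ztp = [pl for pl in payloads if pl.grad1_ztp is not None]
    if not ztp or n_pos_total == 0:
        raise ValueError("no site has positive counts; ZTP aggregation undefined")
    g2 = sum(pl.n_pos * pl.grad1_ztp for pl in ztp) / n_pos_total
    h2 = sum(pl.n_pos * pl.hess_ztp for pl in ztp) / n_pos_total
    return AggregatedGradients(
        evaluated_at=init,
        n_total=n_total,
        n_pos_total=n_pos_total,
        grad1_logistic=g1,
        hess_logistic=h1,
        grad1_ztp=g2,
        hess_ztp=h2,
    )


# ---------------------------------------------------------------------------
# Surrogate likelihood


def _surrogate_parts(lead_data: HurdleDataset, agg: AggregatedGradients):
    """Precompute lead-site average-scale gradients at the initial values and
    the constant gradient/Hessian corrections for both components."""
    init = agg.evaluated_at
    n1, m1 = lead_data.n, lead_data.n_pos
    if m1 == 0:
        raise ValueError("lead site has no positive counts; ZTP surrogate undefined")
    g1_lead = logistic_gradient(init.beta_bar, lead_data) / n1
    h1_lead = logistic_hessian(init.beta_bar, lead_data) / n1
    g2_lead = ztp_gradient(init.gamma_bar, lead_data) / m1
    h2_lead = ztp_hessian(init.gamma_bar, lead_data) / m1
    dg1 = agg.grad1_logistic - g1_lead
    dh1 = agg.hess_logistic - h1_lead
    dg2 = agg.grad1_ztp - g2_lead
    dh2 = agg.hess_ztp - h2_lead
    return dg1, dh1, dg2, dh2


def surrogate_loglik(
    params: HurdleParams,
    lead_data: HurdleDataset,
    aggregated: AggregatedGradients,
    init: InitialEstimates,
) -> tuple[float, float]:
    """Evaluate both surrogate log-likelihoods at ``params``.

    Each component is the lead site's average log-likelihood plus a linear
    correction ``<g_N - g_lead, theta>`` and a quadratic correction
    ``1/2 (theta - theta_bar)' (H_N - H_lead) (theta - theta_bar)``.
    """
    if not _same_init(init, aggregated.evaluated_at):
        raise ValueError("aggregated gradients were not evaluated at this init")
    dg1, dh1, dg2, dh2 = _surrogate_parts(lead_data, aggregated)
    beta, gamma = params.beta, params.gamma
    db = beta - init.beta_bar
    dgm = gamma - init.gamma_bar
    l1 = (
        logistic_loglik(beta, lead_data) / lead_data.n
        + dg1 @ beta
        + 0.5 * db @ dh1 @ db
    )
    l2 = (
        ztp_loglik(gamma, lead_data) / lead_data.n_pos
        + dg2 @ gamma
        + 0.5 * dgm @ dh2 @ dgm
    )
    return float(l1), float(l2)


def odah_solve(
    lead_data: HurdleDataset,
    aggregated: AggregatedGradients,
    init: InitialEstimates,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> OdahResult:
    """Maximize each surrogate log-likelihood by Newton-Raphson from the
    initial estimates.

    Covariance is the inverse of N times the negated surrogate Hessian at the
    optimum (N = total n for the logistic component, total positive-count n
    for the ZTP component), restoring absolute scale from the 1/N-averaged
    likelihood.  A non-concave corrected Hessian raises with the offending
    eigenvalue.
    """
    if not _same_init(init, aggregated.evaluated_at):
        raise ValueError("aggregated gradients were not evaluated at this init")
    dg1, dh1, dg2, dh2 = _surrogate_parts(lead_data, aggregated)
    n1, m1 = lead_data.n, lead_data.n_pos
    bbar, gbar = init.beta_bar, init.gamma_bar

    def check_concave(hess: np.ndarray, label: str) -> None:
        top = np.linalg.eigvalsh(hess)[-1]
        if top >= 0:
            raise ValueError(
                f"surrogate {label} Hessian is not negative definite "
                f"(largest eigenvalue {top:.3e})"
            )

    def sur1(b):
        db = b - bbar
        return logistic_loglik(b, lead_data) / n1 + dg1 @ b + 0.5 * db @ dh1 @ db

    def sur1_grad(b):
        return logistic_gradient(b, lead_data) / n1 + dg1 + dh1 @ (b - bbar)

    def sur1_hess(b):
        return logistic_hessian(b, lead_data) / n1 + dh1

    def sur2(g):
        dg = g - gbar
        return ztp_loglik(g, lead_data) / m1 + dg2 @ g + 0.5 * dg @ dh2 @ dg

    def sur2_grad(g):
        return ztp_gradient(g, lead_data) / m1 + dg2 + dh2 @ (g - gbar)

    def sur2_hess(g):
        return ztp_hessian(g, lead_data) / m1 + dh2

    check_concave(sur1_hess(bbar), "logistic")
    check_concave(sur2_hess(gbar), "zero-truncated Poisson")

    beta, Hb, conv_b, _ = _newton_maximize(
        bbar, sur1, sur1_grad, sur1_hess, tol=tol, max_iter=max_iter
    )
    gamma, Hg, conv_g, _ = _newton_maximize(
        gbar, sur2, sur2_grad, sur2_hess, tol=tol, max_iter=max_iter
    )
    beta_var = _covariance(aggregated.n_total * Hb)
    gamma_var = _covariance(aggregated.n_pos_total * Hg)
    return OdahResult(
        params=HurdleParams(beta=beta, gamma=gamma),
        beta_var=beta_var,
        gamma_var=gamma_var,
        initial=init,
        surrogate_loglik_logistic=sur1(beta),
        surrogate_loglik_ztp=sur2(gamma),
        n_total=aggregated.n_total,
        n_pos_total=aggregated.n_pos_total,
        converged=conv_b and conv_g,
    )


# ---------------------------------------------------------------------------
# Protocol driver


def run_protocol(
    datasets: list[HurdleDataset],
    initializer: str = "meta",
    tol: float = 1e-8,
    max_iter: int = 100,
    site_fits: list[FitResult] | None = None,
) -> tuple[OdahResult, dict]:
    """Execute the full one-shot protocol with the first dataset as lead.

    Returns the ODAH result plus a transcript dict recording, per site, how
    many aggregate messages it sent (two under meta initialization, one under
    lead initialization), for auditability.
    """
    from .hurdle import fit_hurdle  # local import to avoid cycle at module load

    if not datasets:
        raise ValueError("at least one site dataset required")
    lead = datasets[0]
    exchanges = {d.site_id: 0 for d in datasets}
    if initializer == "meta":
        if site_fits is None:
            site_fits = [fit_hurdle(d, tol=tol, max_iter=max_iter) for d in datasets]
        summaries = []
        for d, f in zip(datasets, site_fits):
            summaries.append(summarize_fit(f, d))
            exchanges[d.site_id] += 1  # round-1 summary message
        init = meta_initialize(summaries)
    elif initializer == "lead":
        lead_fit = (
            site_fits[0] if site_fits is not None else fit_hurdle(lead, tol=tol, max_iter=max_iter)
        )
        init = lead_initialize(lead_fit)
    else:
        raise ValueError("initializer must be 'meta' or 'lead'")
    payloads = []
    for d in datasets:
        payloads.append(compute_gradients(d, init))
        exchanges[d.site_id] += 1  # round-2 gradient message
    agg = aggregate_gradients(payloads)
    result = odah_solve(lead, agg, init, tol=tol, max_iter=max_iter)
    transcript = {"messages_per_site": exchanges, "initializer": initializer}
    return result, transcript


class DistributedHurdleRegressor(BaseEstimator):
    """Surrogate-likelihood hurdle fit from lead-site data plus aggregates.

    scikit-learn-style wrapper over :func:`odah_solve`: ``fit`` takes the
    lead site's raw covariates and counts together with the aggregated
    cross-site gradients and the broadcast initial estimates.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, *, aggregated: AggregatedGradients, init: InitialEstimates):
        X, y = check_X_y(X, y, y_numeric=True)
        data = HurdleDataset.from_covariates(y=y, covariates=X, site_id="lead")
        result = odah_solve(
            data, aggregated, init, tol=self.tol, max_iter=self.max_iter
        )
        self.n_features_in_ = X.shape[1]
        self.beta_ = result.params.beta
        self.gamma_ = result.params.gamma
        self.beta_cov_ = result.beta_var
        self.gamma_cov_ = result.gamma_var
        self.converged_ = result.converged
        self.result_ = result
        return self

    def get_result(self) -> OdahResult:
        check_is_fitted(self, "result_")
        return self.result_
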