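"""Comparator estimators: pooled (gold standard), fixed-effects
meta-analysis, and lead-site-only analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import HurdleDataset
from .hurdle import FitResult, HurdleParams, fit_hurdle
from .protocol import SiteSummary, _meta_combine

__all__ = ["MethodEstimate", "pooled_fit", "meta_fit", "lead_fit", "concat_datasets"]

_METHODS = ("pooled", "meta", "lead", "odah")


@dataclass
class MethodEstimate:
    """One method's coefficient estimates with diagonal variances."""

    method: str
    params: HurdleParams
    beta_var_diag: np.ndarray
    gamma_var_diag: np.ndarray
    converged: bool = True
    converged_logistic: bool = True
    converged_ztp: bool = True

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        self.beta_var_diag = np.asarray(self.beta_var_diag, dtype=float).ravel()
        self.gamma_var_diag = np.asarray(self.gamma_var_diag, dtype=float).ravel()


def _from_fit(method: str, fit: FitResult) -> MethodEstimate:
    return MethodEstimate(
        method=method,
        params=fit.params,
        beta_var_diag=np.diag(fit.beta_var),
        gamma_var_diag=np.diag(fit.gamma_var),
        converged=fit.converged,
        converged_logistic=fit.converged_logistic,
        converged_ztp=fit.converged_ztp,
    )


def concat_datasets(datasets: list[HurdleDataset]) -> HurdleDataset:
    """Row-wise concatenation of site datasets into one pooled dataset."""
    if not datasets:
        raise ValueError("at least one dataset required")
    p, q = datasets[0].p, datasets[0].q
    for d in datasets[1:]:
        if d.p != p or d.q != q:
            raise ValueError("datasets have mismatched design dimensions")
    return HurdleDataset(
        y=np.concatenate([d.y for d in datasets]),
        X=np.vstack([d.X for d in datasets]),
        Z=np.vstack([d.Z for d in datasets]),
        site_id="pooled",
    )


def pooled_fit(datasets: list[HurdleDataset], **fit_kwargs) -> MethodEstimate:
    """Hurdle MLE on all patient-level rows pooled together."""
    return _from_fit("pooled", fit_hurdle(concat_datasets(datasets), **fit_kwargs))


def meta_fit(summaries: list[SiteSummary]) -> MethodEstimate:
    """Fixed-effects inverse-variance meta-analysis of per-site fits.

    Point estimates are coordinate-wise inverse-variance weighted means; the
    combined variance of each coefficient is ``1 / sum_j w_j``.  Sites whose
    local fit did not converge for a component are excluded from that
    component (recorded via the converged flags when nothing is combinable).
    """
    if not summaries:
        raise ValueError("at least one site summary required")
    ok_b = [s for s in summaries if s.converged_logistic]
    ok_g = [s for s in summaries if s.converged_ztp]
    p = summaries[0].beta_hat.shape[0]
    q = summaries[0].gamma_hat.shape[0]
    if ok_b:
        beta, beta_var = _meta_combine(
            [s.beta_hat for s in ok_b], [s.beta_var_diag for s in ok_b]
        )
    else:
        beta, beta_var = np.zeros(p), np.full(p, np.nan)
    if ok_g:
        gamma, gamma_var = _meta_combine(
            [s.gamma_hat for s in ok_g], [s.gamma_var_diag for s in ok_g]
        )
    else:
        gamma, gamma_var = np.zeros(q), np.full(q, np.nan)
    return MethodEstimate(
        method="meta",
        params=HurdleParams(beta=beta, gamma=gamma),
        beta_var_diag=beta_var,
        gamma_var_diag=gamma_var,
        converged=bool(ok_b) and bool(ok_g),
        converged_logistic=bool(ok_b),
        converged_ztp=bool(ok_g),
    )


def lead_fit(lead_data: HurdleDataset, **fit_kwargs) -> MethodEstimate:
    """Single-site analysis using only the lead site's rows.

    Rare-event lead sites may fail to converge; the flags propagate so the
    study runner can aggregate with medians over successful replicates.
    """
    return _from_fit("lead", fit_hurdle(lead_data, **fit_kwargs))
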