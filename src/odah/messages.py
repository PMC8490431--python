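"""JSON message formats for the inter-site exchanges.

One file per site per round.  Numbers are serialized at full double
precision (Python's ``repr`` round-trips IEEE-754 doubles exactly).  Each
reader validates structurally before any computation: required keys, types,
and array shapes; a payload may contain only fixed-dimension aggregate
vectors/matrices, never row-level data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .protocol import GradientPayload, InitialEstimates, SiteSummary

__all__ = [
    "MessageError",
    "summary_to_dict",
    "summary_from_dict",
    "init_to_dict",
    "init_from_dict",
    "gradient_to_dict",
    "gradient_from_dict",
    "write_message",
    "read_summary",
    "read_init",
    "read_gradient",
]


class MessageError(ValueError):
    """A message failed structural validation."""


def _vec(x: np.ndarray) -> list:
    return [float(v) for v in np.asarray(x).ravel()]


def _mat(x: np.ndarray) -> list:
    return [[float(v) for v in row] for row in np.asarray(x)]


def _require(obj: dict, key: str, kind, where: str):
    if key not in obj:
        raise MessageError(f"{where}: missing key {key!r}")
    val = obj[key]
    if kind is int and (not isinstance(val, int) or isinstance(val, bool)):
        raise MessageError(f"{where}: key {key!r} must be an integer")
    if kind is str and not isinstance(val, str):
        raise MessageError(f"{where}: key {key!r} must be a string")
    if kind is bool and not isinstance(val, bool):
        raise MessageError(f"{where}: key {key!r} must be a boolean")
    if kind is list and not isinstance(val, list):
        raise MessageError(f"{where}: key {key!r} must be an array")
    if kind is dict and not isinstance(val, dict):
        raise MessageError(f"{where}: key {key!r} must be an object")
    return val


def _as_vector(val, key: str, where: str) -> np.ndarray:
    arr = np.asarray(val, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise MessageError(f"{where}: key {key!r} must be a non-empty 1-d array")
    return arr


def _as_matrix(val, key: str, where: str, dim: int) -> np.ndarray:
    arr = np.asarray(val, dtype=float)
    if arr.shape != (dim, dim):
        raise MessageError(f"{where}: key {key!r} must be a {dim}x{dim} matrix")
    return arr


# -- summary (round 1) ------------------------------------------------------


def summary_to_dict(s: SiteSummary) -> dict:
    return {
        "message": "summary",
        "site_id": s.site_id,
        "n": int(s.n),
        "n_pos": int(s.n_pos),
        "beta_hat": _vec(s.beta_hat),
        "gamma_hat": _vec(s.gamma_hat),
        "beta_var": _vec(s.beta_var_diag),
        "gamma_var": _vec(s.gamma_var_diag),
        "converged_logistic": bool(s.converged_logistic),
        "converged_ztp": bool(s.converged_ztp),
    }


def summary_from_dict(obj: dict) -> SiteSummary:
    where = "summary message"
    site_id = _require(obj, "site_id", str, where)
    n = _require(obj, "n", int, where)
    n_pos = _require(obj, "n_pos", int, where)
    beta = _as_vector(_require(obj, "beta_hat", list, where), "beta_hat", where)
    gamma = _as_vector(_require(obj, "gamma_hat", list, where), "gamma_hat", where)
    bvar = _as_vector(_require(obj, "beta_var", list, where), "beta_var", where)
    gvar = _as_vector(_require(obj, "gamma_var", list, where), "gamma_var", where)
    if bvar.shape != beta.shape or gvar.shape != gamma.shape:
        raise MessageError(f"{where}: variance vectors must match estimate lengths")
    return SiteSummary(
        site_id=site_id,
        n=n,
        n_pos=n_pos,
        beta_hat=beta,
        gamma_hat=gamma,
        beta_var_diag=bvar,
        gamma_var_diag=gvar,
        converged_logistic=bool(obj.get("converged_logistic", True)),
        converged_ztp=bool(obj.get("converged_ztp", True)),
    )


# -- initial estimates (broadcast) ------------------------------------------


def init_to_dict(init: InitialEstimates) -> dict:
    return {
        "message": "init",
        "source": init.source,
        "beta_bar": _vec(init.beta_bar),
        "gamma_bar": _vec(init.gamma_bar),
    }


def init_from_dict(obj: dict) -> InitialEstimates:
    where = "init message"
    source = _require(obj, "source", str, where)
    beta = _as_vector(_require(obj, "beta_bar", list, where), "beta_bar", where)
    gamma = _as_vector(_require(obj, "gamma_bar", list, where), "gamma_bar", where)
    return InitialEstimates(beta_bar=beta, gamma_bar=gamma, source=source)


# -- gradients (round 2) -----------------------------------------------------


def gradient_to_dict(p: GradientPayload) -> dict:
    return {
        "message": "gradient",
        "site_id": p.site_id,
        "n": int(p.n),
        "n_pos": int(p.n_pos),
        "evaluated_at": {
            "beta_bar": _vec(p.evaluated_at.beta_bar),
            "gamma_bar": _vec(p.evaluated_at.gamma_bar),
            "source": p.evaluated_at.source,
        },
        "grad1_logistic": _vec(p.grad1_logistic),
        "hess_logistic": _mat(p.hess_logistic),
        "grad1_ztp": None if p.grad1_ztp is None else _vec(p.grad1_ztp),
        "hess_ztp": None if p.hess_ztp is None else _mat(p.hess_ztp),
    }


def gradient_from_dict(obj: dict) -> GradientPayload:
    where = "gradient message"
    site_id = _require(obj, "site_id", str, where)
    n = _require(obj, "n", int, where)
    n_pos = _require(obj, "n_pos", int, where)
    at = _require(obj, "evaluated_at", dict, where)
    beta_bar = _as_vector(_require(at, "beta_bar", list, where), "beta_bar", where)
    gamma_bar = _as_vector(_require(at, "gamma_bar", list, where), "gamma_bar", where)
    init = InitialEstimates(
        beta_bar=beta_bar, gamma_bar=gamma_bar, source=at.get("source", "meta")
    )
    p = beta_bar.shape[0]
    q = gamma_bar.shape[0]
    g1 = _as_vector(
        _require(obj, "grad1_logistic", list, where), "grad1_logistic", where
    )
    if g1.shape != (p,):
        raise MessageError(f"{where}: grad1_logistic must have length {p}")
    h1 = _as_matrix(_require(obj, "hess_logistic", list, where), "hess_logistic", where, p)
    if obj.get("grad1_ztp") is None:
        g2 = h2 = None
        if n_pos != 0:
            raise MessageError(f"{where}: ZTP gradients absent but n_pos > 0")
    else:
        g2 = _as_vector(obj["grad1_ztp"], "grad1_ztp", where)
        if g2.shape != (q,):
            raise MessageError(f"{where}: grad1_ztp must have length {q}")
        h2 = _as_matrix(obj.get("hess_ztp"), "hess_ztp", where, q)
    return GradientPayload(
        site_id=site_id,
        n=n,
        n_pos=n_pos,
        evaluated_at=init,
        grad1_logistic=g1,
        hess_logistic=h1,
        grad1_ztp=g2,
        hess_ztp=h2,
    )


# -- file I/O ----------------------------------------------------------------


def write_message(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def _load(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise MessageError(f"{path}: not valid JSON ({err})") from err


def read_summary(path) -> SiteSummary:
    return summary_from_dict(_load(path))


def read_init(path) -> InitialEstimates:
    return init_from_dict(_load(path))


def read_gradient(path) -> GradientPayload:
    return gradient_from_dict(_load(path))
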