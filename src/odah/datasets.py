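"""Patient-level data container for hurdle regression.

A site's data is a non-negative integer count outcome ``y`` together with two
design matrices: ``X`` for the logistic (zero vs. positive) component and
``Z`` for the zero-truncated Poisson (magnitude) component.  Both matrices
carry an explicit all-ones intercept as column 0.  The binary hurdle response
``w = 1(y > 0)`` is never stored; it is always recomputed from ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HurdleDataset", "add_intercept", "read_site_csv"]


def add_intercept(covariates: np.ndarray) -> np.ndarray:
    """Prepend an all-ones intercept column to a covariate matrix."""
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return np.column_stack([np.ones(covariates.shape[0]), covariates])


@dataclass
class HurdleDataset:
    """One site's patient-level rows.

    Parameters
    ----------
    y : array of shape (n,)
        Non-negative integer counts.
    X : array of shape (n, p)
        Design matrix for the logistic component; column 0 is the intercept.
    Z : array of shape (n, q)
        Design matrix for the zero-truncated Poisson component; column 0 is
        the intercept.
    site_id : str
        Label for the site the rows belong to.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    site_id: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1:
            raise ValueError("y must be a 1-d count vector")
        if not np.all(self.y >= 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.equal(np.mod(self.y, 1), 0)):
            raise ValueError("counts must be integer-valued")
        self.y = self.y.astype(np.int64)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = self.y.shape[0]
        for name, mat in (("X", self.X), ("Z", self.Z)):
            if mat.ndim != 2 or mat.shape[0] != n:
                raise ValueError(f"{name} must be 2-d with {n} rows")
            if not np.allclose(mat[:, 0], 1.0):
                raise ValueError(f"{name} must carry an all-ones intercept in column 0")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_pos(self) -> int:
        return int(np.count_nonzero(self.y))

    @property
    def w(self) -> np.ndarray:
        """Hurdle indicator w_i = 1(y_i > 0), recomputed on access."""
        return (self.y > 0).astype(float)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def positive_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts and Z-rows restricted to positive-count observations."""
        mask = self.y > 0
        return self.y[mask], self.Z[mask]

    @classmethod
    def from_covariates(
        cls,
        y: np.ndarray,
        covariates: np.ndarray,
        site_id: str = "",
        ztp_covariates: np.ndarray | None = None,
    ) -> "HurdleDataset":
        """Build a dataset from raw covariates, adding intercepts.

        By default the same covariates feed both components.
        """
        X = add_intercept(covariates)
        Z = X if ztp_covariates is None else add_intercept(ztp_covariates)
        return cls(y=y, X=X, Z=Z, site_id=site_id)


def read_site_csv(
    path,
    outcome_column: str = "y",
    logistic_covariates: list[str] | None = None,
    ztp_covariates: list[str] | None = None,
    site_id: str | None = None,
) -> HurdleDataset:
    """Read one site's patient-level CSV into a :class:`HurdleDataset`.

    The file must have a header; ``outcome_column`` holds the counts and the
    remaining columns are covariates, used in file order for both components
    unless explicit per-component covariate lists are given.  Integral floats
    (e.g. ``2.0``) are accepted as counts; fractional values are rejected.
    """
    frame = pd.read_csv(path)
    if outcome_column not in frame.columns:
        raise ValueError(f"outcome column {outcome_column!r} not found in {path}")
    y_raw = frame[outcome_column].to_numpy(dtype=float)
    if not np.all(np.equal(np.mod(y_raw, 1), 0)):
        raise ValueError(f"non-integral counts in column {outcome_column!r}")
    default_covs = [c for c in frame.columns if c != outcome_column]
    x_cols = logistic_covariates if logistic_covariates else default_covs
    z_cols = ztp_covariates if ztp_covariates else default_covs
    missing = [c for c in set(x_cols) | set(z_cols) if c not in frame.columns]
    if missing:
        raise ValueError(f"covariate columns missing from {path}: {missing}")
    X = add_intercept(frame[x_cols].to_numpy(dtype=float))
    Z = add_intercept(frame[z_cols].to_numpy(dtype=float))
    label = site_id if site_id is not None else str(path)
    return HurdleDataset(y=y_raw, X=X, Z=Z, site_id=label)
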