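"""Shared fixtures: small random hurdle datasets and cached study runs."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from odah import HurdleDataset, HurdleParams
from odah.simulate import generate_covariates, generate_outcome

logging.getLogger("odah").setLevel(logging.ERROR)
logging.getLogger("odah.protocol").setLevel(logging.ERROR)


def make_dataset(
    seed: int,
    n: int = 300,
    beta=(-0.5, 0.4, -0.3),
    gamma=(0.3, 0.2, -0.4),
    site_id: str = "site",
) -> HurdleDataset:
    """A moderately informative random dataset: ~30-60% positives, counts
    spread over several values, so every component is well identified."""
    rng = np.random.default_rng(seed)
    cov = np.column_stack(
        [rng.normal(0.0, 1.0, size=n), rng.binomial(1, 0.4, size=n).astype(float)]
    )
    params = HurdleParams(beta=np.asarray(beta), gamma=np.asarray(gamma))
    data = HurdleDataset.from_covariates(
        y=np.zeros(n), covariates=cov, site_id=site_id
    )
    data.y = generate_outcome(data.X, params, rng)
    if data.n_pos == 0 or data.n_pos == n:  # pragma: no cover - defensive
        raise RuntimeError("degenerate draw; pick another seed")
    return data


def make_multisite(seed: int, K: int = 3, n: int = 400) -> list[HurdleDataset]:
    return [
        make_dataset(seed * 101 + j, n=n, site_id=f"site{j + 1}") for j in range(K)
    ]


@pytest.fixture()
def dataset() -> HurdleDataset:
    return make_dataset(7)


@pytest.fixture()
def multisite() -> list[HurdleDataset]:
    return make_multisite(11)


@pytest.fixture(scope="session")
def study_cache():
    """Lazily computed, session-shared simulation studies per scenario.

    The replicated studies are the expensive part of the suite; every test
    that needs a scenario's summaries pulls from here so each (setting,
    replicates) pair is simulated exactly once.
    """
    from odah import run_study, table1_settings

    cache: dict[tuple[str, int], object] = {}
    settings = {s.name: s for s in table1_settings(seed=20260919)}

    def get(name: str, n_replicates: int = 60):
        key = (name, n_replicates)
        if key not in cache:
            cache[key] = run_study(settings[name], n_replicates)
        return cache[key]

    return get
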