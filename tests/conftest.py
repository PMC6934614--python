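"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from dmrpart import (
    CovariateTable,
    DMParams,
    SimDesign,
    TaxaCountMatrix,
    body_site_profiles,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def small_counts():
    return TaxaCountMatrix(
        [[5, 3, 2], [1, 7, 2], [4, 4, 2], [9, 0, 1]],
        sample_ids=["a", "b", "c", "d"],
    )


def make_three_group(rng, group_size=40, theta=0.08, sd=0.2, reads=2000,
                     n_taxa=10):
    """Three DM groups tied to one normal covariate (means -1, 0, 1)."""
    pis = body_site_profiles(n_taxa)
    design = SimDesign(
        groups=[(pi, mu, group_size) for pi, mu in zip(pis, (-1.0, 0.0, 1.0))],
        theta=theta, reads=reads, covariate_sd=sd,
    )
    return simulate_dataset(design, rng)


@pytest.fixture
def three_group_data(rng):
    return make_three_group(rng)


def make_binary_illustration(rng, n=100):
    """Two uniform covariates and a binary outcome with region-wise P(Z=1):
    0.95 if Y<=0.5; 0.05 if Y>0.5 and X<=0.5; 0.70 otherwise."""
    X = rng.uniform(size=n)
    Y = rng.uniform(size=n)
    p = np.where(Y <= 0.5, 0.95, np.where(X <= 0.5, 0.05, 0.70))
    Z = (rng.uniform(size=n) < p).astype(int)
    cov = CovariateTable(np.column_stack([X, Y]), ["X", "Y"])
    return Z, cov
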