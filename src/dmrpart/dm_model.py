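"""Dirichlet-multinomial model for overdispersed taxa counts.

The Dirichlet-multinomial (DM) distribution models a vector of taxa counts
``x = (x_1, ..., x_J)`` with fixed total ``N = sum_j x_j`` as a multinomial
whose probability vector is itself Dirichlet-distributed.  It is
parameterized here by the expected taxa proportions ``pi`` (on the simplex)
and a scalar overdispersion ``theta`` in ``[0, 1)``:

    P(X = x | pi, theta) =
        (N! / prod_j x_j!) *
        prod_j prod_{r=1..x_j} {pi_j (1-theta) + (r-1) theta}
        / prod_{r=1..N} {(1-theta) + (r-1) theta}

``theta = 0`` recovers the plain multinomial; larger ``theta`` inflates
between-sample variability, which is the typical situation for real
microbiome count data sequenced at a common read depth.

Parameters are estimated by the method of moments (MoM): ``pi`` as pooled
proportions and ``theta`` by the weighted moment estimator that equates
between-sample and within-sample variance components.  The group
log-likelihood and the log-likelihood-ratio (LLR) homogeneity score built
from it are the splitting machinery of the recursive-partitioning engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "THETA_MAX",
    "DMParams",
    "TaxaCountMatrix",
    "dm_log_pmf",
    "estimate_mom",
    "group_log_likelihood",
    "llr_statistic",
]

#: theta is clamped into [0, THETA_MAX] so the pmf stays well defined.
THETA_MAX = 1.0 - 1e-9


@dataclass(frozen=True)
class DMParams:
    """Fitted (or true) Dirichlet-multinomial parameters.

    Attributes
    ----------
    pi
        Expected taxa proportions, length ``J``; entries in [0, 1] summing
        to 1 (tolerance 1e-9).
    theta
        Overdispersion in ``[0, 1)``; 0 means plain multinomial.
    """

    pi: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.ndim != 1:
            raise ValueError("pi must be a 1-D vector")
        if np.any(pi < -1e-12) or np.any(pi > 1 + 1e-12):
            raise ValueError("pi entries must lie in [0, 1]")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi must sum to 1 (got {pi.sum()!r})")
        if not (0.0 <= self.theta <= THETA_MAX):
            raise ValueError(f"theta must lie in [0, 1) (got {self.theta!r})")

    @property
    def n_taxa(self) -> int:
        return self.pi.shape[0]


@dataclass
class TaxaCountMatrix:
    """Samples x taxa matrix of non-negative integer read counts.

    ``counts[i, j]`` is the number of reads of taxon ``j`` in sample ``i``;
    row totals are the per-sample read depths.  All-zero sample rows are
    rejected (a sample with no reads carries no compositional information
    and would break frequency normalization).
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        if counts.shape[1] < 2:
            raise ValueError("at least two taxa are required")
        if np.any(~np.isfinite(counts.astype(float))):
            raise ValueError("counts must be finite")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        as_int = counts.astype(np.int64)
        if np.any(as_int.astype(counts.dtype) != counts):
            raise ValueError("counts must be integers")
        self.counts = as_int
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(as_int.shape[0])]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if self.taxon_ids is None:
            self.taxon_ids = [f"T{j + 1}" for j in range(as_int.shape[1])]
        else:
            self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != as_int.shape[0]:
            raise ValueError("sample_ids length does not match counts")
        if len(self.taxon_ids) != as_int.shape[1]:
            raise ValueError("taxon_ids length does not match counts")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        totals = as_int.sum(axis=1)
        if np.any(totals == 0):
            bad = [self.sample_ids[i] for i in np.nonzero(totals == 0)[0][:5]]
            raise ValueError(f"all-zero sample rows are not allowed: {bad}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Reads per sample, ``N_i = sum_j x_ij`` (computed, never stored)."""
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-sample taxa frequencies ``x_ij / N_i``."""
        return self.counts / self.row_totals[:, None]

    def subset(self, indices: Sequence[int]) -> "TaxaCountMatrix":
        idx = np.asarray(indices, dtype=int)
        return TaxaCountMatrix(
            self.counts[idx],
            [self.sample_ids[i] for i in idx],
            list(self.taxon_ids),
        )


# ---------------------------------------------------------------------------
# log-pmf and likelihood
# ---------------------------------------------------------------------------

def _loglik_rows(counts: np.ndarray, pi: np.ndarray, theta: float) -> np.ndarray:
    """Per-row DM log-likelihood WITHOUT the multinomial coefficient.

    Uses the log-gamma identity
    ``sum_{r=1..x} log(a + (r-1)t) = x log t + lgamma(a/t + x) - lgamma(a/t)``
    so the cost is independent of the read depth; the ``x log t`` terms of
    numerator and denominator cancel exactly and are dropped.
    Rows with positive counts on a zero-probability taxon get ``-inf``.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    totals = X.sum(axis=1)
    pos = pi > 0.0
    impossible = (X[:, ~pos] > 0).any(axis=1) if (~pos).any() else np.zeros(X.shape[0], bool)
    if theta == 0.0:
        with np.errstate(divide="ignore"):
            logpi = np.log(pi[pos])
        ll = X[:, pos] @ logpi
    else:
        a = pi[pos] * (1.0 - theta) / theta
        b = (1.0 - theta) / theta
        ll = (gammaln(a[None, :] + X[:, pos]) - gammaln(a)[None, :]).sum(axis=1)
        ll -= gammaln(b + totals) - gammaln(b)
    ll = np.where(impossible, -np.inf, ll)
    return ll


def _log_multinomial_coef(counts: np.ndarray) -> np.ndarray:
    X = np.asarray(counts, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return gammaln(X.sum(axis=1) + 1.0) - gammaln(X + 1.0).sum(axis=1)


def dm_log_pmf(sample_counts: Sequence[int], params: DMParams,
               include_coefficient: bool = True) -> float:
    """Log probability of one count vector under DM(pi, theta).

    Parameters
    ----------
    sample_counts
        Non-negative integer counts, length ``J`` (J >= 1).
    params
        DM parameters dimensioned to the counts.
    include_coefficient
        Whether to add the log multinomial coefficient.  It does not depend
        on the parameters and cancels in every likelihood ratio.

    Returns
    -------
    float
        ``log P(X = x | pi, theta)``; ``-inf`` when a taxon with
        ``pi_j = 0`` has positive counts.
    """
    x = np.asarray(sample_counts)
    if x.ndim != 1:
        raise ValueError("sample_counts must be a vector")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if x.shape[0] != params.n_taxa:
        raise ValueError("counts length does not match params")
    ll = float(_loglik_rows(x[None, :], params.pi, params.theta)[0])
    if include_coefficient:
        ll += float(_log_multinomial_coef(x[None, :])[0])
    return ll


# ---------------------------------------------------------------------------
# method-of-moments estimation
# ---------------------------------------------------------------------------

def _mom_from_counts(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Pooled-proportion pi-hat and weighted-moment theta-hat from raw counts.

    theta-hat equates between-sample (S_j) and within-sample (G_j) variance
    components, weighted by read depth:

        S_j = 1/(N-1) * sum_i N_i (p_ij - pi_j)^2
        G_j = 1/sum_i(N_i - 1) * sum_i N_i p_ij (1 - p_ij)
        n_c = (sum_i N_i - sum_i N_i^2 / sum_i N_i) / (N - 1)
        theta = sum_j (S_j - G_j) / sum_j (S_j + (n_c - 1) G_j)

    Negative estimates (under-dispersion) clamp to 0; estimates >= 1 clamp
    to just below 1 so the pmf stays proper.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot estimate parameters from an empty group")
    totals = X.sum(axis=1)
    grand = totals.sum()
    pi = X.sum(axis=0) / grand
    if n == 1 or grand == n:  # single sample, or one read per sample
        return pi, 0.0
    P = X / totals[:, None]
    S = (totals[:, None] * (P - pi[None, :]) ** 2).sum(axis=0) / (n - 1)
    G = (totals[:, None] * P * (1.0 - P)).sum(axis=0) / (grand - n)
    n_c = (grand - (totals ** 2).sum() / grand) / (n - 1)
    denom = (S + (n_c - 1.0) * G).sum()
    if denom <= 0:
        return pi, 0.0
    theta = (S - G).sum() / denom
    return pi, float(np.clip(theta, 0.0, THETA_MAX))


def estimate_mom(group: TaxaCountMatrix) -> DMParams:
    """Method-of-moments fit of (pi, theta) to a group of samples.

    A single-sample group has no between-sample variance and yields
    ``theta = 0``.
    """
    pi, theta = _mom_from_counts(group.counts)
    return DMParams(pi=pi, theta=theta)


def group_log_likelihood(group: TaxaCountMatrix, params: DMParams,
                         include_coefficient: bool = False) -> float:
    """Sum of per-sample DM log-pmfs over a group (0 for an empty group).

    The multinomial coefficients are excluded by default: they are
    parameter-free and cancel exactly in every log-likelihood ratio.
    """
    if group.n_taxa != params.n_taxa:
        raise ValueError("group and params have different numbers of taxa")
    if group.n_samples == 0:
        return 0.0
    ll = float(_loglik_rows(group.counts, params.pi, params.theta).sum())
    if include_coefficient:
        ll += float(_log_multinomial_coef(group.counts).sum())
    return ll


def llr_statistic(parent: TaxaCountMatrix, left: TaxaCountMatrix,
                  right: TaxaCountMatrix) -> float:
    """Log-likelihood-ratio homogeneity score of a two-way split.

    Fits MoM parameters separately to the parent and to each child and
    returns ``LL0 - (LL1 + LL2)``.  Values near 0 mean the children look
    like one DM population; the farther from 0 (the split criterion uses
    ``|LLR|``) the stronger the evidence for two distinct populations.

    Raises if left and right are not a disjoint, complete partition of the
    parent (checked by sample id).
    """
    ids_l, ids_r = set(left.sample_ids), set(right.sample_ids)
    if ids_l & ids_r:
        raise ValueError("left and right children overlap")
    if ids_l | ids_r != set(parent.sample_ids):
        raise ValueError("children do not partition the parent")
    ll0 = group_log_likelihood(parent, estimate_mom(parent))
    ll1 = group_log_likelihood(left, estimate_mom(left))
    ll2 = group_log_likelihood(right, estimate_mom(right))
    return ll0 - (ll1 + ll2)
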