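"""Dirichlet-multinomial simulator and factorial simulation study.

The generator emulates a multi-group body-site style design: each group g
has its own expected composition ``pi_g``, all groups share an
overdispersion ``theta`` and a fixed read depth, and every sample carries
one normally distributed covariate whose mean differs by group (-1, 0, 1
by default) with a shared standard deviation controlling how much the
groups overlap in covariate space.  Group labels are returned for
evaluation only; they are never available to the tree fit.

Sampling follows the standard compounding: draw
``p ~ Dirichlet(pi * (1 - theta) / theta)`` and then
``counts ~ Multinomial(reads, p)``; ``theta = 0`` short-circuits to the
plain multinomial.

The evaluation metric of the study is the terminal-node MSE: the average
over terminal nodes of the mean squared Euclidean distance between member
sample frequency vectors and the node's fitted composition pi-hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dm_model import DMParams, TaxaCountMatrix
from .prune_cv import CVConfig, fit as _fit
from .tree_engine import CovariateTable, FitConfig, Tree

__all__ = [
    "SimDesign",
    "sample_dm",
    "simulate_dataset",
    "node_mse",
    "run_simulation_study",
    "body_site_profiles",
]


def body_site_profiles(n_taxa: int = 20, decay: float = 0.25) -> list[np.ndarray]:
    """Three synthetic J-taxon composition presets for the study driver.

    A log-linear abundance decay ``pi_j ~ exp(-decay * j)`` and two fixed
    rearrangements of it (a cyclic shift and a reversal), giving three
    clearly distinct compositions reminiscent of distinct body-site
    communities.  Deterministic; no randomness involved.
    """
    base = np.exp(-decay * np.arange(n_taxa))
    base /= base.sum()
    return [base, np.roll(base, n_taxa // 3), base[::-1].copy()]


@dataclass
class SimDesign:
    """One cell of the factorial simulation design.

    ``groups`` is a list of (pi, covariate mean, group size) triples;
    ``theta`` and the covariate SD are shared across groups within a
    replicate, and every sample is sequenced to the same read depth.
    """

    groups: list[tuple[np.ndarray, float, int]]
    theta: float = 0.08
    reads: int = 50_000
    covariate_sd: float = 0.2
    covariate_name: str = "c1"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        for pi, _, size in self.groups:
            DMParams(pi=np.asarray(pi, float), theta=self.theta)  # validates
            if size < 1:
                raise ValueError("group sizes must be >= 1")
        if self.covariate_sd <= 0:
            raise ValueError("covariate SD must be > 0")
        if self.reads < 1:
            raise ValueError("reads must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(size for _, _, size in self.groups)


def sample_dm(params: DMParams, n_samples: int, reads: int,
              rng: np.random.Generator) -> TaxaCountMatrix:
    """Draw DM-distributed count vectors, each summing to ``reads``.

    Taxa with ``pi_j = 0`` receive Dirichlet mass 0 and stay at zero
    counts.  ``theta = 0`` draws straight from Multinomial(reads, pi).
    """
    if reads < 1:
        raise ValueError("reads must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    pi, theta = params.pi, params.theta
    J = pi.shape[0]
    if theta == 0.0:
        counts = rng.multinomial(reads, pi, size=n_samples)
    else:
        alpha = pi * (1.0 - theta) / theta
        pos = alpha > 0
        p = np.zeros((n_samples, J))
        p[:, pos] = rng.dirichlet(alpha[pos], size=n_samples)
        counts = np.vstack([rng.multinomial(reads, p[i]) for i in range(n_samples)])
    return TaxaCountMatrix(counts)


def simulate_dataset(design: SimDesign, rng: np.random.Generator
                     ) -> tuple[TaxaCountMatrix, CovariateTable, np.ndarray]:
    """One replicate dataset: counts, one-covariate table, true group labels.

    Stream order is fixed (per group: covariates first, then counts) so a
    seeded generator reproduces the dataset bit for bit.
    """
    blocks, covs, labels = [], [], []
    for g, (pi, mean, size) in enumerate(design.groups):
        covs.append(rng.normal(mean, design.covariate_sd, size=size))
        pars = DMParams(pi=np.asarray(pi, float), theta=design.theta)
        blocks.append(sample_dm(pars, size, design.reads, rng).counts)
        labels.extend([g] * size)
    counts = TaxaCountMatrix(np.vstack(blocks))
    table = CovariateTable(np.concatenate(covs)[:, None],
                           [design.covariate_name],
                           sample_ids=counts.sample_ids)
    return counts, table, np.asarray(labels)


def node_mse(tree: Tree, outcome: TaxaCountMatrix,
             covariates: Optional[CovariateTable] = None) -> float:
    """Average over terminal nodes of the mean member-to-pi-hat squared distance.

    With ``covariates`` given, samples are routed through the tree (for
    held-out data); otherwise the training membership stored in the tree
    is used.  Terminal nodes that receive no samples are excluded with a
    warning.
    """
    if tree.mode != "dm":
        raise ValueError("node_mse is defined for dm-mode trees")
    freqs = outcome.frequencies
    if covariates is None:
        groups = {leaf.node_id: leaf.members for leaf in tree.leaves()}
    else:
        groups = {leaf.node_id: [] for leaf in tree.leaves()}
        for i in range(covariates.n_samples):
            row = dict(zip(covariates.covariate_names, covariates.values[i]))
            groups[tree.predict_node(row)].append(i)
    per_node = []
    for leaf in tree.leaves():
        idx = np.asarray(groups[leaf.node_id], dtype=int)
        if idx.size == 0:
            warnings.warn(f"terminal node {leaf.node_id} received no samples; "
                          "excluded from node MSE")
            continue
        per_node.append(float(((freqs[idx] - leaf.params.pi[None, :]) ** 2)
                              .sum(axis=1).mean()))
    return float(np.mean(per_node))


def run_simulation_study(
    group_sizes: Sequence[int] = (40, 80, 120),
    thetas: Sequence[float] = (0.08, 0.2, 0.6),
    sds: Sequence[float] = (0.2, 0.35, 0.5),
    pis: Optional[Sequence[np.ndarray]] = None,
    replicates: int = 20,
    reads: int = 50_000,
    seed: Optional[int] = None,
    fit_config: Optional[FitConfig] = None,
    cv_repetitions: int = 3,
    cv_folds: int = 10,
    rule: str = "min_cv",
) -> pd.DataFrame:
    """Factorial study: simulate, fit, CV-prune, score node MSE per cell.

    The grid crosses per-group sample size x theta x covariate SD; every
    cell is replicated and the mean selected-tree node MSE is reported.
    Common random numbers are used across cells (replicate r shares its
    seed stream in every cell) to sharpen between-cell comparisons.

    Returns a tidy DataFrame with one row per cell:
    ``group_size, total_n, theta, sd, mean_node_mse, mean_leaves``.
    """
    pis = list(pis) if pis is not None else body_site_profiles()
    means = [-1.0 + i * (2.0 / max(1, len(pis) - 1)) for i in range(len(pis))]
    root_seq = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 root_seq.spawn(replicates)]
    rows = []
    for size, theta, sd in product(group_sizes, thetas, sds):
        design = SimDesign(
            groups=[(pi, mu, size) for pi, mu in zip(pis, means)],
            theta=theta, reads=reads, covariate_sd=sd,
        )
        mses, leaves = [], []
        for r in range(replicates):
            rng = np.random.default_rng(rep_seeds[r])  # CRN across cells
            counts, cov, _ = simulate_dataset(design, rng)
            cv_seed = int(rng.integers(2 ** 31))
            res = _fit(counts, cov, fit_config,
                       CVConfig(folds=cv_folds, repetitions=cv_repetitions,
                                seed=cv_seed, rule=rule))
            mses.append(node_mse(res.selected, counts))
            leaves.append(res.selected.n_leaves)
        rows.append({
            "group_size": size, "total_n": design.n_samples, "theta": theta,
            "sd": sd, "mean_node_mse": float(np.mean(mses)),
            "mean_leaves": float(np.mean(leaves)),
        })
    return pd.DataFrame(rows)


def study_pivot(tidy: pd.DataFrame) -> pd.DataFrame:
    """Reshape a tidy study table to total-N rows x (SD, theta) columns."""
    return tidy.pivot_table(index="total_n", columns=["sd", "theta"],
                            values="mean_node_mse")
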