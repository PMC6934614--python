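"""Cost-complexity pruning, the CP table, and repeated cross-validation.

The penalized fit of a subtree T is

    C_alpha(T) = sum_{terminal n} S_n(T) + alpha * |T|

with S_n the node score (classification: misclassification count; DM
mode: node deviance, minus the node's DM log-likelihood) and |T| the
number of terminal nodes.  Weakest-link pruning repeatedly collapses the
internal node whose branch removal raises training error least per leaf
removed, producing the unique nested sequence T_Full > ... > T_Root with
its critical alpha values.  Alphas are reported in relative-error units
(divided by the root node's error), matching the CP-table convention in
which the row for subtree T_k carries the alpha at which the next larger
tree collapses into T_k and the full tree carries alpha = 0.

The right-sized tree is chosen by repeated 10-fold cross-validation: the
full tree's alpha levels are applied to each fold's refitted tree, fold
scores are the mean squared Euclidean distance between held-out sample
frequency vectors and the pi-hat of the terminal node they route to (the
PRESS statistic; classification mode substitutes the misclassification
rate), and fold means are averaged over folds and then over repetitions.
Selection is by minimum mean CV error or by the 1-SE rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dm_model import TaxaCountMatrix
from .tree_engine import CovariateTable, FitConfig, Outcome, Tree, grow_full_tree

__all__ = [
    "CPTableRow",
    "CVConfig",
    "CVResult",
    "cost_complexity_alpha",
    "prune_sequence",
    "prune_at_alpha",
    "relative_error",
    "cross_validate",
    "select_right_sized_tree",
    "fit",
    "FitResult",
]

_TOL = 1e-12


@dataclass(frozen=True)
class CPTableRow:
    """One row of the complexity table (one subtree of the sequence)."""

    tree_complexity: int       # |T|, number of terminal nodes
    alpha: float               # critical cost-complexity value, relative units
    n_splits: int              # |T| - 1
    relative_error: float      # resubstitution error / root error
    cv_error: float            # mean CV error over repetitions
    cv_error_se: float         # SE of the repetition means


@dataclass
class CVConfig:
    """Repeated k-fold cross-validation settings."""

    folds: int = 10
    repetitions: int = 100
    seed: Optional[int] = None
    rule: str = "min_cv"       # "min_cv" | "one_se"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.rule not in ("min_cv", "one_se"):
            raise ValueError(f"unknown selection rule {self.rule!r}")


def cost_complexity_alpha(re_small: float, re_large: float,
                          size_small: int, size_large: int) -> float:
    """Critical alpha collapsing the larger of two nested subtrees.

    The difference of the relative errors divided by the reduction in the
    number of terminal nodes, e.g. (0.371 - 0.286) / (5 - 3).
    """
    if size_large <= size_small:
        raise ValueError("size_large must exceed size_small")
    return (re_small - re_large) / (size_large - size_small)


# ---------------------------------------------------------------------------
# weakest-link pruning
# ---------------------------------------------------------------------------

def _root_error(tree: Tree) -> float:
    return float(tree.root.error)


def _branch_stats(node) -> tuple[float, int]:
    """(sum of leaf errors, number of leaves) of the branch under a node."""
    if node.is_leaf:
        return node.error, 1
    le, ln = _branch_stats(node.left)
    re_, rn = _branch_stats(node.right)
    return le + re_, ln + rn


def _weakest_links(tree: Tree) -> tuple[float, list[int]]:
    """Minimum g(t) over internal nodes and the ids attaining it."""
    gmin, ids = np.inf, []
    for nd in tree.internal_nodes():
        br_err, br_leaves = _branch_stats(nd)
        g = (nd.error - br_err) / (br_leaves - 1)
        if g < gmin - _TOL:
            gmin, ids = g, [nd.node_id]
        elif g <= gmin + _TOL:
            ids.append(nd.node_id)
    return float(gmin), ids


def _collapse(tree: Tree, node_ids: Sequence[int]) -> None:
    wanted = set(node_ids)
    for nd in tree.iter_nodes():
        if nd.node_id in wanted and not nd.is_leaf:
            nd.split = None
            nd.left = None
            nd.right = None


def prune_sequence(full_tree: Tree) -> list[tuple[float, Tree]]:
    """Nested weakest-link subtree sequence with critical alphas.

    Returns ``[(alpha, subtree), ...]`` ordered by increasing complexity
    (root first).  The alpha attached to a subtree is the weakest-link
    value at which the next larger member collapses into it; the full tree
    has alpha 0.  Alphas are in relative-error units (g / root error) and
    are non-increasing as complexity grows.
    """
    r0 = _root_error(full_tree)
    if r0 <= 0:
        warnings.warn("root node has zero error; relative errors are degenerate")
        r0 = 1.0
    seq: list[tuple[float, Tree]] = [(0.0, full_tree.copy())]
    current = full_tree.copy()
    while current.n_leaves > 1:
        g, ids = _weakest_links(current)
        _collapse(current, ids)
        seq.append((max(g, 0.0) / r0, current.copy()))
    seq.reverse()   # root first, alpha non-increasing with complexity
    return seq


def prune_at_alpha(full_tree: Tree, alpha: float) -> Tree:
    """Smallest subtree minimizing C_alpha (weak inequality -> smaller tree).

    ``alpha`` is on the relative-error scale of the tree's own root.
    """
    r0 = _root_error(full_tree)
    if r0 <= 0:
        r0 = 1.0
    current = full_tree.copy()
    while current.n_leaves > 1:
        g, ids = _weakest_links(current)
        if g / r0 > alpha + _TOL:
            break
        _collapse(current, ids)
    return current


def relative_error(full_tree: Tree, subtree: Optional[Tree] = None) -> float:
    """Resubstitution error of a subtree relative to the unsplit root.

    Classification mode: misclassification-count ratio.  DM mode: the
    deviance ratio D(T)/D(root) with D(T) = -sum of terminal-node
    log-likelihoods.  The root row is exactly 1.
    """
    sub = subtree if subtree is not None else full_tree
    r0 = _root_error(full_tree)
    if r0 <= 0:
        warnings.warn("root node has zero error; relative error defined as 0")
        return 0.0
    return sub.resubstitution_error() / r0


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_assignments(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random near-equal-size fold labels 0..folds-1 for n samples."""
    labels = np.arange(n) % folds
    return labels[rng.permutation(n)]


def _subset_outcome(outcome: Outcome, idx: np.ndarray) -> Outcome:
    if isinstance(outcome, TaxaCountMatrix):
        return outcome.subset(idx)
    return outcome[idx]


def _subset_covariates(cov: CovariateTable, idx: np.ndarray) -> CovariateTable:
    return CovariateTable(
        cov.values[idx], list(cov.covariate_names),
        None if cov.sample_ids is None else [cov.sample_ids[i] for i in idx],
    )


def _score_heldout(tree: Tree, outcome: Outcome, cov: CovariateTable,
                   idx: np.ndarray) -> float:
    """Mean held-out score: squared distance to pi-hat (DM) or error rate."""
    rows = (dict(zip(cov.covariate_names, cov.values[i])) for i in idx)
    if tree.mode == "dm":
        freqs = outcome.frequencies[idx]
        d = [float(((freqs[k] - tree.predict_composition(row)) ** 2).sum())
             for k, row in enumerate(rows)]
        return float(np.mean(d))
    labels = outcome[idx]
    pred = np.array([tree.predict_class(row) for row in rows])
    return float(np.mean(pred != labels))


@dataclass
class CVResult:
    full_tree: Tree
    sequence: list[tuple[float, Tree]]    # root-first, as prune_sequence
    cp_table: list[CPTableRow]
    rep_errors: np.ndarray                # repetitions x sequence rows
    config: CVConfig

    def cp_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.cp_table])


def cross_validate(outcome: Outcome, covariates: CovariateTable,
                   fit_config: Optional[FitConfig] = None,
                   cv_config: Optional[CVConfig] = None,
                   full_tree: Optional[Tree] = None) -> CVResult:
    """Repeated k-fold CV over the full tree's pruning sequence.

    Implements the procedure: fit the full tree on all data and derive its
    alpha levels; per repetition, randomly partition into folds; per fold,
    refit the full tree on the remaining data, prune it at each alpha
    level, route held-out samples, and score them against the terminal
    pi-hat of the fold fit; average scores over folds, then over
    repetitions.
    """
    fit_config = fit_config or FitConfig()
    cv_config = cv_config or CVConfig()
    if isinstance(outcome, TaxaCountMatrix):
        n = outcome.n_samples
    else:
        outcome = np.asarray(outcome)
        n = outcome.shape[0]
    if n < 2 * cv_config.folds:
        raise ValueError("need at least 2 samples per fold")

    if full_tree is None:
        full_tree = grow_full_tree(outcome, covariates, fit_config)
    seq = prune_sequence(full_tree)
    alphas = [a for a, _ in seq]

    rng = np.random.default_rng(cv_config.seed)
    rep_errors = np.zeros((cv_config.repetitions, len(seq)))
    for m in range(cv_config.repetitions):
        assign = _fold_assignments(n, cv_config.folds, rng)
        fold_scores = np.zeros((cv_config.folds, len(seq)))
        for f in range(cv_config.folds):
            test_idx = np.nonzero(assign == f)[0]
            train_idx = np.nonzero(assign != f)[0]
            t_out = _subset_outcome(outcome, train_idx)
            t_cov = _subset_covariates(covariates, train_idx)
            fold_tree = grow_full_tree(t_out, t_cov, fit_config)
            for k, a in enumerate(alphas):
                pruned = prune_at_alpha(fold_tree, a)
                fold_scores[f, k] = _score_heldout(pruned, outcome,
                                                   covariates, test_idx)
        rep_errors[m] = fold_scores.mean(axis=0)

    cv_mean = rep_errors.mean(axis=0)
    if cv_config.repetitions > 1:
        cv_se = rep_errors.std(axis=0, ddof=1) / np.sqrt(cv_config.repetitions)
    else:
        cv_se = np.zeros(len(seq))

    # classification CV errors are reported relative to the root
    # resubstitution rate (Table-5 convention); DM errors stay absolute.
    scale = 1.0
    if full_tree.mode == "gini":
        root_rate = _root_error(full_tree) / n
        if root_rate > 0:
            scale = 1.0 / root_rate
    table = [
        CPTableRow(
            tree_complexity=t.n_leaves, alpha=a, n_splits=t.n_splits,
            relative_error=relative_error(full_tree, t),
            cv_error=cv_mean[k] * scale, cv_error_se=cv_se[k] * scale,
        )
        for k, (a, t) in enumerate(seq)
    ]
    return CVResult(full_tree=full_tree, sequence=seq, cp_table=table,
                    rep_errors=rep_errors, config=cv_config)


def select_right_sized_tree(cp_table: Sequence[CPTableRow],
                            sequence: Sequence[tuple[float, Tree]],
                            rule: str = "min_cv") -> Tree:
    """Pick the right-sized tree from a CP table.

    ``min_cv`` returns the subtree with the smallest mean CV error (ties
    go to the smaller tree); ``one_se`` returns the simplest subtree whose
    CV error is within one standard error of that minimum.  Either may be
    the root, reported downstream as "no split".
    """
    if len(cp_table) != len(sequence):
        raise ValueError("cp_table and sequence are not aligned")
    errors = np.array([r.cv_error for r in cp_table])
    k0 = int(np.argmin(errors))        # first min -> smallest |T| on ties
    if rule == "min_cv":
        return sequence[k0][1]
    if rule == "one_se":
        thr = errors[k0] + cp_table[k0].cv_error_se
        for k, r in enumerate(cp_table):
            if r.cv_error <= thr:
                return sequence[k][1]
        return sequence[k0][1]
    raise ValueError(f"unknown selection rule {rule!r}")


@dataclass
class FitResult:
    """End-to-end fit: full tree, CP table, and the selected subtree."""

    full_tree: Tree
    cv: CVResult
    selected: Tree

    @property
    def no_split(self) -> bool:
        return self.selected.n_leaves == 1


def fit(outcome: Outcome, covariates: CovariateTable,
        fit_config: Optional[FitConfig] = None,
        cv_config: Optional[CVConfig] = None) -> FitResult:
    """Grow, cross-validate, and select the right-sized tree in one call."""
    cv_config = cv_config or CVConfig()
    cv = cross_validate(outcome, covariates, fit_config, cv_config)
    selected = select_right_sized_tree(cv.cp_table, cv.sequence, cv_config.rule)
    return FitResult(full_tree=cv.full_tree, cv=cv, selected=selected)
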