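"""Binary recursive partitioning with pluggable split criteria.

Two outcome modes share one engine:

* ``"dm"`` — the outcome is a samples x taxa count matrix; a candidate
  split is scored by the absolute Dirichlet-multinomial log-likelihood
  ratio |LLR| between the parent fit and the two child fits, each fitted
  by the method of moments.  The split with the largest |LLR| wins.
* ``"gini"`` — the outcome is a vector of class labels; splits are scored
  by the weighted Gini impurity decrease (the classical CART criterion for
  categorical outcomes).

Cut points are the midpoints between adjacent distinct observed values of
a covariate within the node; cuts leaving fewer than ``min_bucket``
samples on either side are not considered.  Routing convention: a sample
goes left iff ``value <= cut``.  Rows missing a covariate are excluded
from that covariate's evaluation and, once a split is chosen, follow the
child with more (non-missing) training samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln

from .dm_model import (
    THETA_MAX,
    DMParams,
    TaxaCountMatrix,
    _loglik_rows,
    _mom_from_counts,
)

__all__ = [
    "CovariateTable",
    "SplitRule",
    "TreeNode",
    "Tree",
    "FitConfig",
    "enumerate_cutpoints",
    "best_split",
    "grow_full_tree",
    "predict_node",
    "predict_composition",
]

_SCORE_TOL = 1e-9     # minimum improvement for a split to count
_CHUNK_ELEMS = 4_000_000  # cap on (cuts x samples x taxa) tensor elements


@dataclass
class CovariateTable:
    """Samples x covariates table aligned with the outcome's samples.

    Continuous and binary (0/1-encoded) covariates only; missing values
    are NaN.  Alignment with the outcome is positional and is checked by
    sample id when ids are provided.
    """

    values: np.ndarray
    covariate_names: list[str]
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        self.values = v
        self.covariate_names = [str(c) for c in self.covariate_names]
        if len(self.covariate_names) != v.shape[1]:
            raise ValueError("covariate_names length does not match values")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("duplicate covariate names")
        if self.sample_ids is not None:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != v.shape[0]:
                raise ValueError("sample_ids length does not match values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.covariate_names.index(name)]


@dataclass(frozen=True)
class SplitRule:
    """``value <= cut_point`` goes to the left child."""

    covariate_name: str
    cut_point: float


@dataclass
class TreeNode:
    node_id: int                      # heap numbering: root 1, children 2k, 2k+1
    members: np.ndarray               # training sample indices
    depth: int = 0
    # node summary -- DM mode
    params: Optional[DMParams] = None
    # node summary -- classification mode
    class_counts: Optional[np.ndarray] = None
    majority_class: Optional[int] = None
    # node score S_n in error units (DM: deviance -LL; gini: misclass count)
    error: float = 0.0
    split: Optional[SplitRule] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    missing_to: str = "left"          # routing for rows missing the split covariate

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def copy(self) -> "TreeNode":
        node = TreeNode(
            node_id=self.node_id, members=self.members, depth=self.depth,
            params=self.params, class_counts=self.class_counts,
            majority_class=self.majority_class, error=self.error,
            split=self.split, missing_to=self.missing_to,
        )
        if self.left is not None:
            node.left = self.left.copy()
        if self.right is not None:
            node.right = self.right.copy()
        return node


@dataclass
class FitConfig:
    """Growth controls for the full tree.

    ``min_split`` is the smallest node eligible for splitting, ``min_bucket``
    the smallest admissible child; ``min_split >= 2 * min_bucket`` is
    enforced so an eligible node can actually be split.
    """

    min_split: int = 10
    min_bucket: int = 5
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_bucket < 1:
            raise ValueError("min_bucket must be >= 1")
        if self.min_split < 2 * self.min_bucket:
            raise ValueError("min_split must be >= 2 * min_bucket")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


@dataclass
class Tree:
    """Fitted binary partitioning tree."""

    root: TreeNode
    mode: str                        # "dm" | "gini"
    config: FitConfig
    covariate_names: list[str]
    n_samples: int
    taxon_ids: Optional[list[str]] = None
    class_labels: Optional[list[int]] = None

    def leaves(self) -> list[TreeNode]:
        return [nd for nd in self.iter_nodes() if nd.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [nd for nd in self.iter_nodes() if not nd.is_leaf]

    def iter_nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            if not nd.is_leaf:
                stack.extend((nd.right, nd.left))

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_splits(self) -> int:
        return self.n_leaves - 1

    def node(self, node_id: int) -> TreeNode:
        for nd in self.iter_nodes():
            if nd.node_id == node_id:
                return nd
        raise KeyError(f"no node with id {node_id}")

    def resubstitution_error(self) -> float:
        """Sum of terminal-node scores S_n (deviance or misclass count)."""
        return float(sum(nd.error for nd in self.leaves()))

    def copy(self) -> "Tree":
        return Tree(
            root=self.root.copy(), mode=self.mode, config=self.config,
            covariate_names=list(self.covariate_names),
            n_samples=self.n_samples,
            taxon_ids=None if self.taxon_ids is None else list(self.taxon_ids),
            class_labels=None if self.class_labels is None else list(self.class_labels),
        )

    # ---- prediction -----------------------------------------------------

    def _route(self, row: Mapping[str, float]) -> TreeNode:
        nd = self.root
        while not nd.is_leaf:
            name = nd.split.covariate_name
            if name not in row:
                raise KeyError(f"covariate {name!r} required for routing is absent")
            v = row[name]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                nd = nd.left if nd.missing_to == "left" else nd.right
            elif v <= nd.split.cut_point:
                nd = nd.left
            else:
                nd = nd.right
        return nd

    def predict_node(self, row: Mapping[str, float]) -> int:
        """Terminal node id a covariate row is routed to."""
        return self._route(row).node_id

    def predict_composition(self, row: Mapping[str, float]) -> np.ndarray:
        """Fitted taxa proportions pi-hat of the routed terminal node."""
        if self.mode != "dm":
            raise ValueError("predict_composition requires a dm-mode tree; "
                             "use predict_class_distribution for classification")
        return self._route(row).params.pi

    def predict_class_distribution(self, row: Mapping[str, float]) -> np.ndarray:
        if self.mode != "gini":
            raise ValueError("class distributions exist only for gini-mode trees")
        counts = self._route(row).class_counts
        return counts / counts.sum()

    def predict_class(self, row: Mapping[str, float]) -> int:
        if self.mode != "gini":
            raise ValueError("class prediction requires a gini-mode tree")
        return self.class_labels[self._route(row).majority_class]

    def rows(self, covariates: CovariateTable) -> Iterator[dict]:
        for i in range(covariates.n_samples):
            yield dict(zip(covariates.covariate_names, covariates.values[i]))


Outcome = Union[TaxaCountMatrix, np.ndarray]


# ---------------------------------------------------------------------------
# cut point enumeration
# ---------------------------------------------------------------------------

def enumerate_cutpoints(values: Sequence[float], min_bucket: int = 1,
                        covariate_name: str = "x") -> list[SplitRule]:
    """Candidate splits for one covariate within a node.

    Midpoints between adjacent distinct sorted values, dropping any cut
    that would leave fewer than ``min_bucket`` samples on either side.
    NaN values are ignored (they do not participate in the evaluation).
    """
    if min_bucket < 1:
        raise ValueError("min_bucket must be >= 1")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    cuts, _ = _cut_positions(np.sort(v), min_bucket)
    return [SplitRule(covariate_name, float(c)) for c in cuts]


def _cut_positions(sorted_values: np.ndarray, min_bucket: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint cuts and left-group sizes for an ascending value vector."""
    n = sorted_values.shape[0]
    if n < 2 * min_bucket:
        return np.empty(0), np.empty(0, dtype=int)
    change = np.nonzero(np.diff(sorted_values) > 0)[0]   # left size = idx + 1
    ks = change + 1
    keep = (ks >= min_bucket) & (n - ks >= min_bucket)
    ks = ks[keep]
    cuts = (sorted_values[ks - 1] + sorted_values[ks]) / 2.0
    return cuts, ks


# ---------------------------------------------------------------------------
# vectorized split scans
# ---------------------------------------------------------------------------

def _gini_scan(labels: np.ndarray, n_classes: int, ks: np.ndarray) -> np.ndarray:
    """Gini impurity decrease for every candidate left size in ``ks``.

    ``labels`` must already be sorted by the covariate.  Scores are the
    weighted decrease n*G(parent) - (nL*G(L) + nR*G(R)) with
    G = 1 - sum_c p_c^2.
    """
    n = labels.shape[0]
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), labels] = 1.0
    pref = np.cumsum(onehot, axis=0)
    tot = pref[-1]
    left = pref[ks - 1]
    right = tot[None, :] - left
    nl = ks.astype(float)
    nr = n - nl

    def wgini(cnt: np.ndarray, m: np.ndarray) -> np.ndarray:
        return m - (cnt ** 2).sum(axis=1) / m

    parent = n - (tot ** 2).sum() / n
    return parent - wgini(left, nl) - wgini(right, nr)


def _mom_prefix(Xs: np.ndarray, ks: np.ndarray, from_right: bool
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MoM (pi, theta) of the left (or right) groups at each cut.

    ``Xs`` is the node's count matrix sorted by the covariate; ``ks`` are
    left-group sizes.  Returns (pi (K,J), theta (K,), n_members (K,)).
    """
    n = Xs.shape[0]
    totals = Xs.sum(axis=1).astype(float)
    P = Xs / totals[:, None]
    stats = {
        "x": Xs.astype(float),
        "N": totals[:, None],
        "N2": (totals ** 2)[:, None],
        "Np2": Xs * P,                      # N_i p^2 = x^2 / N
        "Npq": Xs * (1.0 - P),              # N_i p (1-p)
    }
    agg = {}
    for key, arr in stats.items():
        pref = np.cumsum(arr, axis=0)
        if from_right:
            agg[key] = pref[-1][None, :] - pref[ks - 1]
        else:
            agg[key] = pref[ks - 1]
    m = (n - ks if from_right else ks).astype(float)
    sumN = agg["N"][:, 0]
    sumN2 = agg["N2"][:, 0]
    pi = agg["x"] / sumN[:, None]
    theta = np.zeros(len(ks))
    ok = (m > 1) & (sumN > m)   # >1 sample and not all depth-1
    if ok.any():
        mm, sN = m[ok], sumN[ok]
        S = (agg["Np2"][ok] - 2 * pi[ok] * agg["x"][ok]
             + pi[ok] ** 2 * agg["N"][ok]) / (mm - 1)[:, None]
        G = agg["Npq"][ok] / (sN - mm)[:, None]
        n_c = (sN - sumN2[ok] / sN) / (mm - 1)
        denom = (S + (n_c[:, None] - 1.0) * G).sum(axis=1)
        num = (S - G).sum(axis=1)
        th = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        theta[ok] = np.clip(th, 0.0, THETA_MAX)
    return pi, theta, m


def _group_ll_at_cuts(Xs: np.ndarray, ks: np.ndarray, pi: np.ndarray,
                      theta: np.ndarray, from_right: bool) -> np.ndarray:
    """No-coefficient DM log-likelihood of each cut's group under its own fit.

    For overdispersed cuts the lgamma sums are evaluated as a
    (cuts x samples x taxa) tensor, cumulated over samples and read off at
    the cut position; chunked to bound memory.
    """
    n, J = Xs.shape
    totals = Xs.sum(axis=1).astype(float)
    K = len(ks)
    ll = np.zeros(K)
    colsum = np.cumsum(Xs, axis=0).astype(float)
    group_cols = (colsum[-1][None, :] - colsum[ks - 1]) if from_right else colsum[ks - 1]
    m = (n - ks if from_right else ks).astype(float)

    zero = theta == 0.0
    if zero.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(pi[zero] > 0, np.log(np.where(pi[zero] > 0, pi[zero], 1.0)), 0.0)
        ll[zero] = (group_cols[zero] * lp).sum(axis=1)

    idx = np.nonzero(~zero)[0]
    if idx.size:
        chunk = max(1, _CHUNK_ELEMS // (n * J))
        for s in range(0, idx.size, chunk):
            sel = idx[s:s + chunk]
            th = theta[sel][:, None]
            p = pi[sel]
            mask = p > 0
            A = np.where(mask, p, 1.0) * (1.0 - th) / th
            T = gammaln(A[:, None, :] + Xs[None, :, :].astype(float))
            cT = np.cumsum(T, axis=1)
            pick = (cT[:, -1, :] - cT[np.arange(len(sel)), ks[sel] - 1, :]) \
                if from_right else cT[np.arange(len(sel)), ks[sel] - 1, :]
            num = np.where(mask, pick - m[sel][:, None] * gammaln(A), 0.0).sum(axis=1)
            B = (1.0 - theta[sel]) / theta[sel]
            D = gammaln(B[:, None] + totals[None, :])
            cD = np.cumsum(D, axis=1)
            dpick = (cD[:, -1] - cD[np.arange(len(sel)), ks[sel] - 1]) \
                if from_right else cD[np.arange(len(sel)), ks[sel] - 1]
            ll[sel] = num - (dpick - m[sel] * gammaln(B))
    return ll


def _llr_scan(Xs: np.ndarray, ks: np.ndarray, parent_ll: float) -> np.ndarray:
    """LLR = LL0 - (LL1 + LL2) for every candidate left size ``ks``."""
    pi_l, th_l, _ = _mom_prefix(Xs, ks, from_right=False)
    pi_r, th_r, _ = _mom_prefix(Xs, ks, from_right=True)
    ll_l = _group_ll_at_cuts(Xs, ks, pi_l, th_l, from_right=False)
    ll_r = _group_ll_at_cuts(Xs, ks, pi_r, th_r, from_right=True)
    return parent_ll - (ll_l + ll_r)


# ---------------------------------------------------------------------------
# split search and growth
# ---------------------------------------------------------------------------

def _node_summary(outcome: Outcome, members: np.ndarray, mode: str,
                  n_classes: int = 0) -> dict:
    """Fit the per-node summary and score S_n."""
    if mode == "dm":
        X = outcome.counts[members]
        pi, theta = _mom_from_counts(X)
        params = DMParams(pi=pi, theta=theta)
        ll = float(_loglik_rows(X, pi, theta).sum())
        return {"params": params, "error": -ll}
    labels = outcome[members]
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    maj = int(np.argmax(counts))
    return {"class_counts": counts, "majority_class": maj,
            "error": float(len(members) - counts[maj])}


def _is_pure(outcome: Outcome, members: np.ndarray, mode: str) -> bool:
    if mode == "dm":
        X = outcome.counts[members]
        return bool((X == X[0]).all())
    labels = outcome[members]
    return bool((labels == labels[0]).all())


def best_split(members: np.ndarray, outcome: Outcome,
               covariates: CovariateTable, config: FitConfig,
               criterion: str, n_classes: int = 0,
               node_ll: Optional[float] = None) -> Optional[SplitRule]:
    """Best admissible split of a node, or None.

    Scores every midpoint cut of every covariate; ``criterion="dm"``
    maximizes |LLR|, ``criterion="gini"`` maximizes weighted impurity
    decrease.  Ties break by covariate column order, then smaller cut
    point.  Returns None when no cut is admissible or the best improvement
    is zero.
    """
    if criterion not in ("dm", "gini"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if _is_pure(outcome, members, criterion):
        return None
    best_rule, best_score = None, _SCORE_TOL
    for ci, name in enumerate(covariates.covariate_names):
        col = covariates.values[members, ci]
        valid = ~np.isnan(col)
        if valid.sum() < 2 * config.min_bucket:
            continue
        sub = members[valid]
        order = np.argsort(col[valid], kind="stable")
        vs = col[valid][order]
        cuts, ks = _cut_positions(vs, config.min_bucket)
        if len(ks) == 0:
            continue
        if criterion == "dm":
            Xs = outcome.counts[sub][order]
            if node_ll is None or valid.sum() != len(members):
                pi, th = _mom_from_counts(Xs)
                pll = float(_loglik_rows(Xs, pi, th).sum())
            else:
                pll = node_ll
            scores = np.abs(_llr_scan(Xs, ks, pll))
        else:
            labels = outcome[sub][order]
            scores = _gini_scan(labels, n_classes, ks)
        j = int(np.argmax(scores))   # first max -> smallest cut wins ties
        if scores[j] > best_score:   # strict -> earlier covariate wins ties
            best_score = float(scores[j])
            best_rule = SplitRule(name, float(cuts[j]))
    return best_rule


def grow_full_tree(outcome: Outcome, covariates: CovariateTable,
                   config: Optional[FitConfig] = None) -> Tree:
    """Grow the full tree by greedy recursive splitting.

    Splitting stops in a node when it is smaller than ``min_split``, its
    outcomes are identical, no admissible cut exists, or the best score
    shows no improvement.  Deterministic given the inputs.
    """
    config = config or FitConfig()
    if isinstance(outcome, TaxaCountMatrix):
        mode, n_classes, class_labels = "dm", 0, None
        n = outcome.n_samples
        if covariates.sample_ids is not None and \
                covariates.sample_ids != outcome.sample_ids:
            raise ValueError("covariate sample ids do not match outcome")
    else:
        outcome = np.asarray(outcome)
        if outcome.ndim != 1:
            raise ValueError("classification outcome must be a label vector")
        mode = "gini"
        class_labels = sorted(int(c) for c in np.unique(outcome))
        lut = {c: i for i, c in enumerate(class_labels)}
        outcome = np.array([lut[int(c)] for c in outcome])
        n_classes = len(class_labels)
        n = outcome.shape[0]
    if n == 0:
        raise ValueError("cannot grow a tree on empty data")
    if covariates.n_samples != n:
        raise ValueError("outcome and covariates have different sample counts")

    root = TreeNode(node_id=1, members=np.arange(n), depth=0,
                    **_node_summary(outcome, np.arange(n), mode, n_classes))
    queue = [root]
    while queue:
        nd = queue.pop(0)
        if nd.n < config.min_split:
            continue
        if config.max_depth is not None and nd.depth >= config.max_depth:
            continue
        node_ll = -nd.error if mode == "dm" else None
        rule = best_split(nd.members, outcome, covariates, config, mode,
                          n_classes, node_ll)
        if rule is None:
            continue
        col = covariates.column(rule.covariate_name)[nd.members]
        go_left = col <= rule.cut_point          # NaN compares False
        missing = np.isnan(col)
        n_left = int((go_left & ~missing).sum())
        n_right = int((~go_left & ~missing).sum())
        missing_to = "left" if n_left >= n_right else "right"
        if missing.any():
            if missing_to == "left":
                go_left = go_left | missing
        left_m = nd.members[go_left]
        right_m = nd.members[~go_left]
        if len(left_m) == 0 or len(right_m) == 0:
            continue
        nd.split = rule
        nd.missing_to = missing_to
        nd.left = TreeNode(node_id=2 * nd.node_id, members=left_m,
                           depth=nd.depth + 1,
                           **_node_summary(outcome, left_m, mode, n_classes))
        nd.right = TreeNode(node_id=2 * nd.node_id + 1, members=right_m,
                            depth=nd.depth + 1,
                            **_node_summary(outcome, right_m, mode, n_classes))
        queue.extend((nd.left, nd.right))

    return Tree(root=root, mode=mode, config=config,
                covariate_names=list(covariates.covariate_names),
                n_samples=n,
                taxon_ids=list(outcome.taxon_ids) if mode == "dm" else None,
                class_labels=class_labels)


def predict_node(tree: Tree, row: Mapping[str, float]) -> int:
    """Terminal node id for a covariate row (module-level convenience)."""
    return tree.predict_node(row)


def predict_composition(tree: Tree, row: Mapping[str, float]) -> np.ndarray:
    """Predicted taxa proportions for a covariate row (dm-mode trees)."""
    return tree.predict_composition(row)
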