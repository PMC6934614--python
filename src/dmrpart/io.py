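"""File I/O: count/covariate tables, tree JSON, CP-table CSV, ASCII trees.

Canonical interchange is TSV (CSV accepted): counts files carry the
sample id in the first column and one integer column per taxon; a
transposed "taxa as rows" dialect is supported via an orientation flag.
Trees serialize to a versioned JSON schema that round-trips structure,
split rules, and node parameters losslessly; every artifact embeds the
tool version, the seed, and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .dm_model import DMParams, TaxaCountMatrix
from .prune_cv import CPTableRow
from .tree_engine import CovariateTable, FitConfig, SplitRule, Tree, TreeNode

__all__ = [
    "read_counts",
    "read_covariates",
    "align_covariates",
    "write_counts",
    "write_tree",
    "read_tree",
    "write_cp_table",
    "read_cp_table",
    "render_tree",
]

TREE_SCHEMA_VERSION = 1
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


def _sep_for(path: Union[str, Path], csv: Optional[bool]) -> str:
    if csv is None:
        csv = str(path).lower().endswith(".csv")
    return "," if csv else "\t"


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# counts and covariates
# ---------------------------------------------------------------------------

def read_counts(path: Union[str, Path], orientation: str = "samples-rows",
                csv: Optional[bool] = None) -> TaxaCountMatrix:
    """Load a taxa count table.

    ``orientation="samples-rows"`` (default): first column sample ids,
    header row taxon names.  ``"taxa-rows"``: transposed dialect.
    Rejects duplicate sample ids, negative, missing, or non-integer cells.
    """
    if orientation not in ("samples-rows", "taxa-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path, csv), index_col=0, comment="#")
    if orientation == "taxa-rows":
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dup[:5]}")
    if df.isna().any().any():
        raise ValueError(f"missing values in count table {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"non-numeric counts in {path}")
    if np.any(values != np.floor(values)):
        raise ValueError(f"non-integer counts in {path}")
    return TaxaCountMatrix(values.astype(np.int64),
                           sample_ids=[str(i) for i in df.index],
                           taxon_ids=[str(c) for c in df.columns])


def write_counts(matrix: TaxaCountMatrix, path: Union[str, Path],
                 csv: Optional[bool] = None) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.sample_ids,
                      columns=matrix.taxon_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path, csv))


def read_covariates(path: Union[str, Path],
                    names: Optional[Sequence[str]] = None,
                    binary_maps: Optional[dict[str, dict[str, int]]] = None,
                    csv: Optional[bool] = None) -> CovariateTable:
    """Load a sample metadata table of continuous/binary covariates.

    ``names`` selects (and orders) a subset of columns.  String columns
    listed in ``binary_maps`` are recoded to 0/1 via the declared mapping,
    e.g. ``{"group": {"IS": 0, "IR": 1}}``.  Missing-value tokens (empty,
    "NA") become NaN; all-missing columns are dropped with a warning;
    any other non-numeric column is an error naming the offending rows.
    """
    df = pd.read_csv(path, sep=_sep_for(path, csv), index_col=0, comment="#",
                     na_values=sorted(_MISSING_TOKENS), keep_default_na=True,
                     dtype=object)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if names is not None:
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise ValueError(f"covariates not found in {path}: {missing}")
        df = df[list(names)]
    binary_maps = binary_maps or {}
    cols, keep = {}, []
    for col in df.columns:
        series = df[col]
        if col in binary_maps:
            mapping = binary_maps[col]
            bad = series.dropna()[~series.dropna().isin(mapping)]
            if len(bad):
                raise ValueError(
                    f"column {col!r} has values outside its declared mapping "
                    f"in rows {bad.index.tolist()[:5]}")
            series = series.map(mapping)
        numeric = pd.to_numeric(series, errors="coerce")
        bad_rows = series.notna() & numeric.isna()
        if bad_rows.any():
            raise ValueError(
                f"non-numeric covariate column {col!r} in rows "
                f"{series.index[bad_rows].tolist()[:5]}; declare a binary "
                "mapping for categorical columns")
        if numeric.isna().all():
            warnings.warn(f"covariate {col!r} is entirely missing; dropped")
            continue
        cols[col] = numeric.to_numpy(dtype=float)
        keep.append(col)
    if not keep:
        raise ValueError(f"no usable covariate columns in {path}")
    values = np.column_stack([cols[c] for c in keep])
    return CovariateTable(values, keep, sample_ids=[str(i) for i in df.index])


def align_covariates(counts: TaxaCountMatrix,
                     covariates: CovariateTable) -> CovariateTable:
    """Reorder covariate rows to the count matrix's sample order.

    Raises a descriptive error naming any count sample absent from the
    covariate table.
    """
    if covariates.sample_ids is None:
        if covariates.n_samples != counts.n_samples:
            raise ValueError("covariates lack sample ids and row counts differ")
        return covariates
    pos = {s: i for i, s in enumerate(covariates.sample_ids)}
    missing = [s for s in counts.sample_ids if s not in pos]
    if missing:
        raise ValueError(
            f"samples present in counts but absent in metadata: {missing[:5]}")
    idx = [pos[s] for s in counts.sample_ids]
    return CovariateTable(covariates.values[idx],
                          list(covariates.covariate_names),
                          sample_ids=list(counts.sample_ids))


# ---------------------------------------------------------------------------
# tree JSON
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode, include_members: bool) -> dict:
    d: dict = {"n": int(node.n), "depth": int(node.depth),
               "error": float(node.error)}
    if include_members:
        d["members"] = [int(i) for i in node.members]
    if node.params is not None:
        d["pi"] = [float(p) for p in node.params.pi]
        d["theta"] = float(node.params.theta)
    if node.class_counts is not None:
        d["class_counts"] = [int(c) for c in node.class_counts]
        d["majority_class"] = int(node.majority_class)
    if node.split is not None:
        d["split"] = {"covariate": node.split.covariate_name,
                      "cut_point": float(node.split.cut_point),
                      "missing_to": node.missing_to}
    return d


def write_tree(tree: Tree, path: Union[str, Path],
               seed: Optional[int] = None,
               include_members: bool = True) -> None:
    """Serialize a tree to the versioned JSON schema."""
    cfg = {"min_split": tree.config.min_split,
           "min_bucket": tree.config.min_bucket,
           "max_depth": tree.config.max_depth}
    nodes = {str(nd.node_id): _node_to_dict(nd, include_members)
             for nd in tree.iter_nodes()}
    doc = {
        "format": "dmrpart-tree",
        "schema_version": TREE_SCHEMA_VERSION,
        "tool_version": __version__,
        "mode": tree.mode,
        "routing": "value <= cut_point goes left",
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "n_samples": tree.n_samples,
        "covariate_names": tree.covariate_names,
        "taxon_ids": tree.taxon_ids,
        "class_labels": tree.class_labels,
        "nodes": nodes,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _node_from_dict(node_id: int, nodes: dict, depth: int) -> TreeNode:
    d = nodes[str(node_id)]
    members = np.asarray(d.get("members", []), dtype=int)
    params = None
    if "pi" in d:
        params = DMParams(pi=np.asarray(d["pi"], float), theta=d["theta"])
    node = TreeNode(
        node_id=node_id, members=members, depth=d.get("depth", depth),
        params=params,
        class_counts=(np.asarray(d["class_counts"], float)
                      if "class_counts" in d else None),
        majority_class=d.get("majority_class"),
        error=float(d.get("error", 0.0)),
    )
    if "split" in d:
        s = d["split"]
        node.split = SplitRule(s["covariate"], float(s["cut_point"]))
        node.missing_to = s.get("missing_to", "left")
        node.left = _node_from_dict(2 * node_id, nodes, depth + 1)
        node.right = _node_from_dict(2 * node_id + 1, nodes, depth + 1)
        if node.left.n + node.right.n != node.n:
            raise ValueError(
                f"invalid tree file: child sample counts of node {node_id} "
                f"({node.left.n}+{node.right.n}) do not sum to parent ({node.n})")
    return node


def read_tree(path: Union[str, Path]) -> Tree:
    """Load a tree JSON, validating schema version and node invariants."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "dmrpart-tree":
        raise ValueError(f"{path} is not a dmrpart tree file")
    if doc.get("schema_version") != TREE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported tree schema version {doc.get('schema_version')!r} "
            f"(expected {TREE_SCHEMA_VERSION})")
    cfg = doc["config"]
    config = FitConfig(min_split=cfg["min_split"], min_bucket=cfg["min_bucket"],
                       max_depth=cfg.get("max_depth"))
    root = _node_from_dict(1, doc["nodes"], 0)
    return Tree(root=root, mode=doc["mode"], config=config,
                covariate_names=list(doc["covariate_names"]),
                n_samples=int(doc["n_samples"]),
                taxon_ids=doc.get("taxon_ids"),
                class_labels=doc.get("class_labels"))


# ---------------------------------------------------------------------------
# CP table CSV
# ---------------------------------------------------------------------------

def write_cp_table(rows: Sequence[CPTableRow], path: Union[str, Path],
                   seed: Optional[int] = None,
                   config: Optional[dict] = None) -> None:
    """CP table as CSV with a provenance comment header."""
    header = (f"# dmrpart {__version__} seed={seed} "
              f"config_hash={config_hash(config or {})}\n")
    df = pd.DataFrame([r.__dict__ for r in rows])
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_cp_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# ASCII rendering
# ---------------------------------------------------------------------------

def render_tree(tree: Tree, top_taxa: int = 3) -> str:
    """Plain-text tree: node id, rule, n, % of root, and node summary."""
    lines: list[str] = []
    total = tree.root.n if tree.root.n else 1

    def describe(nd: TreeNode) -> str:
        pct = 100.0 * nd.n / total
        bits = [f"node {nd.node_id}", f"n={nd.n}", f"{pct:.0f}%"]
        if tree.mode == "dm" and nd.params is not None:
            bits.append(f"theta={nd.params.theta:.4f}")
            if tree.taxon_ids:
                order = np.argsort(nd.params.pi)[::-1][:top_taxa]
                tops = ", ".join(f"{tree.taxon_ids[j]}:{nd.params.pi[j]:.3f}"
                                 for j in order)
                bits.append(f"top[{tops}]")
        elif nd.class_counts is not None:
            label = tree.class_labels[nd.majority_class]
            bits.append(f"class={label} counts={nd.class_counts.astype(int).tolist()}")
        if nd.is_leaf:
            bits.append("*")
        return "  ".join(bits)

    def walk(nd: TreeNode, prefix: str, rule: str) -> None:
        lines.append(f"{prefix}{rule}{describe(nd)}")
        if not nd.is_leaf:
            name, cut = nd.split.covariate_name, nd.split.cut_point
            walk(nd.left, prefix + "  ", f"[{name} <= {cut:g}] ")
            walk(nd.right, prefix + "  ", f"[{name} > {cut:g}] ")

    walk(tree.root, "", "")
    return "\n".join(lines)
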