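"""Fast decision-tree learner with reduced-error pruning.

A REPTree-style classifier built for rule extraction rather than raw
predictive power:

* splits maximize Shannon information gain; candidate thresholds for real
  attributes are midpoints between consecutive distinct sorted values;
* nominal attributes split multiway on their value domain;
* ties between equal-gain splits break on (lower attribute index, smaller
  threshold) so learning is fully deterministic given the seed;
* reduced-error pruning on a held-out fraction of the training data
  replaces a subtree by its majority leaf whenever that does not increase
  held-out error;
* missing values route to the child with larger training support (no
  fractional instance weighting).

Thresholds are kept at the full precision of the midpoint computation —
the ``3749.05``-style constants that appear in extracted rules are midpoint
artifacts, not rounded values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .prep import LabelledInstanceTable

__all__ = ["TreeParams", "TreeNode", "DecisionTree", "TreePath",
           "learn_tree", "prune", "predict", "extract_paths",
           "tree_to_json", "tree_from_json", "tree_to_text"]

_EPS = 1e-12


@dataclass(frozen=True)
class TreeParams:
    min_leaf: int = 2
    max_depth: Optional[int] = None
    prune_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ConfigError("min_leaf must be >= 1")
        if not 0.0 <= self.prune_fraction < 1.0:
            raise ConfigError("prune_fraction must be in [0, 1)")
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigError("max_depth must be >= 0")


@dataclass
class TreeNode:
    kind: str                       # 'leaf' | 'real' | 'nominal'
    counts: dict[str, int]          # training class counts at this node
    support: int
    label: Optional[str] = None     # leaf majority label
    attribute: Optional[str] = None
    threshold: Optional[float] = None      # real split: left iff x < threshold
    values: Optional[list[str]] = None     # nominal split branch values
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"

    def majority_label(self) -> str:
        # tie -> lexicographically smallest, for determinism
        best = max(sorted(self.counts), key=lambda c: self.counts[c])
        return best

    def default_child_index(self) -> int:
        """Missing values go to the child with larger support (tie: first)."""
        supports = [c.support for c in self.children]
        return int(np.argmax(supports))


@dataclass
class DecisionTree:
    root: TreeNode
    feature_columns: list[str]
    feature_kinds: dict[str, str]   # column -> 'real' | 'nominal'
    params: TreeParams
    labels: list[str]

    @property
    def depth(self) -> int:
        def d(n: TreeNode) -> int:
            return 0 if n.is_leaf else 1 + max(d(c) for c in n.children)
        return d(self.root)

    @property
    def n_nodes(self) -> int:
        def c(n: TreeNode) -> int:
            return 1 + sum(c(ch) for ch in n.children)
        return c(self.root)


@dataclass
class TreePath:
    """One root-to-leaf conjunction of threshold conditions."""

    conditions: list[tuple[str, str, object]]  # (attribute, op, constant)
    label: str
    support: int
    purity: float


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(y, minlength=k)


def _best_real_split(x: np.ndarray, y: np.ndarray, k: int,
                     min_leaf: int) -> Optional[tuple[float, float]]:
    """(gain, threshold) of the best midpoint split, or None."""
    present = ~np.isnan(x)
    xv, yv = x[present], y[present]
    n_all = len(x)
    n = len(xv)
    if n < 2 * min_leaf:
        return None
    order = np.argsort(xv, kind="stable")
    xs, ys = xv[order], yv[order]
    onehot = np.zeros((n, k))
    onehot[np.arange(n), ys] = 1.0
    left = np.cumsum(onehot, axis=0)          # left[i] = counts of first i+1
    total = left[-1]
    h_total = _entropy(total)
    boundaries = np.nonzero(xs[1:] != xs[:-1])[0]  # split after index i
    best: Optional[tuple[float, float]] = None
    frac_known = n / n_all
    for i in boundaries:
        nl = i + 1
        nr = n - nl
        if nl < min_leaf or nr < min_leaf:
            continue
        lc = left[i]
        rc = total - lc
        gain = frac_known * (
            h_total - (nl / n) * _entropy(lc) - (nr / n) * _entropy(rc))
        if gain > _EPS and (best is None or gain > best[0] + _EPS):
            thr = (xs[i] + xs[i + 1]) / 2.0
            best = (gain, float(thr))
    return best


def _best_nominal_split(x: np.ndarray, y: np.ndarray, k: int,
                        min_leaf: int) -> Optional[tuple[float, list[str]]]:
    present = np.array([v is not None for v in x])
    xv, yv = x[present], y[present]
    n_all = len(x)
    n = len(xv)
    if n < 2 * min_leaf:
        return None
    values = sorted({str(v) for v in xv})
    if len(values) < 2:
        return None
    total = _class_counts(yv, k)
    h_total = _entropy(total)
    rest = h_total
    sizes = []
    for v in values:
        m = np.array([str(u) == v for u in xv])
        cnt = _class_counts(yv[m], k)
        sizes.append(int(m.sum()))
        rest -= (m.sum() / n) * _entropy(cnt)
    if min(sizes) < min_leaf:
        return None
    gain = (n / n_all) * rest
    if gain <= _EPS:
        return None
    return gain, values


def _grow(X: dict[str, np.ndarray], kinds: dict[str, str],
          columns: Sequence[str], y: np.ndarray, labels: list[str],
          idx: np.ndarray, depth: int, params: TreeParams) -> TreeNode:
    k = len(labels)
    counts_arr = _class_counts(y[idx], k)
    counts = {labels[i]: int(counts_arr[i]) for i in range(k)
              if counts_arr[i] > 0}
    node = TreeNode(kind="leaf", counts=counts, support=int(len(idx)))
    node.label = node.majority_label()
    if counts_arr.max() == len(idx):
        return node
    if params.max_depth is not None and depth >= params.max_depth:
        return node

    best: Optional[tuple[float, int, str, object]] = None  # gain, j, kind, extra
    for j, col in enumerate(columns):
        if kinds[col] == "real":
            r = _best_real_split(X[col][idx], y[idx], k, params.min_leaf)
            if r is not None and (best is None or r[0] > best[0] + _EPS):
                best = (r[0], j, "real", r[1])
        else:
            r = _best_nominal_split(X[col][idx], y[idx], k, params.min_leaf)
            if r is not None and (best is None or r[0] > best[0] + _EPS):
                best = (r[0], j, "nominal", r[1])
    if best is None:
        return node

    _gain, j, split_kind, extra = best
    col = columns[j]
    x = X[col][idx]
    if split_kind == "real":
        thr = float(extra)
        known = ~np.isnan(x)
        go_left = known & (x < thr)
        go_right = known & ~go_left
        # missing rows follow the majority side
        n_left, n_right = int(go_left.sum()), int(go_right.sum())
        missing = ~known
        if missing.any():
            if n_left >= n_right:
                go_left = go_left | missing
            else:
                go_right = go_right | missing
        left = _grow(X, kinds, columns, y, labels, idx[go_left],
                     depth + 1, params)
        right = _grow(X, kinds, columns, y, labels, idx[go_right],
                      depth + 1, params)
        node = TreeNode(kind="real", counts=counts, support=int(len(idx)),
                        attribute=col, threshold=thr, children=[left, right])
        return node
    values = list(extra)
    masks = []
    known = np.array([v is not None for v in x])
    for v in values:
        masks.append(np.array([u is not None and str(u) == v for u in x]))
    missing = ~known
    if missing.any():
        biggest = int(np.argmax([m.sum() for m in masks]))
        masks[biggest] = masks[biggest] | missing
    children = [_grow(X, kinds, columns, y, labels, idx[m], depth + 1, params)
                for m in masks]
    return TreeNode(kind="nominal", counts=counts, support=int(len(idx)),
                    attribute=col, values=values, children=children)


def _matrix(table: LabelledInstanceTable) -> tuple[dict[str, np.ndarray],
                                                   dict[str, str]]:
    X: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for col in table.feature_columns:
        s = table.frame[col]
        if pd.api.types.is_numeric_dtype(s):
            X[col] = s.to_numpy(dtype=float)
            kinds[col] = "real"
        else:
            X[col] = np.array(
                [None if (v is None or (isinstance(v, float) and math.isnan(v)))
                 else str(v) for v in s], dtype=object)
            kinds[col] = "nominal"
    return X, kinds


def _subset(table: LabelledInstanceTable,
            idx: np.ndarray) -> LabelledInstanceTable:
    return LabelledInstanceTable(
        frame=table.frame.iloc[idx].reset_index(drop=True),
        feature_columns=list(table.feature_columns),
        provenance=(table.provenance.iloc[idx].reset_index(drop=True)
                    if table.provenance is not None else None))


def learn_tree(table: LabelledInstanceTable,
               params: TreeParams = TreeParams()) -> DecisionTree:
    """Grow (and, with ``prune_fraction > 0``, reduce-error prune) a tree.

    Deterministic given the table and params: the held-out pruning split is
    drawn from ``params.seed``, and all tie-breaks are fixed.
    """
    n = len(table)
    if n < 1:
        raise ConfigError("learning needs at least one instance")
    if not table.feature_columns:
        raise ConfigError("learning needs at least one feature")
    X, kinds = _matrix(table)
    label_list = sorted(set(map(str, table.labels)))
    label_index = {l: i for i, l in enumerate(label_list)}
    y = np.array([label_index[str(l)] for l in table.labels])

    grow_table = table
    prune_table: Optional[LabelledInstanceTable] = None
    if params.prune_fraction > 0.0 and n >= 2:
        rng = np.random.default_rng(params.seed)
        perm = rng.permutation(n)
        n_prune = int(round(params.prune_fraction * n))
        n_prune = min(n_prune, n - 1)
        prune_idx = np.sort(perm[:n_prune])
        grow_idx = np.sort(perm[n_prune:])
        grow_table = _subset(table, grow_idx)
        prune_table = _subset(table, prune_idx) if n_prune else None
        X, kinds = _matrix(grow_table)
        y = np.array([label_index[str(l)] for l in grow_table.labels])

    root = _grow(X, kinds, list(table.feature_columns), y, label_list,
                 np.arange(len(grow_table)), 0, params)
    tree = DecisionTree(root=root, feature_columns=list(table.feature_columns),
                        feature_kinds=kinds, params=params, labels=label_list)
    if prune_table is not None and len(prune_table):
        tree = prune(tree, prune_table)
    return tree


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _route(node: TreeNode, tree: DecisionTree, row: pd.Series) -> TreeNode:
    while not node.is_leaf:
        v = row.get(node.attribute)
        missing = v is None or (isinstance(v, float) and math.isnan(v))
        if node.kind == "real":
            if missing:
                node = node.children[node.default_child_index()]
            elif float(v) < node.threshold:
                node = node.children[0]
            else:
                node = node.children[1]
        else:
            if missing or str(v) not in node.values:
                node = node.children[node.default_child_index()]
            else:
                node = node.children[node.values.index(str(v))]
    return node


def _copy_node(node: TreeNode) -> TreeNode:
    return TreeNode(kind=node.kind, counts=dict(node.counts),
                    support=node.support, label=node.label,
                    attribute=node.attribute, threshold=node.threshold,
                    values=list(node.values) if node.values else None,
                    children=[_copy_node(c) for c in node.children])


def prune(tree: DecisionTree,
          pruning_set: LabelledInstanceTable) -> DecisionTree:
    """Reduced-error pruning: bottom-up subtree replacement by majority leaf.

    A subtree collapses whenever the leaf's error on the pruning set does
    not exceed the subtree's; the pruned tree's pruning-set error is
    therefore never larger than the unpruned tree's.  An empty pruning set
    returns the tree unchanged (with a warning).
    """
    if len(pruning_set) == 0:
        import logging
        logging.getLogger("vitalwatch.tree").warning(
            "empty pruning set; tree returned unchanged")
        return tree

    rows = [pruning_set.frame.iloc[i] for i in range(len(pruning_set))]
    labels = [str(l) for l in pruning_set.labels]

    def rec(node: TreeNode, reach: list[int]) -> tuple[TreeNode, int]:
        node = _copy_node(node)
        majority = node.majority_label()
        leaf_err = sum(1 for i in reach if labels[i] != majority)
        if node.is_leaf:
            return node, leaf_err
        groups: dict[int, list[int]] = {ci: [] for ci in range(len(node.children))}
        for i in reach:
            row = rows[i]
            v = row.get(node.attribute)
            missing = v is None or (isinstance(v, float) and math.isnan(v))
            if node.kind == "real":
                ci = (node.default_child_index() if missing
                      else (0 if float(v) < node.threshold else 1))
            else:
                ci = (node.default_child_index()
                      if missing or str(v) not in node.values
                      else node.values.index(str(v)))
            groups[ci].append(i)
        sub_err = 0
        new_children = []
        for ci, child in enumerate(node.children):
            nc, e = rec(child, groups[ci])
            new_children.append(nc)
            sub_err += e
        if leaf_err <= sub_err:
            leaf = TreeNode(kind="leaf", counts=dict(node.counts),
                            support=node.support)
            leaf.label = majority
            return leaf, leaf_err
        node.children = new_children
        return node, sub_err

    new_root, _err = rec(tree.root, list(range(len(rows))))
    return DecisionTree(root=new_root,
                        feature_columns=list(tree.feature_columns),
                        feature_kinds=dict(tree.feature_kinds),
                        params=tree.params, labels=list(tree.labels))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(tree: DecisionTree, instance: Union[pd.Series, dict]) -> str:
    """Label of the leaf the instance reaches.

    A value exactly on a threshold routes to the ``>=`` branch; a missing
    value routes to the child with larger training support (tie: the ``<``
    branch).
    """
    row = instance if isinstance(instance, pd.Series) else pd.Series(instance)
    return _route(tree.root, tree, row).label


def predict_frame(tree: DecisionTree, frame: pd.DataFrame) -> list[str]:
    return [predict(tree, frame.iloc[i]) for i in range(len(frame))]


def training_error(tree: DecisionTree, table: LabelledInstanceTable) -> int:
    pred = predict_frame(tree, table.frame)
    return int(sum(p != str(l) for p, l in zip(pred, table.labels)))


# ---------------------------------------------------------------------------
# path extraction
# ---------------------------------------------------------------------------

def _simplify(conditions: list[tuple[str, str, object]]
              ) -> list[tuple[str, str, object]]:
    """Keep the tightest bound per attribute and direction."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    nominal: list[tuple[str, str, object]] = []
    order: list[tuple[str, str]] = []
    for attr, op, c in conditions:
        if op == "<":
            if attr not in upper or float(c) < upper[attr]:
                upper[attr] = float(c)
            key = (attr, "<")
        elif op == ">=":
            if attr not in lower or float(c) > lower[attr]:
                lower[attr] = float(c)
            key = (attr, ">=")
        else:
            if (attr, op, c) not in nominal:
                nominal.append((attr, op, c))
            key = (attr, "=")
        if key not in order:
            order.append(key)
    out: list[tuple[str, str, object]] = []
    for attr, op in order:
        if op == "<":
            out.append((attr, "<", upper[attr]))
        elif op == ">=":
            out.append((attr, ">=", lower[attr]))
        else:
            out.extend(nc for nc in nominal if nc[0] == attr)
    return out


def extract_paths(tree: DecisionTree,
                  label_filter: Optional[set[str]] = None,
                  min_support: int = 1,
                  min_purity: float = 0.0) -> list[TreePath]:
    """Root-to-leaf paths of qualifying leaves, sorted by support descending.

    ``label_filter=None`` keeps every leaf label.  Conditions are
    simplified per attribute (tightest bound per direction survives).
    """
    if min_support < 1:
        raise ConfigError("min_support must be >= 1")
    if not 0.0 <= min_purity <= 1.0:
        raise ConfigError("min_purity must be in [0, 1]")
    paths: list[TreePath] = []

    def walk(node: TreeNode, conds: list[tuple[str, str, object]]) -> None:
        if node.is_leaf:
            if label_filter is not None and node.label not in label_filter:
                return
            if node.support < min_support or node.support == 0:
                return
            purity = node.counts.get(node.label, 0) / node.support
            if purity < min_purity:
                return
            paths.append(TreePath(conditions=_simplify(conds),
                                  label=node.label, support=node.support,
                                  purity=purity))
            return
        if node.kind == "real":
            walk(node.children[0], conds + [(node.attribute, "<", node.threshold)])
            walk(node.children[1], conds + [(node.attribute, ">=", node.threshold)])
        else:
            for v, child in zip(node.values, node.children):
                walk(child, conds + [(node.attribute, "=", v)])

    walk(tree.root, [])
    paths.sort(key=lambda p: -p.support)
    return paths


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    d = {"kind": node.kind, "counts": node.counts, "support": node.support}
    if node.is_leaf:
        d["label"] = node.label
    else:
        d["attribute"] = node.attribute
        if node.kind == "real":
            d["threshold"] = node.threshold
        else:
            d["values"] = node.values
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(kind=d["kind"],
                    counts={str(k): int(v) for k, v in d["counts"].items()},
                    support=int(d["support"]), label=d.get("label"),
                    attribute=d.get("attribute"), threshold=d.get("threshold"),
                    values=d.get("values"),
                    children=[_node_from_dict(c) for c in d.get("children", [])])
    return node


def tree_to_json(tree: DecisionTree) -> str:
    return json.dumps({
        "root": _node_to_dict(tree.root),
        "feature_columns": tree.feature_columns,
        "feature_kinds": tree.feature_kinds,
        "labels": tree.labels,
        "params": {"min_leaf": tree.params.min_leaf,
                   "max_depth": tree.params.max_depth,
                   "prune_fraction": tree.params.prune_fraction,
                   "seed": tree.params.seed},
    }, indent=2, sort_keys=True)


def tree_from_json(text: str) -> DecisionTree:
    d = json.loads(text)
    p = d["params"]
    return DecisionTree(root=_node_from_dict(d["root"]),
                        feature_columns=list(d["feature_columns"]),
                        feature_kinds=dict(d["feature_kinds"]),
                        params=TreeParams(min_leaf=p["min_leaf"],
                                          max_depth=p["max_depth"],
                                          prune_fraction=p["prune_fraction"],
                                          seed=p["seed"]),
                        labels=list(d["labels"]))


def tree_to_text(tree: DecisionTree) -> str:
    """Indented printout in the style of common workbench tree dumps."""
    lines: list[str] = []

    def leaf_suffix(node: TreeNode) -> str:
        errors = node.support - node.counts.get(node.label, 0)
        return f" : {node.label} ({node.support}/{errors})"

    def walk(node: TreeNode, depth: int) -> None:
        pad = "|   " * depth
        if node.is_leaf:
            lines.append(pad + leaf_suffix(node)[3:])
            return
        if node.kind == "real":
            branches = [(f"{node.attribute} < {node.threshold:g}", node.children[0]),
                        (f"{node.attribute} >= {node.threshold:g}", node.children[1])]
        else:
            branches = [(f"{node.attribute} = {v}", c)
                        for v, c in zip(node.values, node.children)]
        for text, child in branches:
            if child.is_leaf:
                lines.append(pad + text + leaf_suffix(child))
            else:
                lines.append(pad + text)
                walk(child, depth + 1)

    walk(tree.root, 0)
    return "\n".join(lines)
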