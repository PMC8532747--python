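"""Gain-ratio decision-tree and random-tree induction, pruning, rules.

Written from scratch: binary axis-aligned splits over the five numeric
attributes (broiler age, T, RH, AV, NH3), split quality judged by the gain
ratio (information gain in bits divided by the split information, the C4.5
criterion), candidate thresholds at midpoints between consecutive distinct
sorted values.  The random-tree variant considers a seeded random subset of
k attributes at every node (default k = ceil(sqrt(p))).

Two pruning operators are provided: cost-complexity ("error-complexity")
pruning, which computes the weakest-link alpha sequence from training counts
and returns the subtree minimizing holdout error (ties broken toward fewer
leaves), and minimum-support pruning, which merges leaves covering less than
a given fraction of the training sample into their parent, repeated to a
fixed point.

Trees serialize to a JSON dialect and export to Graphviz DOT text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quality import CLASS_LABELS, N_CLASSES, QualityClass

__all__ = [
    "FEATURES",
    "TreeParams",
    "TreeNode",
    "Rule",
    "RuleSet",
    "OneSidedSplitError",
    "gain_ratio",
    "fit_decision_tree",
    "fit_random_tree",
    "error_complexity_prune",
    "min_support_prune",
    "predict",
    "predict_table",
    "extract_rules",
    "tree_to_json",
    "tree_from_json",
    "tree_to_dot",
]

#: Feature names, in canonical order (ties between equally good splits are
#: broken toward the earlier attribute).
FEATURES: tuple[str, ...] = ("age_days", "t_db", "rh", "av", "nh3")

#: Accepted aliases for feature columns (CSV schema -> feature name).
FEATURE_ALIASES: dict[str, str] = {
    "t_db_c": "t_db",
    "rh_pct": "rh",
    "av_ms": "av",
    "nh3_mgm3": "nh3",
}

_GAIN_EPS = 1e-12


class OneSidedSplitError(ValueError):
    """A candidate threshold left one side of the split empty."""


@dataclass
class TreeParams:
    """Induction hyperparameters."""

    min_leaf: int = 2
    max_depth: int | None = None
    #: attributes considered per node: None = all, or an integer k (random-tree).
    attributes_per_node: int | None = None
    seed: int = 0
    min_support_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError(f"min_leaf must be >= 1, got {self.min_leaf}")
        k = self.attributes_per_node
        if k is not None and not 1 <= k <= len(FEATURES):
            raise ValueError(f"attributes_per_node must be in [1, {len(FEATURES)}], got {k}")


@dataclass
class TreeNode:
    """A node of an axis-aligned binary classification tree.

    Internal nodes carry ``attribute``/``threshold`` and route a record left
    when ``value <= threshold``; every node (leaves included) carries the
    training class counts, so any internal node can be collapsed into a leaf.
    """

    class_counts: np.ndarray  # shape (4,), training counts in CLASS_ORDER
    support_fraction: float
    attribute: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    def __post_init__(self) -> None:
        self.class_counts = np.asarray(self.class_counts, dtype=np.int64)
        if self.class_counts.shape != (N_CLASSES,):
            raise ValueError(f"class_counts must have shape ({N_CLASSES},)")
        if self.is_leaf and self.n == 0:
            raise ValueError("a leaf must cover at least one training record")
        if self.threshold is not None and not math.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold}")

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    @property
    def predicted(self) -> QualityClass:
        # argmax returns the first maximum; class order is severity-ascending,
        # so ties break toward the less severe class.
        return QualityClass(int(np.argmax(self.class_counts)))

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def copy(self) -> "TreeNode":
        return TreeNode(
            class_counts=self.class_counts.copy(),
            support_fraction=self.support_fraction,
            attribute=self.attribute,
            threshold=self.threshold,
            left=None if self.left is None else self.left.copy(),
            right=None if self.right is None else self.right.copy(),
        )

    def collapse(self) -> None:
        """Turn this (internal) node into a leaf over its own counts."""
        self.attribute = None
        self.threshold = None
        self.left = None
        self.right = None

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "predicted": self.predicted.label,
                "counts": self.class_counts.tolist(),
                "support": self.support_fraction,
            }
        return {
            "attribute": self.attribute,
            "threshold": self.threshold,
            "counts": self.class_counts.tolist(),
            "support": self.support_fraction,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreeNode":
        node = cls(
            class_counts=np.asarray(d["counts"], dtype=np.int64),
            support_fraction=float(d["support"]),
            attribute=d.get("attribute"),
            threshold=d.get("threshold"),
        )
        if not node.is_leaf:
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


# ---------------------------------------------------------------------------
# Entropy and the gain ratio
# ---------------------------------------------------------------------------


def _entropy_bits(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of count vectors; rows with total 0 yield 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[..., None]
        terms = np.where(counts > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def _labels_to_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array([QualityClass.from_label(l) if isinstance(l, str) else int(l) for l in arr])


def gain_ratio(values, labels, threshold: float) -> float:
    """Gain ratio (bits) of the binary split ``value <= threshold``.

    Raises :class:`OneSidedSplitError` when the threshold leaves either side
    empty (the ratio is undefined there).  Always in ``[0, 1]``: the mutual
    information between the labels and the split indicator cannot exceed the
    split's own entropy.
    """
    v = np.asarray(values, dtype=float)
    y = _labels_to_codes(labels)
    if v.shape != y.shape or v.ndim != 1 or len(v) < 2:
        raise ValueError("values and labels must be equal-length 1-d, length >= 2")
    left = v <= threshold
    n_left = int(left.sum())
    n = len(v)
    if n_left == 0 or n_left == n:
        raise OneSidedSplitError(f"threshold {threshold} puts all {n} records on one side")
    total = np.bincount(y, minlength=N_CLASSES)
    lc = np.bincount(y[left], minlength=N_CLASSES)
    rc = total - lc
    h = _entropy_bits(total[None, :], np.array([n]))[0]
    hl = _entropy_bits(lc[None, :], np.array([n_left]))[0]
    hr = _entropy_bits(rc[None, :], np.array([n - n_left]))[0]
    gain = h - (n_left * hl + (n - n_left) * hr) / n
    pl = n_left / n
    split_info = -(pl * math.log2(pl) + (1 - pl) * math.log2(1 - pl))
    return max(0.0, gain / split_info)


def _best_split_for_attribute(
    v: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best (gain_ratio, threshold) for one attribute, or None.

    Vectorized scan over all midpoint thresholds satisfying min_leaf.  Among
    candidates, only those whose information gain reaches the average gain of
    all positive-gain candidates compete on gain ratio — the standard C4.5
    guard against the ratio favouring tiny, uninformative splits.
    """
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    vs = v[order]
    ys = y[order]
    change = vs[1:] != vs[:-1]
    sizes_left = np.arange(1, n)
    valid = change & (sizes_left >= min_leaf) & (n - sizes_left >= min_leaf)
    if not valid.any():
        return None

    onehot = np.zeros((n, N_CLASSES), dtype=np.int64)
    onehot[np.arange(n), ys] = 1
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    lc = cum[:-1][valid]
    rc = total[None, :] - lc
    nl = sizes_left[valid].astype(float)
    nr = n - nl

    h = _entropy_bits(total[None, :], np.array([float(n)]))[0]
    gains = h - (nl * _entropy_bits(lc, nl) + nr * _entropy_bits(rc, nr)) / n
    pl = nl / n
    split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))

    positive = gains > _GAIN_EPS
    if not positive.any():
        return None
    admissible = positive & (gains >= gains[positive].mean() - _GAIN_EPS)
    ratios = np.where(admissible, gains / split_info, -1.0)

    best = int(np.argmax(ratios))  # first max -> smallest threshold on ties
    if ratios[best] <= 0:
        return None
    pos = np.flatnonzero(valid)[best]
    thr = (vs[pos] + vs[pos + 1]) / 2.0
    return float(ratios[best]), float(thr)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize column names to the canonical feature names."""
    return table.rename(columns=FEATURE_ALIASES)


def _extract_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = feature_frame(table)
    missing = [f for f in FEATURES if f not in df.columns]
    if missing:
        raise ValueError(f"training table is missing feature columns {missing}")
    if "arcf" not in df.columns:
        raise ValueError("training table must carry the 'arcf' label column")
    X = df[list(FEATURES)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature values must all be finite")
    y = _labels_to_codes(df["arcf"].to_numpy())
    return X, y


def _fit(table: pd.DataFrame, params: TreeParams, k: int | None) -> TreeNode:
    X, y = _extract_xy(table)
    n_total = len(y)
    if n_total < 2:
        raise ValueError(f"need at least 2 records to fit a tree, got {n_total}")
    rng = np.random.default_rng(params.seed)
    p = len(FEATURES)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], minlength=N_CLASSES)
        node = TreeNode(class_counts=counts, support_fraction=len(idx) / n_total)
        if (
            counts.max() == len(idx)  # pure
            or len(idx) < 2 * params.min_leaf
            or (params.max_depth is not None and depth >= params.max_depth)
        ):
            return node
        if k is None:
            attrs: Sequence[int] = range(p)
        else:
            attrs = sorted(rng.choice(p, size=k, replace=False).tolist())
        best_ratio, best_attr, best_thr = 0.0, None, None
        for a in attrs:
            found = _best_split_for_attribute(X[idx, a], y[idx], params.min_leaf)
            if found is not None and found[0] > best_ratio + _GAIN_EPS:
                best_ratio, (_, best_thr), best_attr = found[0], found, a
        if best_attr is None:
            return node
        node.attribute = FEATURES[best_attr]
        node.threshold = best_thr
        mask = X[idx, best_attr] <= best_thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    return build(np.arange(n_total), 0)


def fit_decision_tree(table: pd.DataFrame, params: TreeParams | None = None) -> TreeNode:
    """Fit a gain-ratio decision tree considering every attribute at each node."""
    return _fit(table, params or TreeParams(), k=None)


def fit_random_tree(table: pd.DataFrame, params: TreeParams | None = None) -> TreeNode:
    """Fit a random tree: a seeded random subset of k attributes per node.

    ``params.attributes_per_node`` defaults to ``ceil(sqrt(p))``; with
    ``k = p`` the result is identical to :func:`fit_decision_tree`.
    """
    params = params or TreeParams()
    k = params.attributes_per_node
    if k is None:
        k = math.ceil(math.sqrt(len(FEATURES)))
    return _fit(table, params, k=k)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def _subtree_error_leaves(node: TreeNode) -> tuple[int, int]:
    """(summed leaf misclassification count, number of leaves) of a subtree."""
    if node.is_leaf:
        return node.n - int(node.class_counts.max()), 1
    el, ll = _subtree_error_leaves(node.left)
    er, lr = _subtree_error_leaves(node.right)
    return el + er, ll + lr


def _weakest_links(node: TreeNode, out: list[tuple[float, TreeNode]]) -> tuple[int, int]:
    if node.is_leaf:
        return node.n - int(node.class_counts.max()), 1
    el, ll = _weakest_links(node.left, out)
    er, lr = _weakest_links(node.right, out)
    r_subtree, leaves = el + er, ll + lr
    r_node = node.n - int(node.class_counts.max())
    g = (r_node - r_subtree) / (leaves - 1)
    out.append((g, node))
    return r_subtree, leaves


def cost_complexity_sequence(tree: TreeNode) -> list[TreeNode]:
    """The nested weakest-link subtree sequence, from the full tree to the root leaf.

    Alphas are computed from the training counts stored in the nodes.
    """
    t = tree.copy()
    seq = [t.copy()]
    while not t.is_leaf:
        links: list[tuple[float, TreeNode]] = []
        _weakest_links(t, links)
        alpha = min(g for g, _ in links)
        for g, nd in links:
            if g <= alpha + 1e-12 and not nd.is_leaf:
                nd.collapse()
        seq.append(t.copy())
    return seq


def error_complexity_prune(
    tree: TreeNode, holdout: pd.DataFrame, params: TreeParams | None = None
) -> TreeNode:
    """Cost-complexity pruning with holdout selection.

    Computes the weakest-link subtree sequence from the tree's training
    counts and returns the member minimizing the holdout misclassification
    count; ties go to the subtree with fewer leaves.
    """
    if holdout is None or len(holdout) == 0:
        raise ValueError("holdout set must be non-empty")
    df = feature_frame(holdout)
    truth = _labels_to_codes(df["arcf"].to_numpy())
    seq = cost_complexity_sequence(tree)

    def holdout_errors(t: TreeNode) -> int:
        pred = np.array([int(predict(t, row)) for _, row in df.iterrows()])
        return int((pred != truth).sum())

    return min(seq, key=lambda t: (holdout_errors(t), t.n_leaves()))


def min_support_prune(tree: TreeNode, min_support_fraction: float) -> TreeNode:
    """Merge leaves covering less than ``min_support_fraction`` of the sample.

    When a node's children are both leaves and either one is under-supported,
    the node becomes a leaf over the summed counts; the pass repeats to a
    fixed point, so merges cascade upward through newly-formed leaf pairs.
    An under-supported leaf whose sibling is still internal is left in place
    rather than discarding the sibling subtree.
    """
    if min_support_fraction >= 1:
        raise ValueError(f"min_support_fraction must be < 1, got {min_support_fraction}")
    t = tree.copy()

    def one_pass(node: TreeNode) -> bool:
        if node.is_leaf:
            return False
        changed = one_pass(node.left) | one_pass(node.right)
        if node.left.is_leaf and node.right.is_leaf and (
            node.left.support_fraction < min_support_fraction
            or node.right.support_fraction < min_support_fraction
        ):
            node.collapse()
            return True
        return changed

    while one_pass(t):
        pass
    return t


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _feature_value(rec, name: str) -> float:
    if isinstance(rec, Mapping):
        if name in rec:
            v = rec[name]
        else:
            alias = next((a for a, f in FEATURE_ALIASES.items() if f == name), None)
            if alias is None or alias not in rec:
                raise ValueError(f"record is missing attribute '{name}'")
            v = rec[alias]
    elif hasattr(rec, name):
        v = getattr(rec, name)
    else:
        raise ValueError(f"record is missing attribute '{name}'")
    v = float(v)
    if math.isnan(v):
        raise ValueError(f"attribute '{name}' is NaN; missing values are not supported")
    return v


def predict(tree: TreeNode, rec) -> QualityClass:
    """Route one record (mapping, Series or EnvRecord) to its leaf label."""
    node = tree
    if isinstance(rec, pd.Series):
        rec = rec.to_dict()
    while not node.is_leaf:
        v = _feature_value(rec, node.attribute)
        node = node.left if v <= node.threshold else node.right
    return node.predicted


def predict_table(tree: TreeNode, table: pd.DataFrame) -> np.ndarray:
    """Predicted labels (strings) for every row of a feature table."""
    df = feature_frame(table)
    return np.array([predict(tree, row.to_dict()) for _, row in df.iterrows()], dtype=object)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """One root-to-leaf path collapsed into interval conditions."""

    conditions: tuple[tuple[str, str, float], ...]  # (attribute, '>' or '<=', threshold)
    predicted: QualityClass
    support: float  # fraction of the training sample at the leaf
    confidence: float  # leaf purity: majority count / leaf count

    def __str__(self) -> str:
        if self.conditions:
            conds = " AND ".join(f"{a} {op} {thr:g}" for a, op, thr in self.conditions)
        else:
            conds = "TRUE"
        return (
            f"IF {conds} THEN {self.predicted.label} "
            f"(support {100 * self.support:.1f}%, confidence {100 * self.confidence:.1f}%)"
        )


@dataclass
class RuleSet:
    """Mutually exclusive, exhaustive rules — one per leaf."""

    rules: list[Rule] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __str__(self) -> str:
        return "\n".join(str(r) for r in self.rules)


def extract_rules(tree: TreeNode) -> RuleSet:
    """One rule per leaf; repeated conditions on an attribute collapse to the
    tightest interval (largest lower bound, smallest upper bound)."""
    rules: list[Rule] = []

    def walk(node: TreeNode, bounds: dict[str, list[float]], order: list[str]) -> None:
        if node.is_leaf:
            conditions = []
            for a in order:
                lo, hi = bounds[a]
                if lo > -math.inf:
                    conditions.append((a, ">", lo))
                if hi < math.inf:
                    conditions.append((a, "<=", hi))
            rules.append(
                Rule(
                    conditions=tuple(conditions),
                    predicted=node.predicted,
                    support=node.support_fraction,
                    confidence=float(node.class_counts.max() / node.n),
                )
            )
            return
        a, thr = node.attribute, node.threshold
        if a not in bounds:
            bounds = {**bounds, a: [-math.inf, math.inf]}
            order = order + [a]
        lo, hi = bounds[a]
        walk(node.left, {**bounds, a: [lo, min(hi, thr)]}, order)
        walk(node.right, {**bounds, a: [max(lo, thr), hi]}, order)

    walk(tree, {}, [])
    return RuleSet(rules)


# ---------------------------------------------------------------------------
# Serialization / export
# ---------------------------------------------------------------------------


def tree_to_json(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to its JSON dialect; optionally write it to ``path``."""
    text = json.dumps(tree.to_dict(), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def tree_from_json(source: str | Path) -> TreeNode:
    """Load a tree from a JSON string or file path."""
    text = str(source)
    if isinstance(source, Path) or not text.lstrip().startswith("{"):
        text = Path(source).read_text()
    return TreeNode.from_dict(json.loads(text))


def tree_to_dot(tree: TreeNode, name: str = "tree") -> str:
    """Graphviz DOT rendering of the tree (internal nodes as boxes, leaves as ovals)."""
    lines = [f"digraph {name} {{", "  node [fontname=Helvetica];"]
    counter = 0

    def walk(node: TreeNode) -> int:
        nonlocal counter
        nid = counter
        counter += 1
        if node.is_leaf:
            lines.append(
                f'  n{nid} [label="{node.predicted.label}\\nn={node.n} '
                f'({100 * node.support_fraction:.1f}%)"];'
            )
        else:
            lines.append(
                f'  n{nid} [shape=box, label="{node.attribute} <= {node.threshold:g}"];'
            )
            lid = walk(node.left)
            rid = walk(node.right)
            lines.append(f'  n{nid} -> n{lid} [label="yes"];')
            lines.append(f'  n{nid} -> n{rid} [label="no"];')
        return nid

    walk(tree)
    lines.append("}")
    return "\n".join(lines)
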