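"""Model/Results interface over the tree miner.

`RearingTreeModel` is constructed from a labeled table (the output of
:func:`broilerenv.suitability.label_dataset`, or any frame carrying the five
feature columns and an ``arcf`` label column); ``fit()`` induces the tree and
returns a :class:`RearingTreeResults` holding the fitted tree, its training
diagnostics, prediction/pruning/evaluation methods and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import tree as tree_mod
from .evaluation import EvalReport, confusion_matrix, evaluation_report
from .quality import CLASS_LABELS
from .tree import (
    FEATURES,
    RuleSet,
    TreeNode,
    TreeParams,
    error_complexity_prune,
    extract_rules,
    fit_decision_tree,
    fit_random_tree,
    min_support_prune,
    predict_table,
)

__all__ = ["RearingTreeModel", "RearingTreeResults"]

_OPERATORS = ("decision", "random")


class RearingTreeModel:
    """A rearing-condition tree classifier specification.

    Parameters
    ----------
    data
        Labeled table with the feature columns (canonical or CSV names) and
        the ``arcf`` target.
    operator
        ``"decision"`` (gain-ratio tree over all attributes) or ``"random"``
        (random per-node attribute subsets).
    params
        Induction hyperparameters; defaults to :class:`TreeParams`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        operator: str = "decision",
        params: TreeParams | None = None,
    ) -> None:
        if operator not in _OPERATORS:
            raise ValueError(f"operator must be one of {_OPERATORS}, got {operator!r}")
        df = tree_mod.feature_frame(data)
        missing = [c for c in (*FEATURES, "arcf") if c not in df.columns]
        if missing:
            raise ValueError(f"data is missing columns {missing}")
        self.data = df
        self.operator = operator
        self.params = params or TreeParams()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        operator: str = "decision",
        **param_overrides,
    ) -> "RearingTreeModel":
        """Build a model, passing any :class:`TreeParams` fields as keywords."""
        return cls(data, operator=operator, params=TreeParams(**param_overrides))

    @property
    def nobs(self) -> int:
        return len(self.data)

    def fit(self) -> "RearingTreeResults":
        """Induce the tree and return the results object."""
        fitter = fit_decision_tree if self.operator == "decision" else fit_random_tree
        return RearingTreeResults(self, fitter(self.data, self.params))


class RearingTreeResults:
    """A fitted rearing-condition tree with its diagnostics."""

    def __init__(self, model: RearingTreeModel, tree: TreeNode) -> None:
        self.model = model
        self.tree = tree

    # -- diagnostics ---------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves()

    @property
    def depth(self) -> int:
        return self.tree.depth()

    @property
    def training_accuracy(self) -> float:
        """Percent of training rows routed to a leaf predicting their label."""
        pred = self.predict(self.model.data)
        truth = self.model.data["arcf"].to_numpy()
        return 100.0 * float(np.mean([p.label == t for p, t in zip(pred, truth)]))

    # -- interface -----------------------------------------------------

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return predict_table(self.tree, data)

    def prune(self, holdout: pd.DataFrame) -> "RearingTreeResults":
        """Cost-complexity prune against a disjoint holdout; returns new results."""
        return RearingTreeResults(
            self.model, error_complexity_prune(self.tree, holdout, self.model.params)
        )

    def prune_min_support(self, min_support_fraction: float | None = None) -> "RearingTreeResults":
        """Merge leaves below the support threshold; returns new results."""
        thr = (
            self.model.params.min_support_fraction
            if min_support_fraction is None
            else min_support_fraction
        )
        return RearingTreeResults(self.model, min_support_prune(self.tree, thr))

    def evaluate(self, test: pd.DataFrame, kappa_threshold: float = 0.60) -> EvalReport:
        """Confusion matrix, accuracy/precision/recall/kappa on a test table."""
        pred = self.predict(test)
        cm = confusion_matrix(
            tree_mod.feature_frame(test)["arcf"].to_numpy(),
            np.array([p.label for p in pred], dtype=object),
        )
        return evaluation_report(cm, kappa_threshold)

    def rules(self) -> RuleSet:
        return extract_rules(self.tree)

    def summary(self) -> str:
        counts = self.tree.class_counts
        dist = ", ".join(f"{lbl}={int(c)}" for lbl, c in zip(CLASS_LABELS, counts))
        rows = [
            ("Operator:", f"{self.model.operator}-tree"),
            ("No. observations:", str(self.nobs)),
            ("Features:", ", ".join(FEATURES)),
            ("Leaves:", str(self.n_leaves)),
            ("Depth:", str(self.depth)),
            ("Training accuracy:", f"{self.training_accuracy:.2f}%"),
            ("Class counts:", dist),
            ("Min leaf size:", str(self.model.params.min_leaf)),
            ("Seed:", str(self.model.params.seed)),
        ]
        width = max(len(k) for k, _ in rows) + 2
        body = "\n".join(f"{k:<{width}}{v}" for k, v in rows)
        title = "Rearing-Condition Tree Classifier Results"
        rule = "=" * max(len(title), width + 24)
        return f"{title}\n{rule}\n{body}\n{rule}"
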