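"""Random-forest variable importance with out-of-bag permutation.

The forest is a bootstrap ensemble of CART trees (Gini splitting,
``mtry = floor(sqrt(p))`` candidate variables per split).  The bootstrap
is drawn in-repo so every tree's out-of-bag (OOB) rows are first-class
objects: permutation importance — overall and per class (absent /
present) — is computed against those OOB sets, and Gini importance is
accumulated from each tree's split nodes as the impurity decrease
weighted by the fraction of samples reaching the node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RandomForest",
    "ImportanceTable",
    "fit_forest",
    "permutation_importance",
    "gini_importance",
    "importance_table",
]


@dataclass
class RandomForest:
    """Bootstrap CART ensemble with retained OOB index sets."""

    trees: list = field(default_factory=list)
    oob_sets: list = field(default_factory=list)  # per-tree OOB row indices
    n_features: int = 0
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over trees."""
        votes = np.zeros((len(X), len(self.classes)))
        for tree in self.trees:
            pred = tree.predict(X).astype(int)
            for ci, c in enumerate(self.classes):
                votes[:, ci] += pred == c
        return self.classes[votes.argmax(axis=1)]

    def oob_error(self, X: np.ndarray, y: np.ndarray) -> float:
        """OOB misclassification rate (rows never OOB are skipped)."""
        votes = np.zeros((len(X), len(self.classes)))
        for tree, oob in zip(self.trees, self.oob_sets):
            if oob.size == 0:
                continue
            pred = tree.predict(X[oob]).astype(int)
            for ci, c in enumerate(self.classes):
                votes[oob, ci] += pred == c
        seen = votes.sum(axis=1) > 0
        pred = self.classes[votes[seen].argmax(axis=1)]
        return float((pred != y[seen]).mean())


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
) -> RandomForest:
    """Fit a bootstrap CART forest with Gini splitting.

    Each tree gets an n-sized bootstrap sample; its out-of-bag rows are
    stored.  Deterministic given the seed.  Constant features are
    tolerated (they are simply never informative splits).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    if mtry is None:
        mtry = max(1, int(math.floor(math.sqrt(p))))
    rng = np.random.default_rng(seed)
    forest = RandomForest(n_features=p, classes=np.unique(y))
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        forest.trees.append(tree)
        forest.oob_sets.append(oob)
    return forest


def permutation_importance(
    forest: RandomForest, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Mean decrease in OOB accuracy when each variable is permuted.

    Per tree and variable: OOB accuracy before minus after shuffling
    that variable's OOB values; averaged over trees.  The per-class
    columns restrict the accuracy difference to each class's OOB rows,
    matching the absent/present breakdown of a per-class importance
    report.  Trees with an empty OOB set are skipped (count reported in
    ``attrs['skipped_trees']``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    p = forest.n_features
    overall = np.zeros(p)
    per_class = {int(c): np.zeros(p) for c in forest.classes}
    used = 0
    skipped = 0
    for tree, oob in zip(forest.trees, forest.oob_sets):
        if oob.size == 0:
            skipped += 1
            continue
        used += 1
        Xo, yo = X[oob], y[oob]
        base_hit = tree.predict(Xo).astype(int) == yo
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            perm_hit = tree.predict(Xp).astype(int) == yo
            overall[j] += base_hit.mean() - perm_hit.mean()
            for c in forest.classes:
                mask = yo == c
                if mask.any():
                    per_class[int(c)][j] += (
                        base_hit[mask].mean() - perm_hit[mask].mean()
                    )
    if used == 0:
        raise ValueError("no tree has a non-empty OOB set")
    df = pd.DataFrame(
        {
            "importance_absent": per_class.get(0, np.zeros(p)) / used,
            "importance_present": per_class.get(1, np.zeros(p)) / used,
            "mean_decrease_accuracy": overall / used,
        }
    )
    df.attrs["skipped_trees"] = skipped
    return df


def gini_importance(forest: RandomForest) -> np.ndarray:
    """Mean decrease in Gini impurity per variable.

    For each split node: (parent impurity - weighted child impurity)
    scaled by the fraction of the tree's samples reaching the node;
    summed per variable within a tree and averaged over trees.
    Always >= 0; a variable never split on scores exactly 0.
    """
    p = forest.n_features
    total = np.zeros(p)
    for tree in forest.trees:
        t = tree.tree_
        imp = np.zeros(p)
        n_root = t.weighted_n_node_samples[0]
        for node in range(t.node_count):
            left, right = t.children_left[node], t.children_right[node]
            if left == -1:  # leaf
                continue
            w = t.weighted_n_node_samples
            decrease = (
                w[node] * t.impurity[node]
                - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]
            ) / n_root
            imp[t.feature[node]] += decrease
        total += imp
    return total / len(forest.trees)


def importance_table(
    forest: RandomForest,
    X: np.ndarray,
    y: np.ndarray,
    variable_names: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable importance report, sorted by descending mean
    decrease in accuracy: absent / present / overall accuracy decrease
    and Gini decrease."""
    perm = permutation_importance(forest, X, y, seed=seed)
    perm.insert(0, "variable", variable_names)
    perm["mean_decrease_gini"] = gini_importance(forest)
    return perm.sort_values(
        "mean_decrease_accuracy", ascending=False
    ).reset_index(drop=True)
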