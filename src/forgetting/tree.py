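"""C4.5-family gain-ratio decision tree over study characteristics.

A small guide classifier: given a study's characteristics, predict which
retention pattern is likely to describe its data.  Splits are binary
thresholds on numeric predictors chosen by information gain ratio (gain
normalised by the split's own entropy, the C4.5 criterion), with
configurable depth and minimum leaf size.  0/1-coded categorical predictors
work as numeric features.  This is a guide, not a verdict: it is trained on
noisy, possibly biased corpora.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GuideTree", "TreeNode", "train_guide_tree", "predict_category"]


@dataclass
class TreeNode:
    """One node: either a leaf (class distribution) or a threshold split."""

    counts: dict[str, int]
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None   # feature <= threshold
    right: Optional["TreeNode"] = None  # feature > threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> str:
        # deterministic tie-break: alphabetical among maxima
        top = max(self.counts.values())
        return sorted(c for c, n in self.counts.items() if n == top)[0]

    @property
    def distribution(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {c: n / total for c, n in sorted(self.counts.items())}

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "counts": dict(self.counts)}
        return {
            "leaf": False,
            "feature": self.feature,
            "threshold": self.threshold,
            "counts": dict(self.counts),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class GuideTree:
    """A fitted gain-ratio tree plus its training metadata."""

    root: TreeNode
    features: tuple[str, ...]
    max_depth: int
    min_leaf: int
    classes: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": list(self.features),
                "max_depth": self.max_depth,
                "min_leaf": self.min_leaf,
                "classes": list(self.classes),
                "root": self.root.to_dict(),
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}-> {node.prediction} {node.distribution}")
                return
            lines.append(f"{pad}if {node.feature} <= {node.threshold:.6g}:")
            walk(node.left, indent + 1)
            lines.append(f"{pad}else:")
            walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _entropy(labels: np.ndarray) -> float:
    counts = np.array(list(Counter(labels.tolist()).values()), dtype=float)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _best_split(
    X: np.ndarray, y: np.ndarray, features: Sequence[str], min_leaf: int
) -> Optional[tuple[int, float, float]]:
    """Best (feature index, threshold, gain ratio) over midpoint candidates."""
    n = y.size
    parent = _entropy(y)
    best: Optional[tuple[int, float, float]] = None
    for fi in range(X.shape[1]):
        col = X[:, fi]
        order = np.argsort(col, kind="stable")
        sorted_col, sorted_y = col[order], y[order]
        values = np.unique(sorted_col)
        if values.size < 2:
            continue
        thresholds = (values[:-1] + values[1:]) / 2.0
        for thr in thresholds:
            left = sorted_col <= thr
            nl = int(left.sum())
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            gain = parent - (
                nl / n * _entropy(sorted_y[left]) + nr / n * _entropy(sorted_y[~left])
            )
            pl, pr = nl / n, nr / n
            split_info = -(pl * math.log2(pl) + pr * math.log2(pr))
            if split_info <= 0 or gain <= 1e-12:
                continue
            ratio = gain / split_info
            if best is None or ratio > best[2]:
                best = (fi, float(thr), ratio)
    return best


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    depth: int,
    max_depth: int,
    min_leaf: int,
) -> TreeNode:
    counts = dict(Counter(y.tolist()))
    node = TreeNode(counts=counts)
    if depth >= max_depth or len(counts) == 1 or y.size < 2 * min_leaf:
        return node
    split = _best_split(X, y, features, min_leaf)
    if split is None:
        return node
    fi, thr, _ = split
    mask = X[:, fi] <= thr
    node.feature = features[fi]
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], features, depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], y[~mask], features, depth + 1, max_depth, min_leaf)
    return node


def train_guide_tree(
    frame: pd.DataFrame,
    labels: Sequence[str],
    predictors: Sequence[str],
    max_depth: int = 5,
    min_leaf: int = 5,
) -> GuideTree:
    """Train a gain-ratio tree predicting pattern from characteristics."""
    y = np.asarray([str(l) for l in labels])
    if y.size < 50:
        warnings.warn(
            f"training on {y.size} datasets (< 50); the guide tree will be unstable"
        )
    X = frame.loc[:, list(predictors)].astype(float).to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in predictors")
    root = _grow(X, y, tuple(predictors), 0, max_depth, min_leaf)
    return GuideTree(
        root=root,
        features=tuple(predictors),
        max_depth=max_depth,
        min_leaf=min_leaf,
        classes=tuple(sorted(set(y.tolist()))),
    )


def predict_category(
    tree: GuideTree, record: Mapping[str, float]
) -> tuple[str, dict[str, float]]:
    """Predict a pattern for one study; returns (category, leaf distribution).

    A missing or non-finite predictor value routes to the majority child with
    a warning.
    """
    node = tree.root
    while not node.is_leaf:
        value = record.get(node.feature, float("nan"))
        try:
            value = float(value)
        except (TypeError, ValueError):
            value = float("nan")
        if not math.isfinite(value):
            warnings.warn(
                f"missing value for {node.feature!r}; routing to majority child"
            )
            nl = sum(node.left.counts.values())
            nr = sum(node.right.counts.values())
            node = node.left if nl >= nr else node.right
        else:
            node = node.left if value <= node.threshold else node.right
    return node.prediction, node.distribution
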