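"""CART-style regression tree for rule extraction from predicted incidence.

The model's six-year cumulative incidence is a black-box function of the
covariates; a small regression tree fitted to the per-subject predictions
turns it into readable rules ("pN in {pN2-pN3}?  yes -> ...").  This is plain
greedy binary recursive partitioning minimizing within-node sum of squared
errors, with threshold stopping and no pruning — the tree is an exploratory
summary, not an inferential model.

Candidate splits: for a categorical covariate, every nonempty proper subset of
its levels (complement-duplicates skipped); for a continuous covariate,
thresholds at midpoints between consecutive observed values.  Ties break
deterministically: first covariate in schema order, then lexicographically
smallest level subset (or smallest threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survdata import Covariate, SurvivalCohort

__all__ = ["TreeNode", "fit_tree", "predict_tree", "render_tree"]


@dataclass
class TreeNode:
    """A node: either a leaf (n, mean) or an internal split with two children.

    For a categorical split, ``subset`` lists the levels answering "yes"
    (left child); for a continuous split, left means value <= ``threshold``.
    """

    n: int
    mean: float
    depth: int = 0
    covariate: str | None = None
    subset: tuple[str, ...] | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def question(self) -> str:
        if self.is_leaf:
            return "<leaf>"
        if self.subset is not None:
            return f"{self.covariate} in {{{', '.join(self.subset)}}}?"
        return f"{self.covariate} <= {self.threshold:g}?"

    def to_dict(self) -> dict:
        d = {"n": self.n, "mean": self.mean, "depth": self.depth}
        if not self.is_leaf:
            d["covariate"] = self.covariate
            if self.subset is not None:
                d["subset"] = list(self.subset)
            else:
                d["threshold"] = self.threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreeNode":
        node = cls(n=int(d["n"]), mean=float(d["mean"]), depth=int(d.get("depth", 0)))
        if "covariate" in d:
            node.covariate = d["covariate"]
            node.subset = tuple(d["subset"]) if "subset" in d else None
            node.threshold = d.get("threshold")
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _categorical_subsets(levels: Sequence[str]) -> list[tuple[str, ...]]:
    """Nonempty proper level subsets, one per binary partition.

    A subset and its complement define the same split; keep only subsets that
    contain the first level, which also fixes the tie-break order.
    """
    levels = list(levels)
    out = []
    rest = levels[1:]
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            s = (levels[0],) + combo
            if len(s) < len(levels):
                out.append(s)
    return out


def _best_split(
    df: pd.DataFrame,
    y: np.ndarray,
    schema: Sequence[Covariate],
    min_node_size: int,
):
    """Best (SSE-reduction) admissible split of this node, or None."""
    parent_sse = _sse(y)
    best = None  # (reduction, cov_index, subset_or_None, threshold_or_None, mask)
    for ci, cov in enumerate(schema):
        col = df[cov.name]
        if cov.kind == "categorical":
            vals = col.astype(str).to_numpy()
            for subset in _categorical_subsets(cov.levels):
                mask = np.isin(vals, subset)
                nl = int(mask.sum())
                if nl < min_node_size or y.size - nl < min_node_size:
                    continue
                red = parent_sse - _sse(y[mask]) - _sse(y[~mask])
                if best is None or red > best[0] + 1e-12:
                    best = (red, ci, subset, None, mask)
        else:
            vals = col.to_numpy(float)
            uniq = np.unique(vals)
            for lo, hi in zip(uniq[:-1], uniq[1:]):
                thr = (lo + hi) / 2.0
                mask = vals <= thr
                nl = int(mask.sum())
                if nl < min_node_size or y.size - nl < min_node_size:
                    continue
                red = parent_sse - _sse(y[mask]) - _sse(y[~mask])
                if best is None or red > best[0] + 1e-12:
                    best = (red, ci, None, thr, mask)
    return best


def fit_tree(
    cohort: SurvivalCohort,
    responses: np.ndarray,
    min_node_size: int = 10,
    min_improvement: float = 0.01,
) -> TreeNode:
    """Greedy regression tree on per-subject responses.

    A split is accepted only if both children have at least ``min_node_size``
    subjects and the SSE reduction is at least ``min_improvement`` times the
    *root* SSE.  With fewer than ``2 * min_node_size`` subjects the tree is a
    single leaf.
    """
    y = np.asarray(responses, float)
    if y.size != cohort.n:
        raise ValueError("one response per subject required")
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    root_sse = _sse(y)
    threshold = min_improvement * root_sse

    def grow(df: pd.DataFrame, yy: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(n=yy.size, mean=float(yy.mean()), depth=depth)
        if yy.size < 2 * min_node_size or _sse(yy) == 0.0:
            return node
        best = _best_split(df, yy, cohort.schema, min_node_size)
        if best is None or best[0] < threshold or best[0] <= 0:
            return node
        red, ci, subset, thr, mask = best
        node.covariate = cohort.schema[ci].name
        node.subset = subset
        node.threshold = thr
        node.left = grow(df.loc[mask], yy[mask], depth + 1)
        node.right = grow(df.loc[~mask], yy[~mask], depth + 1)
        return node

    return grow(cohort.data, y, 0)


def predict_tree(tree: TreeNode, covariates: Mapping) -> float:
    """Route one subject's covariates to a leaf and return its mean response.

    An unseen categorical level follows the branch NOT matching the listed
    subset (the explicit "other" rule).
    """
    node = tree
    while not node.is_leaf:
        if node.subset is not None:
            go_left = str(covariates[node.covariate]) in node.subset
        else:
            go_left = float(covariates[node.covariate]) <= node.threshold
        node = node.left if go_left else node.right
    return node.mean


def render_tree(tree: TreeNode, digits: int = 4) -> str:
    """Indented text rendering with n and mean response per leaf."""
    lines: list[str] = []

    def walk(node: TreeNode, prefix: str) -> None:
        if node.is_leaf:
            lines.append(f"{prefix}leaf: n={node.n}, mean={node.mean:.{digits}f}")
            return
        lines.append(f"{prefix}{node.question()}")
        lines.append(f"{prefix}  yes:")
        walk(node.left, prefix + "    ")
        lines.append(f"{prefix}  no:")
        walk(node.right, prefix + "    ")

    walk(tree, "")
    return "\n".join(lines)
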