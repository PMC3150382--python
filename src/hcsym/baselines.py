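"""Comparison orderings: HC default, HC-PCA, and an exhaustive orbit search.

HC-PCA flips internal nodes against an external one-dimensional reference:
each sample's projection onto the first principal component of the data.
A node is flipped iff the mean reference score of its right subtree is
smaller than that of its left subtree, so scores run ascending left to
right wherever the clade structure allows.

The exhaustive orbit search maximises the sum of similarities between
adjacent leaves over all 2^(n-1) flip states.  That objective is the one
optimal-leaf-ordering methods target; here it serves purely as a small-n
optimality reference in benchmarks, not as a production algorithm.
"""

from __future__ import annotations

import itertools
import os
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrices import SimilarityMatrix
from .tree import Dendrogram, Node, leaf_order


def pc1_scores(data: pd.DataFrame, standardize: bool = False) -> dict[str, float]:
    """Projection of each sample (row) onto the first principal axis.

    Columns are centered (optionally scaled to unit variance); the axis sign
    is fixed so its largest-magnitude loading is positive, making the scores
    deterministic.  Constant data has no principal axis and is rejected.
    """
    x = data.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if np.isnan(x).any():
        raise ValidationError("data contains missing values")
    xc = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        xc = xc[:, keep] / sd[keep]
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValidationError("constant data: zero variance, no principal axis")
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    scores = xc @ v
    return {str(lab): float(sc) for lab, sc in zip(data.index, scores)}


def order_by_reference(tree: Dendrogram, ref: Mapping[str, float]) -> Dendrogram:
    """Flip nodes so the reference scores ascend left to right.

    Returns a reordered copy; each internal node is flipped iff the mean
    score of its right subtree is strictly below its left subtree's.
    """
    missing = tree.leaf_ids - set(ref)
    if missing:
        raise ValidationError(f"reference is missing leaves: {sorted(missing)[:5]}")
    work = tree.copy()
    lists = work.leaf_lists()
    for nd in work.internal_nodes():
        mean_l = np.mean([ref[x] for x in lists[id(nd.left)]])
        mean_r = np.mean([ref[x] for x in lists[id(nd.right)]])
        if mean_r < mean_l:
            work.flip(nd)
    return work


def hc_pca(tree: Dendrogram, data: pd.DataFrame,
           standardize: bool = False) -> Dendrogram:
    """HC-PCA: order the tree against the samples' PC1 projections."""
    return order_by_reference(tree, pc1_scores(data, standardize))


def write_reference_scores(ref: Mapping[str, float],
                           path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for leaf in sorted(ref):
            fh.write(f"{leaf}\t{ref[leaf]:.17g}\n")


def best_adjacent_similarity_order(tree: Dendrogram, sim: SimilarityMatrix
                                   ) -> tuple[tuple[str, ...], float]:
    """Exhaustively search the flip orbit for the leaf order maximising the
    sum of adjacent-leaf similarities.  Exponential; small n only."""
    nodes = tree.internal_nodes()
    if len(nodes) > 12:
        raise ValidationError("exhaustive orbit search limited to n <= 13 leaves")
    best_order: tuple[str, ...] | None = None
    best_score = -np.inf
    for flips in itertools.product((False, True), repeat=len(nodes)):
        for nd, f in zip(nodes, flips):
            if f:
                tree.flip(nd)
        order = tuple(leaf_order(tree))
        idx = sim.indexer(order)
        score = float(sim.values[idx[:-1], idx[1:]].sum())
        if score > best_score or (score == best_score and
                                  (best_order is None or order < best_order)):
            best_score, best_order = score, order
        for nd, f in zip(nodes, flips):
            if f:
                tree.flip(nd)
    return best_order, best_score
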