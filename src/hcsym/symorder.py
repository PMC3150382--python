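"""Leaf reordering by bilateral symmetric distance (HC-SYM).

The idea: at a chosen internal node with left subtree L and right subtree R,
similar objects from the two sides should sit at the shared boundary.  With
L displayed as x_1..x_m and R as y_1..y_n, the *symmetric pairs* are
(x_m, y_1), (x_{m-1}, y_2), ... — the i-th leaf in from the boundary on each
side.  The bilateral symmetric distance is

    B = sum_{i=1..k} d(x_{m-i+1}, y_i),        k = min(m, n),

and B is minimised (over orders consistent with a given matching) when the
pair distances are nondecreasing from the boundary outwards.

``symOrder`` builds a target ordering (the SYM vector) greedily: repeatedly
take the globally closest unpaired (x in L, y in R) pair; the first pair
sits innermost, so pair distances are nondecreasing by construction.  On
the larger side the leftover (unpaired) members are appended outside the
paired block, sorted by their mean distance to the paired members of their
own cluster (optionally, to the whole adjacent cluster).  Finally every
internal node under the target is flipped iff the mean SYM position of its
right subtree's leaves precedes that of its left subtree's — which realises
the SYM arrangement as closely as the fixed clade structure allows, and
never alters that structure.

``HC-SYM`` applies symOrder top-down at every internal node of depth less
than ``level`` that passes two eligibility filters: balance
min(|L|,|R|)/max(|L|,|R|) >= br and size min(|L|,|R|)/n_total >= sr.
Defaults: level=1, br=0.3, sr=0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ValidationError
from .matrices import DistanceMatrix
from .tree import Dendrogram, Node

UnpairedMode = Literal["own", "adjacent"]


@dataclass(frozen=True)
class PairingResult:
    """Greedy symmetric pairing of two clusters.

    ``pairs`` lists (x, y, d) innermost to outermost; distances are
    nondecreasing by construction of the greedy selection.
    """

    pairs: tuple[tuple[str, str, float], ...]

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def B(self) -> float:
        return float(sum(d for _, _, d in self.pairs))

    def __post_init__(self):
        ds = [d for _, _, d in self.pairs]
        if any(b < a for a, b in zip(ds, ds[1:])):
            raise AssertionError(
                "pair distances must be nondecreasing innermost to outermost")


@dataclass(frozen=True)
class SymVector:
    """Target leaf arrangement; ``rank`` maps leaf id to position 1..n."""

    order: tuple[str, ...]
    rank: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValidationError("SYM vector has duplicate leaves")
        object.__setattr__(self, "rank",
                           {lab: i + 1 for i, lab in enumerate(self.order)})


@dataclass(frozen=True)
class HCSymParams:
    level: int = 1
    br: float = 0.3
    sr: float = 0.03
    unpaired_mode: UnpairedMode = "own"

    def __post_init__(self):
        if self.level < 1:
            raise ValidationError("level must be >= 1")
        if not 0.0 <= self.br <= 1.0:
            raise ValidationError("br must be in [0, 1]")
        if not 0.0 <= self.sr <= 0.5:
            raise ValidationError("sr must be in [0, 0.5]")
        if self.unpaired_mode not in ("own", "adjacent"):
            raise ValidationError("unpaired_mode must be 'own' or 'adjacent'")


def bilateral_symmetric_distance(orderL: Sequence[str], orderR: Sequence[str],
                                 dist: DistanceMatrix) -> float:
    """B for the displayed orders: pair i-th from the right end of L with
    the i-th from the left end of R, k = min(|L|, |R|) pairs."""
    if not orderL or not orderR:
        raise ValidationError("both clusters must be nonempty")
    if set(orderL) & set(orderR):
        raise ValidationError("clusters overlap")
    k = min(len(orderL), len(orderR))
    li = dist.indexer(orderL[-k:][::-1])   # innermost first
    ri = dist.indexer(orderR[:k])
    return float(dist.values[li, ri].sum())


def greedy_symmetric_pairing(L_leaves: Iterable[str], R_leaves: Iterable[str],
                             dist: DistanceMatrix) -> PairingResult:
    """Sequentially select the minimum-distance (x in L, y in R) pair among
    the still-unpaired members, k = min(|L|,|R|) times.

    Equal-distance candidates are broken by the lexicographically smallest
    (x, y) id pair, so the result is deterministic.
    """
    L = sorted(set(L_leaves))
    R = sorted(set(R_leaves))
    if not L or not R:
        raise ValidationError("both clusters must be nonempty")
    sub = dist.values[np.ix_(dist.indexer(L), dist.indexer(R))].copy()
    pairs = []
    for _ in range(min(len(L), len(R))):
        d = sub.min()
        hits = np.argwhere(sub == d)
        # L and R are sorted, so row-major order of hits is (x, y)-lexicographic
        i, j = hits[0]
        pairs.append((L[i], R[j], float(d)))
        sub[i, :] = np.inf
        sub[:, j] = np.inf
    return PairingResult(tuple(pairs))


def order_unpaired(unpaired: Iterable[str], ordered_core: Sequence[str],
                   dist: DistanceMatrix,
                   side: Literal["left", "right"]) -> list[str]:
    """Arrange leftover members outward from the paired block.

    Each member is scored by its mean distance to ``ordered_core``; smaller
    scores sit closer to the block.  For ``side='left'`` the returned list
    is meant to be prepended (so it runs outermost to innermost); for
    ``side='right'`` appended (innermost to outermost).
    """
    unpaired = sorted(set(unpaired))
    if not unpaired:
        return []
    if not ordered_core:
        raise ValidationError("cannot score unpaired members against an empty core")
    if set(unpaired) & set(ordered_core):
        raise ValidationError("unpaired members overlap the ordered core")
    core_idx = dist.indexer(ordered_core)
    scores = dist.values[np.ix_(dist.indexer(unpaired), core_idx)].mean(axis=1)
    ranked = [u for _, u in sorted(zip(scores, unpaired))]
    if side == "left":
        ranked.reverse()
    elif side != "right":
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    return ranked


def build_sym_vector(L_leaves: Iterable[str], R_leaves: Iterable[str],
                     dist: DistanceMatrix,
                     unpaired_mode: UnpairedMode = "own") -> SymVector:
    """Assemble the SYM target order for one L/R split.

    Central 2k positions come from the greedy pairing (pair 1 innermost);
    the larger side's unpaired members are placed outside its block, scored
    against the paired members of their own cluster (``own``) or against the
    entire adjacent cluster (``adjacent``).
    """
    L = sorted(set(L_leaves))
    R = sorted(set(R_leaves))
    pairing = greedy_symmetric_pairing(L, R, dist)
    xs = [x for x, _, _ in pairing.pairs]
    ys = [y for _, y, _ in pairing.pairs]
    left_block = xs[::-1]    # pair k .. pair 1
    right_block = ys         # pair 1 .. pair k
    left_extra: list[str] = []
    right_extra: list[str] = []
    rest_L = set(L) - set(xs)
    rest_R = set(R) - set(ys)
    if rest_L:
        core = R if unpaired_mode == "adjacent" else xs
        left_extra = order_unpaired(rest_L, core, dist, "left")
    if rest_R:
        core = L if unpaired_mode == "adjacent" else ys
        right_extra = order_unpaired(rest_R, core, dist, "right")
    return SymVector(tuple(left_extra + left_block + right_block + right_extra))


def _flip_decisions(tree: Dendrogram, node: Node,
                    sym: SymVector) -> list[tuple[Node, bool]]:
    lists = tree.leaf_lists(node)
    if set(lists[id(node)]) != set(sym.order):
        raise ValidationError("SYM vector does not cover the subtree's leaves")
    rank = sym.rank
    out = []
    for nd in tree.internal_nodes(node):
        mean_l = sum(rank[x] for x in lists[id(nd.left)]) / len(lists[id(nd.left)])
        mean_r = sum(rank[x] for x in lists[id(nd.right)]) / len(lists[id(nd.right)])
        out.append((nd, mean_r < mean_l))
    return out


def apply_sym_flips(tree: Dendrogram, node: Node, sym: SymVector) -> Dendrogram:
    """Flip, in place, every internal node under ``node`` whose right
    subtree's mean SYM position precedes its left subtree's.

    Decisions are independent across nodes because flipping never changes
    subtree membership.  Equal means leave the node untouched.  The clade
    signature is preserved.
    """
    for nd, flip in _flip_decisions(tree, node, sym):
        if flip:
            tree.flip(nd)
    return tree


def sym_order(tree: Dendrogram, node: Node, dist: DistanceMatrix,
              unpaired_mode: UnpairedMode = "own",
              log: list | None = None) -> Dendrogram:
    """symOrder at one node: build the SYM vector from its left/right
    subtrees, then realise it by flips.  Mutates ``tree`` in place."""
    if node.is_leaf:
        raise ValidationError("symOrder target must be an internal node")
    lists = tree.leaf_lists(node)
    L = lists[id(node.left)]
    R = lists[id(node.right)]
    sym = build_sym_vector(L, R, dist, unpaired_mode)
    decisions = _flip_decisions(tree, node, sym)
    for nd, flip in decisions:
        if flip:
            tree.flip(nd)
    if log is not None:
        pairing = greedy_symmetric_pairing(L, R, dist)
        log.append({
            "subtree_size": len(lists[id(node)]),
            "left_size": len(L),
            "right_size": len(R),
            "k": pairing.k,
            "B": pairing.B,
            "pair_distances": [d for _, _, d in pairing.pairs],
            "n_flips": sum(flip for _, flip in decisions),
            "n_nodes_examined": len(decisions),
        })
    return tree


def select_target_nodes(tree: Dendrogram, params: HCSymParams) -> list[Node]:
    """Internal nodes at depth < level passing the br and sr filters,
    in pre-order (parents before descendants)."""
    depths = tree.depths()
    sizes = {k: len(v) for k, v in tree.leaf_lists().items()}
    n_total = tree.n_leaves
    out = []
    for nd in tree.internal_nodes():
        if depths[id(nd)] >= params.level:
            continue
        lo = min(sizes[id(nd.left)], sizes[id(nd.right)])
        hi = max(sizes[id(nd.left)], sizes[id(nd.right)])
        if lo / hi < params.br:
            continue
        if lo / n_total < params.sr:
            continue
        out.append(nd)
    return out


def hc_sym(tree: Dendrogram, dist: DistanceMatrix,
           params: HCSymParams | None = None,
           log: list | None = None) -> Dendrogram:
    """HC-SYM: symOrder applied top-down to each selected node.

    Returns a reordered copy; the input tree is untouched.  The set of
    selected nodes is fixed up front (flip-invariant membership); flips by a
    parent may swap a descendant's left/right roles before its own pass,
    which the sequential top-down application handles naturally.
    """
    params = params or HCSymParams()
    missing = tree.leaf_ids - set(dist.labels)
    if missing:
        raise ValidationError(
            f"distance matrix is missing leaves: {sorted(missing)[:5]}")
    work = tree.copy()
    targets = select_target_nodes(work, params)
    depths = work.depths()
    for nd in targets:
        entry_count = len(log) if log is not None else 0
        sym_order(work, nd, dist, params.unpaired_mode, log)
        if log is not None and len(log) > entry_count:
            log[-1]["depth"] = depths[id(nd)]
    return work


def reorder(tree: Dendrogram, dist: DistanceMatrix, *, level: int = 1,
            br: float = 0.3, sr: float = 0.03,
            unpaired_mode: UnpairedMode = "own") -> tuple[Dendrogram, list[dict]]:
    """Primary API: HC-SYM with an execution log of every node visited."""
    log: list[dict] = []
    out = hc_sym(tree, dist, HCSymParams(level, br, sr, unpaired_mode), log)
    return out, log
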