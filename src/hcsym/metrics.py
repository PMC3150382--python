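"""Evaluation of a leaf ordering: supervised seriation rate, unsupervised
generalized anti-Robinson scores.

Supervised.  When class labels are known, the quality of a displayed order
is how tightly each class groups along the line.  With leaves numbered
1..n left to right, the linear distance ld of two leaves is the absolute
difference of their positions.  The seriation score of a class c is

    S(c) = sum over unordered within-class pairs of 1 / ld(x1, x2),

which is largest exactly when the class forms one contiguous block; a
contiguous block of m leaves scores S_max(m) = sum_{g=1..m-1} (m-g)/g.
The seriation rate normalises over all classes:

    SR = sum_c S(c) / sum_c S_max(|c|),    0 <= SR <= 1,

with SR = 1 iff every class is contiguous.  The reciprocal-pair form of
S(c) is this package's concrete rendering of the score: it is the simplest
pairwise statistic with the required behaviour (positive, maximised exactly
at adjacency, normalisable so that SR = 1 iff grouping is error-free), and
it is isolated here so an alternative decay in ld could be swapped in.

Unsupervised.  A symmetric similarity matrix R is (perfectly) Robinson when
values never decrease toward the diagonal: r_ij <= r_ik for j < k < i and
r_ij >= r_ik for i < j < k.  For a permuted proximity matrix P the
generalized anti-Robinson score GAR(w) counts violations of that pattern
restricted to index windows of span w: lower-triangle triples j < k < i
with i - j <= w where p_ij > p_ik, plus the mirrored upper-triangle
triples.  Ties are compliant, and counts are raw (unnormalised), so GAR is
monotone nondecreasing in w and zero for a Robinson matrix at every w.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .matrices import SimilarityMatrix


class ClassLabels:
    """Leaf id -> class label map."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise ValidationError("empty label set")
        self.mapping = {str(k): str(v) for k, v in mapping.items()}

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def k_classes(self) -> int:
        return len(set(self.mapping.values()))

    def members(self, cls: str) -> set[str]:
        return {x for x, c in self.mapping.items() if c == cls}

    def __getitem__(self, leaf: str) -> str:
        try:
            return self.mapping[leaf]
        except KeyError:
            raise ValidationError(f"no class label for leaf {leaf!r}") from None

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ClassLabels":
        mapping = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 2 tab-separated columns")
                if parts[0] in mapping:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate leaf id {parts[0]!r}")
                mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for leaf in sorted(self.mapping):
                fh.write(f"{leaf}\t{self.mapping[leaf]}\n")


def linear_distance(pos1: int, pos2: int) -> int:
    """|pos1 - pos2|: 1 for adjacent leaves, n-1 for the two ends."""
    if pos1 == pos2:
        raise ValidationError("linear distance of a leaf with itself is undefined")
    return abs(pos1 - pos2)


def seriation_score(order: Sequence[str], members: Iterable[str]) -> float:
    """S(c): sum of reciprocal linear distances over within-class pairs."""
    pos = {lab: i + 1 for i, lab in enumerate(order)}
    ps = []
    for m in members:
        if m not in pos:
            raise ValidationError(f"class member {m!r} missing from the order")
        ps.append(pos[m])
    ps.sort()
    return float(sum(1.0 / (ps[j] - ps[i])
                     for i in range(len(ps)) for j in range(i + 1, len(ps))))


def max_seriation_score(m: int) -> float:
    """S(c) of a contiguous block of m leaves: sum_{g=1..m-1} (m-g)/g."""
    return float(sum((m - g) / g for g in range(1, m)))


def seriation_rate(order: Sequence[str], labels: ClassLabels) -> float:
    """SR in [0, 1]; 1 iff every class occupies one contiguous block.

    Degenerate case: if every class is a singleton both sums are 0 and the
    order is vacuously perfect, so SR = 1.
    """
    for leaf in order:
        labels[leaf]  # raises on unlabeled leaf
    num = den = 0.0
    for cls in labels.classes:
        members = labels.members(cls) & set(order)
        if not members:
            continue
        num += seriation_score(order, members)
        den += max_seriation_score(len(members))
    return num / den if den else 1.0


def seriation_report(order: Sequence[str], labels: ClassLabels) -> dict:
    """Per-class S(c), S_max and the overall SR, as one JSON-able dict."""
    per_class = {}
    for cls in labels.classes:
        members = labels.members(cls) & set(order)
        per_class[cls] = {
            "size": len(members),
            "S": seriation_score(order, members) if members else 0.0,
            "S_max": max_seriation_score(len(members)),
        }
    return {"SR": seriation_rate(order, labels), "classes": per_class}


def _check_window(w: int, n: int) -> None:
    if not 2 <= w <= n - 1:
        raise ValidationError(f"window must satisfy 2 <= w <= {n - 1}, got {w}")


def gar_score(sim: SimilarityMatrix, order: Sequence[str], w: int) -> int:
    """GAR(w): anti-Robinson violations of the permuted similarity matrix
    within index windows of span w (both triangles; ties comply)."""
    n = sim.n
    _check_window(w, n)
    P = sim.permuted(order)
    count = 0
    for i in range(n):
        # lower triangle: j < k < i, i - j <= w, violation p_ij > p_ik
        s = P[i, max(0, i - w):i]
        if s.size >= 2:
            count += int(np.triu(s[:, None] > s[None, :], 1).sum())
        # upper triangle: i < j < k, k - i <= w, violation p_ij < p_ik
        s = P[i, i + 1:i + w + 1]
        if s.size >= 2:
            count += int(np.triu(s[:, None] < s[None, :], 1).sum())
    return count


def gar_profile(sim: SimilarityMatrix, order: Sequence[str],
                windows: Iterable[int]) -> dict[int, int]:
    """GAR(w) for each window; nondecreasing in w since the triple sets nest."""
    return {int(w): gar_score(sim, order, int(w)) for w in windows}
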