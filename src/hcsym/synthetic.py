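"""Synthetic inputs for testing and benchmarking the reordering pipeline.

Three generators, all driven by a single integer seed with no hidden
entropy:

* :func:`make_clustered_data` — multi-class Gaussian expression-like
  profiles.  Class c's samples are drawn from N(mu_c, sigma^2 I) with the
  class centers placed on orthogonal coordinate axes and scaled so every
  pair of centers is exactly ``separation * noise`` apart.  This emulates
  the geometry of tissue-type expression panels (well-defined groups, a
  tunable signal-to-noise ratio) without microarray-specific artefacts
  such as intensity-dependent variance or batch effects.
* :func:`make_robinson_similarity` — a perfect Robinson similarity matrix
  s_ij = exp(-decay * |t_i - t_j|) from points on a line, together with the
  generating order, for anti-Robinson scoring tests.
* :func:`random_flips` — each internal node of a dendrogram independently
  flipped with probability p, producing the "same clustering, scrambled
  display" inputs a reordering method must recover from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrices import SimilarityMatrix
from .metrics import ClassLabels
from .tree import Dendrogram


@dataclass
class SyntheticDataset:
    data: pd.DataFrame          # samples x features
    labels: ClassLabels
    params: dict


def make_clustered_data(class_sizes: list[int], dim: int = 20,
                        separation: float = 3.0, noise: float = 1.0,
                        seed: int = 0) -> SyntheticDataset:
    """Gaussian classes with centers ``separation * noise`` apart.

    Orthogonal-axis centers need ``dim >= len(class_sizes)``; all randomness
    flows from one seeded generator, so the same seed is bit-reproducible.

    Samples are presented in a random (seeded) order, not grouped by class:
    the default display order of an agglomerative tree breaks ties by input
    index, so a class-blocked layout would leak the labels into the
    unordered baseline and bias any comparison of reordering methods.
    """
    if any(s < 1 for s in class_sizes):
        raise ValidationError("class sizes must be >= 1")
    if dim < max(2, len(class_sizes)):
        raise ValidationError(
            f"dim must be >= max(2, n_classes) = {max(2, len(class_sizes))}")
    if noise <= 0:
        raise ValidationError("noise must be positive")
    if separation < 0:
        raise ValidationError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    n = sum(class_sizes)
    width = len(str(n))
    # centers on orthogonal axes at radius sep*sigma/sqrt(2): all pairwise
    # center distances equal sep*sigma
    radius = separation * noise / np.sqrt(2.0)
    rows = []
    classes = []
    for c, size in enumerate(class_sizes):
        center = np.zeros(dim)
        center[c] = radius
        rows.append(rng.normal(center, noise, size=(size, dim)))
        classes.extend([f"c{c + 1}"] * size)
    perm = rng.permutation(n)
    ids = [f"s{i + 1:0{width}d}" for i in range(n)]
    labels = {sid: classes[p] for sid, p in zip(ids, perm)}
    data = pd.DataFrame(np.vstack(rows)[perm], index=ids,
                        columns=[f"g{j + 1}" for j in range(dim)])
    params = {"class_sizes": list(class_sizes), "dim": dim,
              "separation": separation, "noise": noise, "seed": seed}
    return SyntheticDataset(data, ClassLabels(labels), params)


def make_robinson_similarity(n: int, decay: float = 1.0,
                             seed: int | None = None
                             ) -> tuple[SimilarityMatrix, list[str]]:
    """Perfect Robinson similarity from n points on a line.

    With ``seed`` the points are sorted uniform draws on [0, n] (distinct
    gaps, so off-diagonal ties are rare); without, they are evenly spaced.
    Returns the matrix and its generating (Robinson-compliant) order.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    if decay <= 0:
        raise ValidationError("decay must be positive")
    if seed is None:
        t = np.arange(n, dtype=float)
    else:
        t = np.sort(np.random.default_rng(seed).uniform(0.0, float(n), n))
    vals = np.exp(-decay * np.abs(t[:, None] - t[None, :]))
    width = len(str(n))
    order = [f"p{i + 1:0{width}d}" for i in range(n)]
    return SimilarityMatrix(order, vals), order


def random_flips(tree: Dendrogram, p: float, seed: int = 0) -> Dendrogram:
    """Copy of ``tree`` with each internal node flipped with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("flip probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    work = tree.copy()
    for nd in work.internal_nodes():
        if rng.random() < p:
            work.flip(nd)
    return work
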