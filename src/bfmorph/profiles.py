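"""Morphological-profile comparison of mutants.

A mutant's morphological profile is the vector of regression
coefficients of its discriminative model (unselected features enter as
exact zeros). Profiles are compared by Pearson correlation and clustered
by agglomerative complete linkage on the distance ``1 - r``; paralog
pairs that perturb morphology in a common direction should then appear
as sister leaves of the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discrim import DiscriminativeModel

__all__ = [
    "ProfileMatrix",
    "Dendrogram",
    "coefficient_profiles",
    "profile_similarity",
    "cluster_profiles",
    "paralog_specific_features",
]


@dataclass
class ProfileMatrix:
    """Genotypes x features matrix of regression coefficients."""

    genotypes: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotypes), len(self.feature_names)):
            raise ValueError("profile matrix shape mismatch")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("genotype labels must be unique")

    @property
    def selected_counts(self) -> dict[str, int]:
        return {
            g: int(np.count_nonzero(self.values[i]))
            for i, g in enumerate(self.genotypes)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotypes, columns=self.feature_names)

    def row(self, genotype: str) -> np.ndarray:
        return self.values[self.genotypes.index(genotype)]


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over labeled items.

    ``merges`` lists (left child, right child, height) with children
    referenced as item indices 0..n-1 or internal node ids n, n+1, ...
    in merge order.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    _children: dict[int, tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")
        self._children = {
            n + k: (m[0], m[1]) for k, m in enumerate(self.merges)
        }

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def leafset(self, node: int) -> frozenset[str]:
        n = len(self.labels)
        if node < n:
            return frozenset([self.labels[node]])
        a, b = self._children[node]
        return self.leafset(a) | self.leafset(b)

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node."""
        n = len(self.labels)
        return [self.leafset(n + k) for k in range(len(self.merges))]

    def is_monophyletic(self, labels) -> bool:
        """True if some internal node holds exactly this label set."""
        want = frozenset(labels)
        return any(c == want for c in self.clades())

    def leaf_order(self) -> list[str]:
        n = len(self.labels)
        root = n + len(self.merges) - 1

        def walk(node):
            if node < n:
                return [self.labels[node]]
            a, b = self._children[node]
            return walk(a) + walk(b)

        return walk(root) if self.merges else list(self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = len(self.labels)
        node_height = {i: 0.0 for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            node_height[n + k] = h

        def walk(node, parent_h):
            bl = parent_h - node_height[node]
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            a, b = self._children[node]
            h = node_height[node]
            return f"({walk(a, h)},{walk(b, h)}):{bl:.6g}"

        root = n + len(self.merges) - 1
        if not self.merges:
            return f"({self.labels[0]});"
        a, b = self._children[root]
        h = node_height[root]
        return f"({walk(a, h)},{walk(b, h)});"

    def to_scipy_linkage(self) -> np.ndarray:
        """SciPy-convention linkage matrix (for plotting)."""
        n = len(self.labels)
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            Z[k] = [a, b, h, sizes[n + k]]
        return Z


def coefficient_profiles(
    models_by_genotype: dict[str, DiscriminativeModel],
    feature_names: list[str] | None = None,
) -> ProfileMatrix:
    """Stack each genotype's full-data-refit coefficients into a matrix."""
    if not models_by_genotype:
        raise ValueError("no models given")
    hashes = {
        m.fit_meta.get("schema_hash")
        for m in models_by_genotype.values()
        if "schema_hash" in m.fit_meta
    }
    if len(hashes) > 1:
        raise ValueError(f"models disagree on the feature schema: {hashes}")
    genotypes = list(models_by_genotype)
    p = next(iter(models_by_genotype.values())).beta.size
    if any(m.beta.size != p for m in models_by_genotype.values()):
        raise ValueError("models disagree on the number of features")
    names = feature_names or [f"f{i + 1:03d}" for i in range(p)]
    values = np.vstack([models_by_genotype[g].beta for g in genotypes])
    return ProfileMatrix(genotypes, list(names), values)


def profile_similarity(matrix: ProfileMatrix) -> pd.DataFrame:
    """Pearson correlation between genotype profiles (unit diagonal)."""
    if len(matrix.genotypes) < 2:
        raise ValueError("need at least two profiles")
    sds = matrix.values.std(axis=1)
    for g, s in zip(matrix.genotypes, sds):
        if s == 0:
            raise ValueError(f"profile of {g} is constant; correlation undefined")
    r = np.corrcoef(matrix.values)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=matrix.genotypes, columns=matrix.genotypes)


def cluster_profiles(dist, labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Ties in the minimum pairwise distance break deterministically toward
    the lexicographically first (label-order) pair.
    """
    if isinstance(dist, pd.DataFrame):
        labels = labels or list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        labels = labels or [f"item{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    # cluster id -> current matrix row; ids 0..n-1 leaves, then n, n+1, ...
    live: list[int] = list(range(n))
    dmat = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(live) > 1:
        best = None
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                a, b = live[ai], live[bi]
                d = dmat[(min(a, b), max(a, b))]
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        # complete linkage: distance to the merged cluster is the max
        for c in live:
            if c in (a, b):
                continue
            da = dmat[(min(a, c), max(a, c))]
            db = dmat[(min(b, c), max(b, c))]
            dmat[(c, next_id)] = max(da, db)
        live = [c for c in live if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(labels, merges)


def paralog_specific_features(
    matrix: ProfileMatrix,
    pair: tuple[str, str],
    others: list[str] | None = None,
) -> dict[str, list[str]]:
    """Features whose coefficient sign is specific to one paralog pair.

    ``positive``: coefficient > 0 in both pair members and <= 0 in every
    other genotype; ``negative`` is the mirrored rule. Zero coefficients
    in the other genotypes count as passing (the feature was simply not
    selected there).
    """
    others = (
        [g for g in matrix.genotypes if g not in pair] if others is None else others
    )
    if set(pair) & set(others):
        raise ValueError("pair and others must not overlap")
    a = matrix.row(pair[0])
    b = matrix.row(pair[1])
    rest = (
        np.vstack([matrix.row(g) for g in others])
        if others
        else np.zeros((0, a.size))
    )
    pos = (a > 0) & (b > 0) & np.all(rest <= 0, axis=0)
    neg = (a < 0) & (b < 0) & np.all(rest >= 0, axis=0)
    names = np.asarray(matrix.feature_names)
    return {"positive": list(names[pos]), "negative": list(names[neg])}
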