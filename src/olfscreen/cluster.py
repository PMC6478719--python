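"""Pharmacophore-fingerprint clustering of compounds.

Compounds are described by the counts of their perceived pharmacophore
features plus soft-binned pairwise feature-distance descriptors; pairwise
dissimilarity is the Soergel (generalized Jaccard) distance, max-normalized
to [0, 1] and contrast-sharpened.  Hierarchical agglomerative clustering uses
average linkage ("average distance between all inter-cluster pairs") with a
deterministic lexicographic tie-break, and the number of classes is chosen by
the Kelley criterion: the partition minimizing normalized average within-
cluster spread plus the number of clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemlib import Compound, lowest_energy_conformer
from .errors import ConfigurationError, InsufficientDataError
from .pharmacophore import FEATURE_KINDS, PharmacophoreFeature, perceive_features

#: triangular distance-bin centers and half-width (Angstrom) for feature pairs
DISTANCE_BIN_CENTERS = np.array([3.0, 6.5, 10.0])
DISTANCE_BIN_WIDTH = 3.5

#: contrast-sharpening exponent applied to the max-normalized dissimilarity
DEFAULT_SHARPEN = 2

_PAIRS = list(itertools.combinations_with_replacement(range(len(FEATURE_KINDS)), 2))
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}
_KIND_INDEX = {k: i for i, k in enumerate(FEATURE_KINDS)}


@dataclass(frozen=True)
class FeatureFingerprint:
    """Counts per feature kind plus binned feature-pair distance descriptors."""

    vector: tuple[float, ...]

    @property
    def dim(self) -> int:
        return len(self.vector)


def fingerprint_from_features(features: Sequence[PharmacophoreFeature]) -> FeatureFingerprint:
    """Fingerprint from an explicit feature list (kind counts + soft distance bins).

    Distance-bin occupancies use triangular membership and are capped at 1 so a
    single geometric outlier pair cannot dominate the vector.
    """
    counts = np.zeros(len(FEATURE_KINDS))
    for f in features:
        counts[_KIND_INDEX[f.kind]] += 1
    hist = np.zeros((len(_PAIRS), len(DISTANCE_BIN_CENTERS)))
    for f1, f2 in itertools.combinations(features, 2):
        i1, i2 = _KIND_INDEX[f1.kind], _KIND_INDEX[f2.kind]
        d = float(np.linalg.norm(np.array(f1.center) - np.array(f2.center)))
        w = np.maximum(0.0, 1.0 - np.abs(d - DISTANCE_BIN_CENTERS) / DISTANCE_BIN_WIDTH)
        hist[_PAIR_INDEX[(min(i1, i2), max(i1, i2))]] += w
    hist = np.minimum(hist, 1.0)
    return FeatureFingerprint(vector=tuple(np.concatenate([counts, hist.ravel()])))


def feature_fingerprint(compound: Compound, seed: int = 2019) -> FeatureFingerprint:
    """Fingerprint of a compound's seeded low-energy conformer."""
    mol = lowest_energy_conformer(compound, seed=seed)
    return fingerprint_from_features(perceive_features(mol))


def soergel_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Generalized Jaccard distance for non-negative vectors."""
    mx = np.maximum(u, v).sum()
    if mx == 0:
        return 0.0
    return float(1.0 - np.minimum(u, v).sum() / mx)


def dissimilarity_matrix(
    fps: Sequence[FeatureFingerprint], sharpen: int = DEFAULT_SHARPEN
) -> np.ndarray:
    """Symmetric dissimilarity matrix normalized so the largest entry is 1.

    After max-normalization the matrix is raised elementwise to ``sharpen`` to
    compress within-scaffold noise relative to between-scaffold separation.
    """
    if len(fps) < 2:
        raise InsufficientDataError("need at least two fingerprints")
    dims = {fp.dim for fp in fps}
    if len(dims) != 1:
        raise ConfigurationError("fingerprints have heterogeneous dimensionality")
    X = np.array([fp.vector for fp in fps], float)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = soergel_distance(X[i], X[j])
    m = D.max()
    if m > 0:
        D = D / m
    return D**sharpen


# ---------------------------------------------------------------------------
# average-linkage agglomeration
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Ordered merges of an agglomerative clustering.

    ``merges[t] = (a, b, height, size)`` joins clusters ``a`` and ``b`` into a
    new cluster with id ``n_leaves + t`` (leaf ids are 0..n-1, in input order).
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def cut(self, k: int) -> np.ndarray:
        """Labels (0..k-1) of the k-cluster partition; label order by first leaf."""
        if not 1 <= k <= self.n_leaves:
            raise ConfigurationError(f"cannot cut {self.n_leaves} leaves into {k} clusters")
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t, (a, b, _h, _s) in enumerate(self.merges[: self.n_leaves - k]):
            new = self.n_leaves + t
            parent[find(a)] = new
            parent[find(b)] = new
        labels: dict[int, int] = {}
        out = np.empty(self.n_leaves, int)
        for leaf in range(self.n_leaves):
            root = find(leaf)
            if root not in labels:
                labels[root] = len(labels)
            out[leaf] = labels[root]
        return out

    def to_scipy_linkage(self) -> np.ndarray:
        """SciPy-format linkage matrix (for plotting / cross-checking)."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], float)


def agglomerate(D: np.ndarray, leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage agglomeration of a dissimilarity matrix.

    Inter-cluster distance is the mean over all cross-pair dissimilarities
    (maintained by the weighted recurrence).  Equal-distance merge candidates
    are resolved by the lexicographically smallest cluster-id pair; cluster ids
    follow input order, new clusters take the next free id.
    """
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ConfigurationError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ConfigurationError("leaf_ids length mismatch")

    size = {i: 1 for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    nxt = n
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        for i, j in itertools.combinations(sorted(active), 2):
            d = dist[(i, j)]
            if best is None or d < best[0] - 1e-15 or (
                abs(d - best[0]) <= 1e-15 and (i, j) < (best[1], best[2])
            ):
                best = (d, i, j)
        d, i, j = best
        size[nxt] = size[i] + size[j]
        merges.append((i, j, d, size[nxt]))
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(k, nxt), max(k, nxt))] = (dik * size[i] + djk * size[j]) / size[nxt]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return Dendrogram(n_leaves=n, merges=merges, leaf_ids=list(leaf_ids))


# ---------------------------------------------------------------------------
# Kelley criterion
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    k: int
    assignments: dict[str, int]  # leaf id -> class label 1..k
    penalties: dict[int, float] = field(default_factory=dict)


def kelley_select(dendrogram: Dendrogram, D: np.ndarray) -> ClusterSolution:
    """Partition level minimizing the Kelley penalty.

    For each dendrogram level the average spread is the mean, over clusters
    with at least two members, of their mean pairwise dissimilarity.  Spreads
    are min-max normalized to [1, n-2] across *all* levels down to the single
    cluster (the full-merge spread anchors the scale, as in the criterion's
    original formulation); the penalty is the normalized spread plus the
    cluster count k.  The minimizing level with 2 <= k <= n-1 is returned,
    ties going to the smaller k.  Class labels are 1..k in order of first
    appearance.
    """
    n = dendrogram.n_leaves
    if n < 3:
        raise InsufficientDataError("Kelley selection needs at least three items")
    D = np.asarray(D, float)
    levels = list(range(1, n))
    spreads = []
    cuts = {}
    for k in levels:
        lab = dendrogram.cut(k)
        cuts[k] = lab
        cluster_spreads = []
        for c in range(k):
            idx = np.where(lab == c)[0]
            if len(idx) >= 2:
                sub = D[np.ix_(idx, idx)]
                cluster_spreads.append(float(sub[np.triu_indices(len(idx), 1)].mean()))
        spreads.append(float(np.mean(cluster_spreads)) if cluster_spreads else 0.0)
    spreads = np.array(spreads)
    lo, hi = spreads.min(), spreads.max()
    if hi > lo:
        norm = 1.0 + (spreads - lo) * (n - 3) / (hi - lo)
    else:
        norm = np.ones_like(spreads)
    penalties = {k: float(norm[i] + k) for i, k in enumerate(levels) if k >= 2}
    k_best = min(penalties, key=lambda k: (penalties[k], k))
    labels = cuts[k_best]
    assignments = {
        dendrogram.leaf_ids[i]: int(labels[i]) + 1 for i in range(n)
    }
    return ClusterSolution(k=k_best, assignments=assignments, penalties=penalties)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def export_dendrogram(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths (leaf depth equals merge height)."""
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: _escape(dendrogram.leaf_ids[i]) for i in range(n)}
    for t, (a, b, h, _s) in enumerate(dendrogram.merges):
        new = n + t
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[new] = h
    root = n + len(dendrogram.merges) - 1 if dendrogram.merges else 0
    return node[root] + ";"


def _escape(name: str) -> str:
    if any(ch in name for ch in " ():,;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def cluster_compounds(
    compounds: Sequence[Compound], sharpen: int = DEFAULT_SHARPEN, seed: int = 2019
) -> tuple[Dendrogram, ClusterSolution, np.ndarray]:
    """Fingerprint, agglomerate and Kelley-select in one call."""
    fps = [feature_fingerprint(c, seed=seed) for c in compounds]
    D = dissimilarity_matrix(fps, sharpen=sharpen)
    dend = agglomerate(D, leaf_ids=[c.id for c in compounds])
    solution = kelley_select(dend, D)
    return dend, solution, D
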