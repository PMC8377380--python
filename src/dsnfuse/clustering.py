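"""Spectral clustering of the fused network and cluster-count selection.

The embedding is the standard normalized-cut recipe: eigenvectors of the
symmetric normalized Laplacian of the affinity, row-normalized, then
k-means with a fixed seed.  The number of clusters is scanned over a range
and selected by mean silhouette width, with the Dunn index breaking ties
and smaller k breaking any remainder; both indices (and the connectivity
index) are reported for every scanned k so the choice can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from dsnfuse.core_io import SimilarityMatrix


@dataclass
class ClusterAssignment:
    """drug_id -> cluster index (1..k); every cluster non-empty."""

    labels: dict[str, int]
    k: int

    def __post_init__(self):
        present = set(self.labels.values())
        if present != set(range(1, self.k + 1)):
            raise ValueError(
                f"cluster indices must be exactly 1..{self.k}, got {sorted(present)}"
            )

    def vector(self, drugs: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[d] for d in drugs], dtype=int)

    @classmethod
    def from_vector(cls, drugs: Sequence[str], vec: Sequence[int]) -> "ClusterAssignment":
        uniq = sorted(set(vec))
        remap = {c: i + 1 for i, c in enumerate(uniq)}
        return cls({d: remap[c] for d, c in zip(drugs, vec)}, len(uniq))


@dataclass
class ValidityProfile:
    """Per-k validity indices from a cluster-count scan."""

    entries: dict[int, dict[str, float]] = field(default_factory=dict)
    chosen_k: int | None = None
    rule: str = "max silhouette, ties by Dunn, then smaller k"


def similarity_to_distance(matrix: SimilarityMatrix) -> np.ndarray:
    """d_ij = 1 - s_ij for a unit-scale similarity matrix.

    The result has zero diagonal and is symmetric; the triangle inequality
    is not guaranteed and not needed by the validity indices used here.
    """
    if matrix.scale != "unit":
        raise ValueError("similarity_to_distance requires a unit-scale matrix")
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    return d


def spectral_cluster(matrix: SimilarityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Normalized-cut spectral clustering of an affinity matrix.

    Embeds drugs in the bottom-k eigenvectors of L_sym = I - D^{-1/2} W
    D^{-1/2}, row-normalizes the embedding, and runs seeded k-means.
    """
    n = len(matrix.drugs)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < {n}")
    w = matrix.values.copy()
    np.fill_diagonal(w, 0.0)
    n_comp, _ = connected_components((w > 0).astype(int), directed=False)
    if n_comp > k:
        raise ValueError(
            f"graph has {n_comp} connected components > k={k}; increase k"
        )
    deg = w.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    _, vecs = eigh(lap, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(emb)
    return ClusterAssignment.from_vector(matrix.drugs, raw)


def _groups(distances: np.ndarray, assignment: ClusterAssignment, drugs: Sequence[str]):
    vec = assignment.vector(drugs)
    return vec, [np.flatnonzero(vec == c) for c in range(1, assignment.k + 1)]


def dunn_index(
    distances: np.ndarray, assignment: ClusterAssignment, drugs: Sequence[str]
) -> float:
    """Smallest between-cluster pair distance over largest within-cluster
    diameter.  Higher is better."""
    if assignment.k < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    vec, groups = _groups(distances, assignment, drugs)
    if all(len(idx) < 2 for idx in groups):
        raise ValueError("Dunn index undefined: all clusters are singletons")
    diam = 0.0
    for idx in groups:
        if len(idx) > 1:
            diam = max(diam, distances[np.ix_(idx, idx)].max())
    sep = np.inf
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            sep = min(sep, distances[np.ix_(groups[a], groups[b])].min())
    if diam == 0.0:
        # identical points within every cluster: perfectly compact
        return float("inf") if sep > 0 else 0.0
    return float(sep / diam)


def silhouette_mean(
    distances: np.ndarray, assignment: ClusterAssignment, drugs: Sequence[str]
) -> float:
    """Mean silhouette width (b_i - a_i)/max(a_i, b_i) over all drugs.

    a_i is the mean distance of drug i to the rest of its cluster and b_i
    the smallest mean distance to any other cluster.  Members of singleton
    clusters contribute 0 (the standard convention), as do drugs with
    a_i = b_i = 0 (co-located points split across clusters).
    """
    if assignment.k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    vec, groups = _groups(distances, assignment, drugs)
    scores = np.zeros(len(drugs))
    for i in range(len(drugs)):
        own = groups[vec[i] - 1]
        if len(own) < 2:
            continue
        a_i = distances[i, own].sum() / (len(own) - 1)
        b_i = min(
            distances[i, idx].mean()
            for c, idx in enumerate(groups, start=1)
            if c != vec[i] and len(idx)
        )
        denom = max(a_i, b_i)
        scores[i] = (b_i - a_i) / denom if denom > 0 else 0.0
    return float(scores.mean())


def connectivity(
    distances: np.ndarray,
    assignment: ClusterAssignment,
    drugs: Sequence[str],
    L: int = 10,
) -> float:
    """Connectivity validity index: sum over drugs of 1/j for every j-th
    nearest neighbor (j = 1..L) that falls outside the drug's cluster.
    Lower is better; 0 when clusters are neighborhood-closed."""
    n = len(drugs)
    if L >= n:
        raise ValueError("L must be smaller than the number of drugs")
    vec = assignment.vector(drugs)
    total = 0.0
    for i in range(n):
        row = distances[i].copy()
        row[i] = np.inf
        nn = np.argsort(row, kind="stable")[:L]
        for j, neighbor in enumerate(nn, start=1):
            if vec[neighbor] != vec[i]:
                total += 1.0 / j
    return total


def select_k(
    matrix: SimilarityMatrix,
    k_range: Sequence[int],
    seed: int = 0,
    L: int = 10,
) -> tuple[int, ValidityProfile]:
    """Scan cluster counts and pick the best by the declared rule.

    Dunn and silhouette are computed on 1 - s distances of the unit-scale
    matrix (affinity input is rescaled first).  The full profile is
    returned so callers can inspect or override the choice.
    """
    from dsnfuse.fusion import unit_rescale

    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    n = len(matrix.drugs)
    if min(ks) < 2 or max(ks) >= n:
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    unit = matrix if matrix.scale == "unit" else unit_rescale(matrix)
    dist = similarity_to_distance(unit)
    profile = ValidityProfile()
    for k in ks:
        try:
            assignment = spectral_cluster(matrix, k, seed)
        except ValueError:
            # e.g. more graph components than k: this k is infeasible
            profile.entries[k] = {"silhouette": np.nan, "dunn": np.nan}
            continue
        entry = {
            "silhouette": silhouette_mean(dist, assignment, matrix.drugs),
            "dunn": dunn_index(dist, assignment, matrix.drugs),
        }
        if L < n:
            entry["connectivity"] = connectivity(dist, assignment, matrix.drugs, L)
        profile.entries[k] = entry
    feasible = [k for k in ks if np.isfinite(profile.entries[k]["silhouette"])]
    if not feasible:
        raise ValueError("no feasible k in the scanned range")
    best = max(
        feasible,
        key=lambda k: (
            round(profile.entries[k]["silhouette"], 12),
            round(profile.entries[k]["dunn"], 12)
            if np.isfinite(profile.entries[k]["dunn"])
            else np.inf,
            -k,
        ),
    )
    profile.chosen_k = best
    return best, profile
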