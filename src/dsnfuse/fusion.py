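"""Integration of multiple drug similarity networks.

The primary integrator is similarity network fusion (SNF): each view's
full diffusion kernel is updated through its K-nearest-neighbor sparse
kernel with the average kernel of the other views, for T rounds, so the
views converge toward a single network that carries both shared and
complementary signal.  Three linear baselines are provided for
comparison: elementwise maximum, weighted average over a weight grid, and
probability disjunction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from dsnfuse.core_io import SimilarityMatrix


@dataclass
class FusionResult:
    fused: SimilarityMatrix
    method: str
    params: dict = field(default_factory=dict)
    views: list[str] = field(default_factory=list)


def _check_aligned(views: Sequence[SimilarityMatrix]) -> list[str]:
    if len(views) < 2:
        raise ValueError("need at least 2 views")
    drugs = views[0].drugs
    for v in views[1:]:
        if v.drugs != drugs:
            diff = sorted(set(v.drugs) ^ set(drugs))
            raise ValueError(f"views have mismatched drug lists; difference: {diff}")
    return drugs


def _full_kernel(w: np.ndarray) -> np.ndarray:
    """Row-normalize to a diffusion kernel: half the mass on the diagonal,
    half spread over the off-diagonal proportionally to similarity."""
    n = w.shape[0]
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    p = off / (2.0 * rowsum)
    np.fill_diagonal(p, 0.5)
    return p


def _knn_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized kernel restricted to each drug's K nearest neighbors
    (self excluded; ties broken by drug order)."""
    n = w.shape[0]
    s = np.zeros_like(w)
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")
        nn = order[:K]
        mass = w[i, nn].sum()
        if mass > 0:
            s[i, nn] = w[i, nn] / mass
    return s


def snf_fuse(
    views: Sequence[SimilarityMatrix],
    eta: float = 0.5,
    K: int = 20,
    T: int = 20,
    view_names: Sequence[str] | None = None,
) -> FusionResult:
    """Fuse aligned similarity networks by iterative cross-diffusion.

    The input networks are consumed directly as affinities (they are
    already bounded similarities); ``eta`` only enters the optional
    distance-kernelization path (:func:`affinity_kernel`) and is echoed in
    the result parameters.  The update is deterministic: no randomness is
    involved at any stage.
    """
    drugs = _check_aligned(views)
    n = len(drugs)
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of drugs ({n})")
    if T < 1:
        raise ValueError("T must be >= 1")
    P = [_full_kernel(v.values) for v in views]
    S = [_knn_kernel(v.values, K) for v in views]
    m = len(views)
    for _ in range(T):
        new_P = []
        for v in range(m):
            others = [P[u] for u in range(m) if u != v]
            avg = np.mean(others, axis=0)
            p = S[v] @ avg @ S[v].T
            p = (p + p.T) / 2.0
            p = _full_kernel(p)
            new_P.append(p)
        P = new_P
    fused = np.mean(P, axis=0)
    fused = (fused + fused.T) / 2.0
    return FusionResult(
        fused=SimilarityMatrix(drugs, fused, "affinity"),
        method="snf",
        params={"eta": eta, "K": K, "T": T},
        views=list(view_names or [f"view{i}" for i in range(m)]),
    )


def affinity_kernel(distances: np.ndarray, K: int = 20, eta: float = 0.5) -> np.ndarray:
    """Scaled-exponential affinity from a distance matrix.

    W_ij = exp(-d_ij^2 / (eta * eps_ij)) where eps_ij averages the mean
    K-nearest-neighbor distance of i, of j, and d_ij itself.  This is the
    optional kernelization path for raw feature distances; the similarity
    networks themselves feed :func:`snf_fuse` directly.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    sorted_d = np.sort(d, axis=1)
    # skip the zero self-distance in column 0
    mean_knn = sorted_d[:, 1 : K + 1].mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + d) / 3.0
    eps[eps == 0] = np.finfo(float).eps
    w = np.exp(-(d**2) / (eta * eps))
    return (w + w.T) / 2.0


def unit_rescale(affinity: SimilarityMatrix) -> SimilarityMatrix:
    """Monotone rescale of a fused affinity matrix to unit scale.

    Off-diagonal entries are divided by the maximum off-diagonal entry and
    the diagonal is set to 1, so distance-based validity indices apply.
    """
    vals = affinity.values.copy()
    off = vals.copy()
    np.fill_diagonal(off, -np.inf)
    top = off.max()
    if top <= 0:
        raise ValueError("all off-diagonal entries are zero")
    vals = vals / top
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(affinity.drugs, np.clip(vals, 0.0, 1.0), "unit")


def max_integrate(
    views: Sequence[SimilarityMatrix], view_names: Sequence[str] | None = None
) -> FusionResult:
    """Elementwise maximum across views."""
    drugs = _check_aligned(views)
    fused = np.maximum.reduce([v.values for v in views])
    scale = "unit" if all(v.scale == "unit" for v in views) else "affinity"
    return FusionResult(
        SimilarityMatrix(drugs, fused, scale),
        "max",
        {},
        list(view_names or [f"view{i}" for i in range(len(views))]),
    )


def weighted_average_integrate(
    views: Sequence[SimilarityMatrix],
    weights: Sequence[float],
    view_names: Sequence[str] | None = None,
) -> FusionResult:
    """Convex combination sum(w_v S_v) / sum(w_v)."""
    drugs = _check_aligned(views)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(views):
        raise ValueError("one weight per view required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    fused = sum(wi * v.values for wi, v in zip(w, views)) / w.sum()
    scale = "unit" if all(v.scale == "unit" for v in views) else "affinity"
    return FusionResult(
        SimilarityMatrix(drugs, fused, scale),
        "wavg",
        {"weights": list(map(float, w))},
        list(view_names or [f"view{i}" for i in range(len(views))]),
    )


def weight_grid(n_views: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All weight vectors on the step-resolution simplex (sum 1, no
    all-zero vector).  For 3 views at step 0.1 there are 66 of them."""
    units = round(1.0 / step)
    grid = []
    for combo in itertools.combinations_with_replacement(range(n_views), units):
        counts = [combo.count(v) for v in range(n_views)]
        grid.append(tuple(c * step for c in counts))
    return sorted(set(grid), reverse=True)


def probability_disjunction(
    views: Sequence[SimilarityMatrix], view_names: Sequence[str] | None = None
) -> FusionResult:
    """Noisy-OR integration: 1 - prod_v (1 - S_v), elementwise.

    Requires unit-scale inputs (entries in [0, 1])."""
    drugs = _check_aligned(views)
    prod = np.ones((len(drugs), len(drugs)))
    for v in views:
        if np.any(v.values < 0) or np.any(v.values > 1 + 1e-12):
            raise ValueError("probability disjunction needs entries in [0, 1]")
        prod *= 1.0 - np.clip(v.values, 0.0, 1.0)
    return FusionResult(
        SimilarityMatrix(drugs, 1.0 - prod, "unit"),
        "disjunction",
        {},
        list(view_names or [f"view{i}" for i in range(len(views))]),
    )
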