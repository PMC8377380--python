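"""End-to-end benchmark experiments on synthetic universes.

These drive the framework's central comparison — non-linear fusion versus
each single property view and versus the linear integrators — on the
complementary three-view benchmark, plus the cluster-count recovery and
repositioning ground-truth checks.  All randomness flows from explicit
seeds.
"""

from __future__ import annotations

import numpy as np

from dsnfuse.clustering import select_k, spectral_cluster
from dsnfuse.core_io import SimilarityMatrix
from dsnfuse.evaluation import RankedPairList, aor_curve, nmi
from dsnfuse.fusion import (
    max_integrate,
    probability_disjunction,
    snf_fuse,
    weight_grid,
    weighted_average_integrate,
)
from dsnfuse.interpretation import annotate_clusters, find_unexpected_drugs, ranked_pairs
from dsnfuse.similarity import build_profile_dsn, build_target_dsn
from dsnfuse.synthetic import (
    SyntheticUniverse,
    UniverseSpec,
    complementary_benchmark,
    simulate_universe,
)

VIEW_NAMES = ("side_effect", "atom_pair", "target")


def build_views(universe: SyntheticUniverse) -> list[SimilarityMatrix]:
    """The three single-property similarity networks of a universe."""
    return [
        build_profile_dsn(universe.side_effects),
        build_profile_dsn(universe.atom_pairs),
        build_target_dsn(universe.target_maps, universe.sequences),
    ]


def _cluster_nmi(matrix: SimilarityMatrix, planted, k: int, seed: int) -> float:
    labels = spectral_cluster(matrix, k, seed).vector(matrix.drugs)
    return nmi(planted, labels)


def integrator_comparison(seed: int, K: int = 20, T: int = 20) -> dict[str, float]:
    """NMI against the planted partition for every route, one seed.

    Single views, SNF fusion, elementwise maximum, probability
    disjunction, and the best grid point of the weighted average (the
    weighted-average baseline is scored at its oracle-best weights, the
    most favorable reading of a traversed weight grid).
    """
    u = simulate_universe(complementary_benchmark(seed))
    views = build_views(u)
    k = u.spec.n_clusters
    planted = u.planted.vector(views[0].drugs)
    out = {
        f"view_{name}": _cluster_nmi(v, planted, k, seed)
        for name, v in zip(VIEW_NAMES, views)
    }
    out["snf"] = _cluster_nmi(snf_fuse(views, K=K, T=T).fused, planted, k, seed)
    out["max"] = _cluster_nmi(max_integrate(views).fused, planted, k, seed)
    out["disjunction"] = _cluster_nmi(
        probability_disjunction(views).fused, planted, k, seed
    )
    out["wavg_best"] = max(
        _cluster_nmi(weighted_average_integrate(views, w).fused, planted, k, seed)
        for w in weight_grid(3, step=0.1)
    )
    return out


def fusion_recovery_medians(n_seeds: int = 20, base_seed: int = 0) -> dict[str, float]:
    """Median per-route NMI across benchmark seeds."""
    runs = [integrator_comparison(base_seed + i) for i in range(n_seeds)]
    return {key: float(np.median([r[key] for r in runs])) for key in runs[0]}


def select_k_recovery(
    planted_ks=(2, 3, 5), n_seeds: int = 10, base_seed: int = 0, n_drugs: int = 60
) -> dict[int, float]:
    """Fraction of noiseless block universes whose planted k is recovered.

    Uses the side-effect view of a fully informative noiseless universe
    (a planted block matrix) and scans k in [2, planted + 2].
    """
    rates = {}
    for k_true in planted_ks:
        hits = 0
        for i in range(n_seeds):
            u = simulate_universe(
                UniverseSpec(n_drugs=n_drugs, n_clusters=k_true, seed=base_seed + i)
            )
            m = build_profile_dsn(u.side_effects)
            k_hat, _ = select_k(m, range(2, k_true + 3), seed=base_seed + i)
            hits += k_hat == k_true
        rates[k_true] = hits / n_seeds
    return rates


def unexpected_drug_recovery(seed: int, label_noise: float = 0.1) -> dict[str, float]:
    """Run the unexpected-drug repositioning route against planted truth.

    Simulates the benchmark with ATC label noise, fuses and clusters at
    the planted k, enriches clusters for ATC codes, and scores how many
    noise-flipped drugs are flagged with their true cluster code proposed.
    """
    spec = complementary_benchmark(seed)
    spec.label_noise = label_noise
    u = simulate_universe(spec)
    views = build_views(u)
    fused = snf_fuse(views, K=20, T=20).fused
    assignment = spectral_cluster(fused, u.spec.n_clusters, seed)
    enrichment = annotate_clusters(assignment, u.registry, "atc", alpha=0.05)
    flags = {c.drugs[0]: c for c in find_unexpected_drugs(assignment, enrichment, u.registry)}
    n_flipped = len(u.flipped)
    flagged = sum(1 for d in u.flipped if d in flags)
    correct = sum(
        1 for d, true_code in u.flipped.items()
        if d in flags and true_code in flags[d].proposed_terms
    )
    return {
        "n_flipped": n_flipped,
        "flagged_fraction": flagged / n_flipped if n_flipped else float("nan"),
        "true_code_proposed_fraction": correct / n_flipped if n_flipped else float("nan"),
    }


def noiseless_aor_curve(
    seed: int, bin_size: int = 500, step: int = 100
) -> list[tuple[int, float]]:
    """AOR along score-ranked pairs of a noiseless fully informative universe."""
    u = simulate_universe(UniverseSpec(n_drugs=120, n_clusters=6, seed=seed))
    m = build_profile_dsn(u.side_effects)
    ranked: RankedPairList = ranked_pairs(m)
    return aor_curve(ranked, u.registry, bin_size=bin_size, step=step)
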