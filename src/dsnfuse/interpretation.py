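"""Downstream interpretation of the integrated network.

Four analyses live here: attribution of each fused-network edge to the
data types that drive it; extraction of repositioning candidates (highly
similar pairs with discordant ATC codes, and cluster members whose own
ATC codes miss their cluster's enriched codes); hypergeometric enrichment
of arbitrary drug-label vocabularies per cluster; and the deviation of a
numeric drug property in a cluster from its reference mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dsnfuse.clustering import ClusterAssignment
from dsnfuse.core_io import ATC_FIRST_LEVELS, DrugRecord, SimilarityMatrix
from dsnfuse.evaluation import RankedPairList, _registry_index


@dataclass(frozen=True)
class EdgeAttribution:
    pair: tuple[str, str]
    contributors: frozenset[str]
    within_cluster: bool | None = None
    cluster: int | None = None


@dataclass
class EnrichmentRecord:
    cluster: int
    term: str
    k: int
    m: int
    n: int
    N: int
    es: float
    p: float
    q: float | None = None
    significant: bool = False


@dataclass
class RepositioningCandidate:
    mode: str  # "high_similarity_pair" | "unexpected_in_cluster"
    drugs: tuple[str, ...]
    rank: int | None = None
    score: float | None = None
    cluster: int | None = None
    proposed_terms: frozenset[str] = frozenset()


def attribute_edge(
    scores: Mapping[str, float], margin: float = 0.10, mode: str = "relative"
) -> frozenset[str]:
    """Attribute one edge to the data types whose similarity drives it.

    Scores are sorted descending and the cut is placed at the first gap
    where the upper score exceeds the next by the margin — relative
    (s_i >= (1 + margin) s_j, the default: a ratio is the only scale-free
    comparison across views of different natural scales) or absolute
    (s_i - s_j >= margin).  Contributors are every view above the cut;
    with no qualifying gap, all views contribute.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if any(s < 0 for s in scores.values()):
        raise ValueError("scores must be non-negative")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    for i in range(len(ordered) - 1):
        hi, lo = ordered[i][1], ordered[i + 1][1]
        if mode == "relative":
            gap = hi > lo and hi >= (1.0 + margin) * lo
        elif mode == "absolute":
            gap = hi - lo >= margin
        else:
            raise ValueError(f"unknown margin mode {mode!r}")
        if gap:
            return frozenset(name for name, _ in ordered[: i + 1])
    return frozenset(scores)


def attribute_network(
    views: Sequence[SimilarityMatrix],
    view_names: Sequence[str],
    fused: SimilarityMatrix,
    assignment: ClusterAssignment | None = None,
    margin: float = 0.10,
    mode: str = "relative",
    top_frac: float | None = 0.05,
) -> list[EdgeAttribution]:
    """Attribute every retained fused-network edge to its data types.

    By default only the top fraction of fused edges (ranked by fused
    score) is retained; pass ``top_frac=None`` to attribute all edges.
    """
    drugs = fused.drugs
    for v in views:
        if v.drugs != drugs:
            raise ValueError("views and fused network must share the drug order")
    n = len(drugs)
    pairs = list(itertools.combinations(range(n), 2))
    if top_frac is not None:
        if not 0 < top_frac <= 1:
            raise ValueError("top_frac must be in (0, 1]")
        keep = max(1, int(round(top_frac * len(pairs))))
        pairs.sort(key=lambda ij: (-fused.values[ij], drugs[ij[0]], drugs[ij[1]]))
        pairs = pairs[:keep]
    out = []
    for i, j in pairs:
        scores = {name: float(v.values[i, j]) for name, v in zip(view_names, views)}
        within = cluster = None
        if assignment is not None:
            ci = assignment.labels[drugs[i]]
            cj = assignment.labels[drugs[j]]
            within = ci == cj
            cluster = ci if within else None
        out.append(
            EdgeAttribution(
                pair=(min(drugs[i], drugs[j]), max(drugs[i], drugs[j])),
                contributors=attribute_edge(scores, margin, mode),
                within_cluster=within,
                cluster=cluster,
            )
        )
    return out


def contribution_summary(
    attributions: Sequence[EdgeAttribution],
) -> dict[str, dict[str, float]]:
    """Fraction of edges per contributor subset, by scope.

    Scopes are ``all``, ``within`` / ``between`` cluster (when cluster
    context is present) and ``cluster_<i>`` for each cluster's internal
    edges.  Category keys are '+'-joined sorted view names; fractions sum
    to 1 within every scope.
    """

    def category(contributors: frozenset[str]) -> str:
        return "+".join(sorted(contributors))

    buckets: dict[str, list[EdgeAttribution]] = {"all": list(attributions)}
    for att in attributions:
        if att.within_cluster is None:
            continue
        buckets.setdefault("within" if att.within_cluster else "between", []).append(att)
        if att.within_cluster:
            buckets.setdefault(f"cluster_{att.cluster}", []).append(att)
    summary = {}
    for scope, edges in buckets.items():
        if not edges:
            continue
        counts: dict[str, int] = {}
        for att in edges:
            key = category(att.contributors)
            counts[key] = counts.get(key, 0) + 1
        total = len(edges)
        summary[scope] = {key: c / total for key, c in counts.items()}
    return summary


def enrichment_score(k: int, n: int, m: int, N: int) -> float:
    """Fold over-representation (k/n) / (m/N) of a label in a cluster."""
    if n <= 0 or m <= 0:
        raise ValueError("cluster size n and label count m must be positive")
    if not (0 <= k <= min(m, n) and m <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, m={m}, N={N}")
    return (k / n) / (m / N)


def hypergeom_p(k: int, n: int, m: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X is the number of labelled drugs in a draw of n from a universe of N
    containing m labelled drugs.
    """
    if not (0 <= n <= N and 0 <= m <= N and k >= 0):
        raise ValueError(f"impossible counts k={k}, n={n}, m={m}, N={N}")
    if k > min(m, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def _vocabulary_map(
    registry: Iterable[DrugRecord], vocabulary: str | Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    if isinstance(vocabulary, str):
        if vocabulary == "atc":
            return {r.drug_id: r.atc_first_levels for r in registry}
        if vocabulary == "superclass":
            return {
                r.drug_id: frozenset([r.superclass]) if r.superclass else frozenset()
                for r in registry
            }
        raise ValueError(f"unknown built-in vocabulary {vocabulary!r}")
    return {d: frozenset(terms) for d, terms in vocabulary.items()}


def annotate_clusters(
    assignment: ClusterAssignment,
    registry: Iterable[DrugRecord],
    vocabulary: str | Mapping[str, Iterable[str]] = "atc",
    alpha: float = 0.05,
    significance_column: str = "p",
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of every (cluster, term) combination.

    ``vocabulary`` is ``"atc"`` (first-level codes), ``"superclass"``, or
    any drug -> term-set mapping (e.g. ADMET flags).  Multi-label drugs
    count once per distinct term.  Benjamini--Hochberg q values are
    computed across all tests; the significance flag defaults to the raw
    p column at ``alpha``, with q selectable instead.
    """
    if significance_column not in ("p", "q"):
        raise ValueError("significance_column must be 'p' or 'q'")
    registry = list(registry)
    drug_terms = _vocabulary_map(registry, vocabulary)
    drugs = [d for d in assignment.labels if d in drug_terms]
    N = len(drugs)
    terms = sorted({t for d in drugs for t in drug_terms[d]})
    m_counts = {t: sum(t in drug_terms[d] for d in drugs) for t in terms}
    records = []
    for c in range(1, assignment.k + 1):
        members = [d for d in drugs if assignment.labels[d] == c]
        n = len(members)
        if n == 0:
            continue
        for t in terms:
            k = sum(t in drug_terms[d] for d in members)
            records.append(
                EnrichmentRecord(
                    cluster=c,
                    term=t,
                    k=k,
                    m=m_counts[t],
                    n=n,
                    N=N,
                    es=enrichment_score(k, n, m_counts[t], N),
                    p=hypergeom_p(k, n, m_counts[t], N),
                )
            )
    if records:
        _, qvals, _, _ = multipletests([r.p for r in records], method="fdr_bh")
        for r, q in zip(records, qvals):
            r.q = float(q)
            r.significant = (r.p if significance_column == "p" else r.q) < alpha
    return records


def find_unexpected_drugs(
    assignment: ClusterAssignment,
    enrichment: Sequence[EnrichmentRecord],
    registry: Iterable[DrugRecord],
) -> list[RepositioningCandidate]:
    """Flag cluster members whose own ATC codes miss every code the
    cluster is significantly enriched for.

    Each candidate carries the cluster's significant term set as the
    proposed novel therapeutic property.  Drugs without any ATC
    annotation are not flagged (nothing is 'unexpected' about them).
    """
    idx = _registry_index(registry)
    sig_terms: dict[int, set[str]] = {}
    for rec in enrichment:
        if rec.significant:
            sig_terms.setdefault(rec.cluster, set()).add(rec.term)
    out = []
    for drug, cluster in assignment.labels.items():
        terms = sig_terms.get(cluster)
        if not terms:
            continue
        own = idx[drug].atc_first_levels
        if own and not (own & terms):
            out.append(
                RepositioningCandidate(
                    mode="unexpected_in_cluster",
                    drugs=(drug,),
                    cluster=cluster,
                    proposed_terms=frozenset(terms),
                )
            )
    return out


def ranked_pairs(matrix: SimilarityMatrix) -> RankedPairList:
    """All drug pairs of a similarity matrix ranked by descending score,
    ties broken by canonical pair order."""
    drugs = matrix.drugs
    entries = []
    for i, j in itertools.combinations(range(len(drugs)), 2):
        a, b = sorted((drugs[i], drugs[j]))
        entries.append((a, b, float(matrix.values[i, j])))
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return RankedPairList(entries)


def top_pairs(
    matrix: SimilarityMatrix,
    registry: Iterable[DrugRecord],
    n_top: int,
) -> list[RepositioningCandidate]:
    """The n_top highest-similarity drug pairs with ATC-concordance flags.

    Pairs whose first-level ATC sets do not intersect are the
    repositioning candidates of the high-similarity route; concordant
    pairs are returned too (score/rank evidence), flagged via
    ``proposed_terms``: empty for concordant pairs, the partner's codes
    for discordant ones.
    """
    ranked = ranked_pairs(matrix)
    if n_top > len(ranked):
        raise ValueError(f"n_top={n_top} exceeds {len(ranked)} pairs")
    idx = _registry_index(registry)
    out = []
    for rank, (a, b, score) in enumerate(ranked.pairs[:n_top], start=1):
        fa, fb = idx[a].atc_first_levels, idx[b].atc_first_levels
        discordant = bool(fa) and bool(fb) and not (fa & fb)
        out.append(
            RepositioningCandidate(
                mode="high_similarity_pair",
                drugs=(a, b),
                rank=rank,
                score=score,
                proposed_terms=frozenset(fa ^ fb) if discordant else frozenset(),
            )
        )
    return out


def atc_repositioning_graph(
    matrix: SimilarityMatrix,
    registry: Iterable[DrugRecord],
    top_frac: float = 0.05,
) -> nx.Graph:
    """Weighted graph over first-level ATC codes from the top drug pairs.

    Restricts to the top fraction of pairs by similarity, assigns each
    drug to every one of its first-level codes, and weights the edge
    between two different codes by the mean similarity of the drug pairs
    spanning the two groups.  Codes with no contributing drugs are absent.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    ranked = ranked_pairs(matrix)
    keep = max(1, int(round(top_frac * len(ranked))))
    idx = _registry_index(registry)
    scores: dict[tuple[str, str], list[float]] = {}
    nodes: set[str] = set()
    for a, b, s in ranked.pairs[:keep]:
        fa, fb = idx[a].atc_first_levels, idx[b].atc_first_levels
        nodes |= fa | fb
        for ca in fa:
            for cb in fb:
                if ca == cb:
                    continue
                key = (min(ca, cb), max(ca, cb))
                scores.setdefault(key, []).append(s)
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for (ca, cb), vals in scores.items():
        g.add_edge(ca, cb, weight=float(np.mean(vals)), n_pairs=len(vals))
    return g


def property_deviation(
    cluster_values: Sequence[float], reference_values: Sequence[float]
) -> tuple[float, float]:
    """Relative deviation of a cluster's mean property from the reference.

    D = (C - A)/A with C the cluster mean and A the reference mean, plus
    the two-sided Welch t-test p value for the difference in means.
    """
    c_vals = np.asarray(cluster_values, dtype=float)
    r_vals = np.asarray(reference_values, dtype=float)
    if len(c_vals) < 2 or len(r_vals) < 2:
        raise ValueError("need at least 2 values per group")
    A = r_vals.mean()
    if A == 0:
        raise ValueError("reference mean is zero; relative deviation undefined")
    D = (c_vals.mean() - A) / A
    _, p = stats.ttest_ind(c_vals, r_vals, equal_var=False)
    return float(D), float(p)
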