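import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dsnfuse.clustering import ClusterAssignment
from dsnfuse.core_io import DrugRecord, SimilarityMatrix
from dsnfuse.interpretation import (
    EnrichmentRecord,
    annotate_clusters,
    atc_repositioning_graph,
    attribute_edge,
    attribute_network,
    contribution_summary,
    enrichment_score,
    find_unexpected_drugs,
    hypergeom_p,
    property_deviation,
    ranked_pairs,
    top_pairs,
)


def record(drug_id, codes=(), superclass=None):
    return DrugRecord(drug_id, drug_id, frozenset(codes), superclass)


def hypergeom_oracle(k, n, m, N):
    """Exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    labelled = set(range(m))
    hits = sum(
        1
        for draw in itertools.combinations(universe, n)
        if len(labelled & set(draw)) >= k
    )
    return hits / comb(N, n)


class TestAttributeEdge:
    def test_dominant_view_takes_the_edge(self):
        assert attribute_edge({"chem": 0.9, "target": 0.5, "side": 0.4}) == {"chem"}

    def test_flat_scores_attribute_all_three(self):
        got = attribute_edge({"chem": 0.5, "target": 0.5, "side": 0.5})
        assert got == {"chem", "target", "side"}

    def test_top_two_share_when_second_gap_fires(self):
        got = attribute_edge({"a": 0.55, "b": 0.52, "c": 0.30})
        assert got == {"a", "b"}

    def test_absolute_mode(self):
        got = attribute_edge({"a": 0.55, "b": 0.40, "c": 0.38}, margin=0.10, mode="absolute")
        assert got == {"a"}

    def test_all_zero_scores_attribute_all(self):
        assert attribute_edge({"a": 0.0, "b": 0.0, "c": 0.0}) == {"a", "b", "c"}

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            attribute_edge({"a": -0.1, "b": 0.2, "c": 0.3})

    @given(
        st.tuples(
            st.floats(0.001, 1.0), st.floats(0.001, 1.0), st.floats(0.001, 1.0)
        ),
        st.floats(0.1, 100.0),
    )
    def test_relative_rule_scale_invariant(self, scores, c):
        named = dict(zip("abc", scores))
        scaled = {k: v * c for k, v in named.items()}
        assert attribute_edge(named) == attribute_edge(scaled)


class TestContributionSummary:
    def toy(self):
        drugs = ["d1", "d2", "d3", "d4"]
        rng = np.random.default_rng(0)

        def mat(vals):
            v = np.asarray(vals, float)
            np.fill_diagonal(v, 1.0)
            return SimilarityMatrix(drugs, (v + v.T) / 2)

        base = rng.uniform(0.1, 0.9, (4, 4))
        views = [mat(base), mat(base * 0.5), mat(base * 0.25)]
        fused = SimilarityMatrix(drugs, views[0].values, "affinity")
        assignment = ClusterAssignment({"d1": 1, "d2": 1, "d3": 2, "d4": 2}, 2)
        return views, fused, assignment

    def test_single_contributor_everywhere(self):
        views, fused, assignment = self.toy()
        atts = attribute_network(views, ["a", "b", "c"], fused, assignment, top_frac=None)
        # view a is uniformly 2x view b: every edge attributed to a alone
        assert all(a.contributors == {"a"} for a in atts)
        summary = contribution_summary(atts)
        for scope in ("all", "within", "between"):
            assert summary[scope] == {"a": 1.0}

    def test_fractions_sum_to_one_per_scope(self, noisy_universe):
        from dsnfuse.similarity import build_profile_dsn
        from dsnfuse.fusion import probability_disjunction

        se = build_profile_dsn(noisy_universe.side_effects)
        ap = build_profile_dsn(noisy_universe.atom_pairs)
        fused = probability_disjunction([se, ap, se])
        atts = attribute_network(
            [se, ap, se], ["se", "ap", "se2"],
            SimilarityMatrix(fused.fused.drugs, fused.fused.values, "affinity"),
            noisy_universe.planted,
        )
        summary = contribution_summary(atts)
        for scope, cats in summary.items():
            assert sum(cats.values()) == pytest.approx(1.0, abs=1e-12)

    def test_hand_counted_six_edge_toy(self):
        from dsnfuse.interpretation import EdgeAttribution

        atts = [
            EdgeAttribution(("a", "b"), frozenset(["x"]), True, 1),
            EdgeAttribution(("a", "c"), frozenset(["x"]), True, 1),
            EdgeAttribution(("b", "c"), frozenset(["x", "y"]), True, 1),
            EdgeAttribution(("d", "e"), frozenset(["y"]), True, 2),
            EdgeAttribution(("a", "d"), frozenset(["x", "y", "z"]), False),
            EdgeAttribution(("b", "e"), frozenset(["z"]), False),
        ]
        summary = contribution_summary(atts)
        assert summary["all"]["x"] == pytest.approx(2 / 6)
        assert summary["within"] == pytest.approx({"x": 0.5, "x+y": 0.25, "y": 0.25})
        assert summary["between"] == pytest.approx({"x+y+z": 0.5, "z": 0.5})
        assert summary["cluster_1"] == pytest.approx({"x": 2 / 3, "x+y": 1 / 3})
        assert summary["cluster_2"] == {"y": 1.0}


class TestEnrichmentScore:
    def test_worked_case(self):
        assert enrichment_score(5, 10, 20, 100) == pytest.approx(2.5)

    def test_zero_hits(self):
        assert enrichment_score(0, 10, 20, 100) == 0.0

    def test_whole_universe_cluster_is_unenriched(self):
        assert enrichment_score(20, 100, 20, 100) == pytest.approx(1.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(5, 0, 20, 100)
        with pytest.raises(ValueError):
            enrichment_score(30, 10, 20, 100)

    @given(st.data())
    def test_es_above_one_iff_cluster_rate_exceeds_background(self, data):
        N = data.draw(st.integers(4, 40))
        n = data.draw(st.integers(1, N))
        m = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(m, n)))
        es = enrichment_score(k, n, m, N)
        assert (es > 1) == (k / n > m / N)


class TestHypergeomP:
    def test_worked_case_2_of_2(self):
        assert hypergeom_p(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_zero_threshold_is_certain(self):
        assert hypergeom_p(0, 5, 3, 10) == 1.0

    def test_impossible_k_scores_zero(self):
        assert hypergeom_p(4, 3, 5, 10) == 0.0
        assert hypergeom_p(6, 8, 5, 10) == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_p(1, 11, 5, 10)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            N = int(rng.integers(2, 13))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(m, n) + 1))
            assert hypergeom_p(k, n, m, N) == pytest.approx(
                hypergeom_oracle(k, n, m, N), abs=1e-12
            )


class TestAnnotateClusters:
    def universe(self):
        registry = [record(f"z{i}", ["N01"]) for i in range(10)]
        registry += [record(f"o{i}", ["A01"]) for i in range(90)]
        labels = {r.drug_id: (1 if r.drug_id.startswith("z") else 2) for r in registry}
        return registry, ClusterAssignment(labels, 2)

    def test_pure_cluster_closed_form(self):
        registry, assignment = self.universe()
        records = annotate_clusters(assignment, registry, "atc")
        rec = next(r for r in records if r.cluster == 1 and r.term == "N")
        assert rec.es == pytest.approx(10.0)
        assert rec.p == pytest.approx(1 / comb(100, 10))
        assert rec.significant

    def test_absent_term_has_k0_es0_p1(self):
        registry, assignment = self.universe()
        records = annotate_clusters(assignment, registry, "atc")
        rec = next(r for r in records if r.cluster == 1 and r.term == "A")
        assert rec.k == 0 and rec.es == 0.0 and rec.p == 1.0 and not rec.significant

    def test_multilabel_drug_counts_once_per_term(self):
        registry = [record("m", ["N01", "A01"])] + [record(f"x{i}", ["C01"]) for i in range(9)]
        labels = {r.drug_id: 1 for r in registry}
        labels["x8"] = 2
        assignment = ClusterAssignment(labels, 2)
        records = annotate_clusters(assignment, registry, "atc")
        ks = {(r.term): r.k for r in records if r.cluster == 1}
        assert ks["N"] == 1 and ks["A"] == 1

    def test_custom_vocabulary_mapping(self):
        registry = [record(f"d{i}") for i in range(8)]
        vocab = {f"d{i}": {"soluble"} if i < 4 else {"insoluble"} for i in range(8)}
        assignment = ClusterAssignment({f"d{i}": 1 if i < 4 else 2 for i in range(8)}, 2)
        records = annotate_clusters(assignment, registry, vocab)
        rec = next(r for r in records if r.cluster == 1 and r.term == "soluble")
        assert rec.k == 4 and rec.es == pytest.approx(2.0)

    def test_q_values_are_bh_monotone(self):
        registry, assignment = self.universe()
        records = annotate_clusters(assignment, registry, "atc")
        by_p = sorted(records, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))


class TestFindUnexpectedDrugs:
    def setup_records(self):
        registry = [record(f"n{i}", ["N01"]) for i in range(8)]
        registry.append(record("odd", ["M01"]))
        registry.append(record("multi", ["N02", "A01"]))
        labels = {r.drug_id: 1 for r in registry}
        assignment = ClusterAssignment(labels, 1)
        enrichment = [
            EnrichmentRecord(1, "N", 9, 9, 10, 10, 1.0, 0.001, 0.001, significant=True)
        ]
        return registry, assignment, enrichment

    def test_discordant_member_flagged_with_proposed_term(self):
        registry, assignment, enrichment = self.setup_records()
        flags = find_unexpected_drugs(assignment, enrichment, registry)
        assert [c.drugs for c in flags] == [("odd",)]
        assert flags[0].proposed_terms == {"N"}
        assert flags[0].mode == "unexpected_in_cluster"

    def test_partial_overlap_not_flagged(self):
        registry, assignment, enrichment = self.setup_records()
        flags = find_unexpected_drugs(assignment, enrichment, registry)
        assert all(c.drugs != ("multi",) for c in flags)

    def test_cluster_without_significant_terms_flags_nothing(self):
        registry, assignment, _ = self.setup_records()
        assert find_unexpected_drugs(assignment, [], registry) == []


class TestTopPairsAndGraph:
    def matrix(self):
        drugs = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [1.0, 0.9, 0.2, 0.1],
                [0.9, 1.0, 0.3, 0.2],
                [0.2, 0.3, 1.0, 0.8],
                [0.1, 0.2, 0.8, 1.0],
            ]
        )
        return SimilarityMatrix(drugs, vals)

    registry = [
        record("a", ["N01"]),
        record("b", ["M01"]),
        record("c", ["N02"]),
        record("d", ["N05"]),
    ]

    def test_dominant_pair_ranked_first_and_flagged(self):
        cands = top_pairs(self.matrix(), self.registry, 3)
        assert cands[0].drugs == ("a", "b") and cands[0].rank == 1
        # a(N) vs b(M): discordant -> repositioning signal with symmetric difference
        assert cands[0].proposed_terms == {"N", "M"}
        # c(N) vs d(N): concordant
        assert cands[1].drugs == ("c", "d") and cands[1].proposed_terms == frozenset()

    def test_tie_break_by_canonical_pair_order(self):
        drugs = ["a", "b", "c"]
        vals = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        m = SimilarityMatrix(drugs, vals)
        ranked = ranked_pairs(m)
        assert [(a, b) for a, b, _ in ranked.pairs] == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_flags_agree_with_aor_indicator(self):
        from dsnfuse.evaluation import aor

        cands = top_pairs(self.matrix(), self.registry, 6)
        for c in cands:
            ai = aor([c.drugs], self.registry)
            assert (len(c.proposed_terms) == 0) == (ai == 1.0)

    def test_repositioning_graph_single_edge_and_mean_weight(self):
        import networkx as nx

        drugs = ["a", "b", "c"]
        vals = np.array([[1.0, 0.9, 0.7], [0.9, 1.0, 0.5], [0.7, 0.5, 1.0]])
        m = SimilarityMatrix(drugs, vals)
        reg = [record("a", ["N01"]), record("b", ["M01"]), record("c", ["M05"])]
        g = atc_repositioning_graph(m, reg, top_frac=1.0)
        assert isinstance(g, nx.Graph)
        # pairs (a,b)=0.9 and (a,c)=0.7 span N-M; (b,c) is M-M and is skipped
        assert g["N"]["M"]["weight"] == pytest.approx(0.8)
        assert g["M"]["N"]["weight"] == g["N"]["M"]["weight"]
        assert set(g.nodes) == {"N", "M"}


class TestPropertyDeviation:
    def test_worked_relative_deviation(self):
        D, _ = property_deviation([1.4, 1.6], [0.9, 1.0, 1.1])
        assert D == pytest.approx(0.5)

    def test_no_deviation(self):
        D, _ = property_deviation([0.9, 1.1], [0.5, 1.5])
        assert D == pytest.approx(0.0)

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ValueError):
            property_deviation([1.0, 2.0], [-1.0, 1.0])

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(37)
        false_pos = 0
        for _ in range(100):
            c = rng.normal(size=12)
            r = rng.normal(size=40)
            _, p = property_deviation(c, r)
            false_pos += p < 0.05
        assert false_pos <= 10
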