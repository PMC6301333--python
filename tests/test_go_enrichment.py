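"""GO depth, contingency construction, Fisher test, E score, ranking."""

import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from idrcompare.annotation_model import GOAnnotation, GOOntology
from idrcompare.go_enrichment import (
    ContingencyTable,
    EnrichmentError,
    ZeroCellError,
    bonferroni,
    build_contingency,
    enrichment_E,
    fisher_two_tailed,
    min_depth,
    top_enriched_terms,
)
from conftest import make_dataset


def tiny_ontology():
    """One MF namespace: root -> {a, b}; a -> deep; diamond d with parents
    (root via a) and (deep), so d's min depth is 2 via the short path."""
    g = nx.MultiDiGraph()

    def add(term, name, parents=()):
        g.add_node(term, name=name, namespace="molecular_function")
        for p in parents:
            g.add_edge(term, p, key="is_a")

    add("GO:R", "root")
    add("GO:A", "a", ["GO:R"])
    add("GO:B", "b", ["GO:R"])
    add("GO:DEEP", "deep", ["GO:A"])
    add("GO:D", "diamond", ["GO:A", "GO:DEEP"])
    return GOOntology(g)


class TestMinDepth:
    def test_root_and_child(self):
        onto = tiny_ontology()
        assert min_depth("GO:R", onto) == 0
        assert min_depth("GO:A", onto) == 1

    def test_diamond_takes_shortest_path(self):
        onto = tiny_ontology()
        assert min_depth("GO:D", onto) == 2  # paths of length 2 and 3
        assert min_depth("GO:DEEP", onto) == 2

    def test_unknown_term(self):
        with pytest.raises(EnrichmentError):
            min_depth("GO:NOPE", tiny_ontology())


class TestContingency:
    def annotations(self):
        cluster = [GOAnnotation(f"c{i}", "GO:A", "molecular_function")
                   for i in range(2)]
        cluster += [GOAnnotation(f"c{i}", "GO:B", "molecular_function")
                    for i in range(8)]
        background = cluster + [
            GOAnnotation(f"b{i}", "GO:B", "molecular_function")
            for i in range(5)]
        return cluster, background

    def test_cluster_counts(self):
        cluster, background = self.annotations()
        t = build_contingency("GO:A", cluster, background,
                              "molecular_function")
        assert (t.A, t.C) == (2, 8)
        assert t.A + t.C == 10 and t.B >= t.A

    def test_cluster_equals_background(self):
        cluster, _ = self.annotations()
        t = build_contingency("GO:A", cluster, cluster, "molecular_function")
        assert t.A == t.B and t.C == t.D

    def test_absent_term_gives_zero_A(self):
        cluster, background = self.annotations()
        t = build_contingency("GO:ZZZ", [], background, "molecular_function")
        assert t.A == 0

    def test_duplicate_assignments_deduplicated(self):
        dup = [GOAnnotation("c0", "GO:A", "molecular_function", "IEA"),
               GOAnnotation("c0", "GO:A", "molecular_function", "IDA")]
        t = build_contingency("GO:A", dup, dup, "molecular_function")
        assert t.A == t.B == 1

    def test_term_missing_from_background_rejected(self):
        cluster = [GOAnnotation("c0", "GO:A", "molecular_function")]
        with pytest.raises(EnrichmentError):
            build_contingency("GO:A", cluster,
                              [GOAnnotation("b0", "GO:B",
                                            "molecular_function")],
                              "molecular_function")


class TestFisher:
    @pytest.mark.parametrize("cells, expected", [
        ((2, 2, 2, 2), 1.0),                       # no association
        ((3, 1, 1, 3), 0.48571428571428565),       # enumeration over a=0..4
        ((5, 0, 0, 5), 0.007936507936507936),      # 2 / C(10,5)
    ])
    def test_known_tables(self, cells, expected):
        p = fisher_two_tailed(ContingencyTable("t", *cells))
        assert p == pytest.approx(expected, rel=1e-9)

    @given(a=st.integers(0, 25), b=st.integers(0, 25),
           c=st.integers(0, 25), d=st.integers(0, 25))
    @settings(max_examples=300, derandomize=True)
    def test_matches_exact_enumeration(self, fisher_oracle, a, b, c, d):
        """Two-tailed p equals exhaustive rational-arithmetic enumeration
        for every table with n <= 100."""
        if a + b + c + d == 0:
            return
        p = fisher_two_tailed(ContingencyTable("t", a, b, c, d))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)

    def test_matches_scipy_on_large_table(self):
        table = ContingencyTable("t", 112, 450, 1388, 14550)
        _, p_scipy = stats.fisher_exact([[112, 450], [1388, 14550]])
        assert fisher_two_tailed(table) == pytest.approx(p_scipy, rel=1e-9)


class TestEScore:
    def test_zero_when_rates_equal(self):
        assert enrichment_E(ContingencyTable("t", 5, 10, 50, 100)) == \
               pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        e = enrichment_E(ContingencyTable("t", 10, 1, 90, 99))
        assert e == pytest.approx(math.log10(11), abs=1e-12)

    def test_antisymmetric_under_cluster_background_swap(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = ContingencyTable("t", int(a), int(b), int(c), int(d))
            swapped = ContingencyTable("t", int(b), int(a), int(d), int(c))
            assert enrichment_E(t) == pytest.approx(-enrichment_E(swapped),
                                                    abs=1e-12)

    def test_zero_cell_excluded(self):
        with pytest.raises(ZeroCellError):
            enrichment_E(ContingencyTable("t", 0, 1, 1, 1))

    def test_bonferroni_monotone_and_capped(self):
        assert bonferroni(0.01, 10) == pytest.approx(0.1)
        assert bonferroni(0.5, 10) == 1.0


class TestTopEnrichedTerms:
    def go(self, acc, term):
        return GOAnnotation(acc, term, "molecular_function")

    def test_no_passing_terms_gives_empty_list(self):
        onto = tiny_ontology()
        cluster = make_dataset("d", [], proteins={"c0"})
        annotations = [self.go("c0", "GO:A"), self.go("b0", "GO:A")]
        assert top_enriched_terms(cluster, annotations, {"c0", "b0"},
                                  onto, "molecular_function") == []

    def test_strong_enrichment_is_found_and_depth_filtered(self):
        onto = tiny_ontology()
        # cluster annotated almost solely with GO:A; background spread over B
        annotations = []
        for i in range(20):
            annotations.append(self.go(f"c{i}", "GO:A"))
            annotations.append(self.go(f"c{i}", "GO:B"))
        for i in range(400):
            annotations.append(self.go(f"b{i}", "GO:B"))
        for i in range(5):
            annotations.append(self.go(f"b{i}", "GO:A"))
        cluster = make_dataset("d", [], proteins={f"c{i}" for i in range(20)})
        union = ({f"c{i}" for i in range(20)}
                 | {f"b{i}" for i in range(400)})
        top = top_enriched_terms(cluster, annotations, union, onto,
                                 "molecular_function", k=5)
        assert top and top[0].term_id == "GO:A"
        assert top[0].E > 0 and top[0].p_adj < 0.05
        for r in top:
            assert r.min_depth <= 4

    def test_planted_enrichment_recovered_in_study_corpus(self, study_corpus):
        """The 3-fold planted term ranks in the dataset's top five E scores
        with a Bonferroni-significant p."""
        corpus, prov = study_corpus
        planted = prov["planted_enrichments"][0]
        ds = corpus.dataset(planted["dataset"])
        union = set().union(*(d.proteins for d in corpus.datasets))
        top = top_enriched_terms(ds, corpus.go_annotations, union,
                                 corpus.ontology, planted["aspect"], k=5)
        ids = [r.term_id for r in top]
        assert planted["term_id"] in ids
        hit = top[ids.index(planted["term_id"])]
        assert hit.p_adj < 0.05 and hit.E > 0
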