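"""GO machinery: propagation, enrichment, similarity, scores, matching."""

import itertools
import math

import pytest

from hunter.evaluation import (
    AnnotationCorpus,
    average_similarity,
    coannotation_score,
    colocalization_score,
    enrichment_pvalue,
    f_measure,
    match_gold_standard,
    parse_annotations,
    parse_obo,
    protein_pair_similarity,
    term_similarity,
)
from hunter.graph_io import ComplexCatalogue, LocalizationData, ValidationError

CHAIN_OBO = """format-version: 1.2
ontology: test-chain

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: level1
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: level2
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: level3
namespace: biological_process
is_a: GO:0000003

[Term]
id: GO:0000005
name: leaf
namespace: biological_process
is_a: GO:0000004
"""

DIAMOND_OBO = """format-version: 1.2
ontology: test-diamond

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: parent A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: parent B
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: child of both
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: other leaf
namespace: biological_process
is_a: GO:0000002
"""


def _corpus(tmp_path, obo_text, annotations):
    obo = tmp_path / "t.obo"
    obo.write_text(obo_text)
    ann = tmp_path / "t.tsv"
    ann.write_text("".join(f"{p}\t{t}\t{a}\n" for p, t, a in annotations))
    return parse_annotations(str(ann), parse_obo(str(obo)))


class TestParsingAndPropagation:
    def test_chain_propagates_to_all_ancestors(self, tmp_path):
        corpus = _corpus(tmp_path, CHAIN_OBO, [("prot1", "GO:0000005", "P")])
        assert corpus.aspects["BP"].annotations["prot1"] == {
            f"GO:000000{i}" for i in range(1, 6)
        }

    def test_two_parents_both_lineages(self, tmp_path):
        corpus = _corpus(tmp_path, DIAMOND_OBO, [("prot1", "GO:0000004", "P")])
        assert corpus.aspects["BP"].annotations["prot1"] == {
            "GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"
        }

    def test_root_probability_is_one(self, tmp_path):
        annotations = [(f"prot{i}", "GO:0000005", "P") for i in range(20)]
        corpus = _corpus(tmp_path, CHAIN_OBO, annotations)
        assert corpus.p("GO:0000001", "BP") == 1.0

    def test_p_monotone_child_to_parent(self, tmp_path):
        corpus = _corpus(
            tmp_path,
            DIAMOND_OBO,
            [("a", "GO:0000004", "P"), ("b", "GO:0000005", "P"), ("c", "GO:0000002", "P")],
        )
        dag = corpus.aspects["BP"].dag
        for child, parent in dag.edges:
            assert corpus.p(parent, "BP") >= corpus.p(child, "BP")

    def test_gaf_layout_and_not_qualifier(self, tmp_path):
        obo = tmp_path / "t.obo"
        obo.write_text(CHAIN_OBO)
        gaf = tmp_path / "t.gaf"
        row = ["DB", "prot1", "PROT1", "", "GO:0000005", "REF", "IEA", "", "P",
               "", "", "protein", "taxon:4932", "20090725", "SGD", "", ""]
        not_row = list(row)
        not_row[1], not_row[3] = "prot2", "NOT"
        gaf.write_text(
            "!gaf-version: 2.0\n" + "\t".join(row) + "\n" + "\t".join(not_row) + "\n"
        )
        corpus = parse_annotations(str(gaf), parse_obo(str(obo)))
        assert "prot1" in corpus.aspects["BP"].annotations
        assert "prot2" not in corpus.aspects["BP"].annotations


class TestEnrichmentPvalue:
    def test_exact_combinatorial_case(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert enrichment_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_x_zero_is_one(self):
        assert enrichment_pvalue(10, 5, 4, 0) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_pvalue(10, 12, 4, 2)

    @pytest.mark.parametrize("N,M,n", [(8, 3, 4), (12, 6, 5), (15, 7, 7)])
    def test_matches_exhaustive_sum(self, N, M, n):
        for x in range(0, min(n, M) + 1):
            exact = sum(
                math.comb(M, i) * math.comb(N - M, n - i)
                for i in range(x, min(n, M) + 1)
            ) / math.comb(N, n)
            assert enrichment_pvalue(N, M, n, x) == pytest.approx(exact, rel=1e-12)

    def test_monotone_decreasing_in_x(self):
        values = [enrichment_pvalue(20, 8, 10, x) for x in range(0, 9)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestFMeasure:
    def _two_term_corpus(self, tmp_path):
        obo = """format-version: 1.2
ontology: two-terms

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000010
name: term A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000020
name: term B
namespace: biological_process
is_a: GO:0000001
"""
        annotations = [(f"p{i}", "GO:0000010", "P") for i in range(5)] + [
            (f"q{i}", "GO:0000020", "P") for i in range(5)
        ]
        return _corpus(tmp_path, obo, annotations)

    def test_perfect_clusters_full_specificity(self, tmp_path):
        corpus = self._two_term_corpus(tmp_path)
        clustering = [{f"p{i}" for i in range(5)}, {f"q{i}" for i in range(5)}]
        sens, spec, f = f_measure(clustering, corpus, "BP", alpha=0.01)
        assert (sens, spec, f) == (1.0, 1.0, 1.0)

    def test_harmonic_mean_on_half_sensitivity(self, tmp_path):
        corpus = self._two_term_corpus(tmp_path)
        clustering = [{f"p{i}" for i in range(5)}]
        sens, spec, f = f_measure(clustering, corpus, "BP", alpha=0.01)
        assert sens == 0.5  # term A recovered, term B not
        assert spec == 1.0
        assert f == pytest.approx(2 / 3)

    def test_singletons_have_no_power(self, tmp_path):
        corpus = self._two_term_corpus(tmp_path)
        clustering = [{"p0"}, {"q3"}]
        sens, spec, f = f_measure(clustering, corpus, "BP", alpha=1e-4)
        assert sens == 0.0 and spec == 0.0 and f == 0.0

    def test_bonferroni_tightens_cutoff(self, tmp_path):
        corpus = self._two_term_corpus(tmp_path)
        clustering = [{f"p{i}" for i in range(5)}]
        # term A's p-value is 1/252 ~ 0.004: enriched at raw alpha 0.005,
        # not at the Bonferroni-adjusted 0.005/2
        raw, _, _ = f_measure(clustering, corpus, "BP", alpha=0.005)
        adj, _, _ = f_measure(clustering, corpus, "BP", alpha=0.005, bonferroni=True)
        assert raw == 0.5 and adj == 0.0

    def test_empty_clustering_rejected(self, tmp_path):
        corpus = self._two_term_corpus(tmp_path)
        with pytest.raises(ValidationError):
            f_measure([], corpus, "BP")

    def test_network_background_restricts_counts(self, tmp_path):
        corpus = self._two_term_corpus(tmp_path)
        clustering = [{f"p{i}" for i in range(5)}]
        background = {f"p{i}" for i in range(5)} | {"q0"}
        # N shrinks to 6: term A annotates 5 of 6 -> weaker enrichment
        sens6, _, _ = f_measure(clustering, corpus, "BP", alpha=0.2, background=background)
        assert sens6 in (0.0, 0.5)


class TestTermSimilarity:
    def _corpus(self, tmp_path):
        annotations = (
            [(f"p{i}", "GO:0000004", "P") for i in range(2)]
            + [(f"q{i}", "GO:0000005", "P") for i in range(4)]
            + [(f"r{i}", "GO:0000002", "P") for i in range(4)]
        )
        return _corpus(tmp_path, DIAMOND_OBO, annotations)

    def test_self_similarity_is_one_minus_p(self, tmp_path):
        corpus = self._corpus(tmp_path)
        p = corpus.p("GO:0000004", "BP")
        assert term_similarity("GO:0000004", "GO:0000004", corpus, "BP") == pytest.approx(1 - p)

    def test_root_only_ancestor_gives_zero(self, tmp_path):
        corpus = self._corpus(tmp_path)
        # GO:0000003 (parent B) and GO:0000005 share only the root
        assert term_similarity("GO:0000003", "GO:0000005", corpus, "BP") == 0.0

    def test_symmetry(self, tmp_path):
        corpus = self._corpus(tmp_path)
        a, b = "GO:0000004", "GO:0000005"
        assert term_similarity(a, b, corpus, "BP") == term_similarity(b, a, corpus, "BP")

    def test_matches_bruteforce_ancestor_max(self, tmp_path):
        corpus = self._corpus(tmp_path)
        data = corpus.aspects["BP"]
        terms = [t for t in data.dag if data.p(t) > 0]
        for a1, a2 in itertools.combinations_with_replacement(terms, 2):
            common = corpus.ancestors_or_self(a1, "BP") & corpus.ancestors_or_self(a2, "BP")
            denom = math.log(data.p(a1)) + math.log(data.p(a2))
            best = 0.0
            for c in common:
                pc = data.p(c)
                if 0 < pc < 1 and denom != 0:
                    best = max(best, 2 * math.log(pc) / denom * (1 - pc))
            assert term_similarity(a1, a2, corpus, "BP") == pytest.approx(best)

    def test_unknown_term_rejected(self, tmp_path):
        corpus = self._corpus(tmp_path)
        with pytest.raises(ValidationError):
            term_similarity("GO:9999999", "GO:0000004", corpus, "BP")


class TestScores:
    def _mk_corpus(self, tmp_path):
        """Two clusters sharing leaf terms in BP and MF."""
        obo = """format-version: 1.2
ontology: score-fixture

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000010
name: bp leaf 1
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000011
name: bp leaf 2
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000002
name: mf root
namespace: molecular_function

[Term]
id: GO:0000020
name: mf leaf 1
namespace: molecular_function
is_a: GO:0000002

[Term]
id: GO:0000021
name: mf leaf 2
namespace: molecular_function
is_a: GO:0000002
"""
        annotations = []
        for i in range(4):
            annotations += [(f"p{i}", "GO:0000010", "P"), (f"p{i}", "GO:0000020", "F")]
        for i in range(4):
            annotations += [(f"q{i}", "GO:0000011", "P"), (f"q{i}", "GO:0000021", "F")]
        return _corpus(tmp_path, obo, annotations)

    def test_coannotation_hand_computed(self, tmp_path):
        corpus = self._mk_corpus(tmp_path)
        clustering = [{f"p{i}" for i in range(4)}, {f"q{i}" for i in range(4)}]
        # every within-cluster pair shares one leaf with p = 0.5 -> sim 0.5
        assert coannotation_score(clustering, corpus) == pytest.approx(0.5)

    def test_coannotation_requires_annotated_pairs(self, tmp_path):
        corpus = self._mk_corpus(tmp_path)
        with pytest.raises(ValidationError):
            coannotation_score([{"x1", "x2"}], corpus)

    def test_average_similarity_identical_pair(self, tmp_path):
        obo = CHAIN_OBO
        annotations = [("A", "GO:0000005", "P"), ("B", "GO:0000005", "P")] + [
            (f"f{i}", "GO:0000002", "P") for i in range(18)
        ]
        corpus = _corpus(tmp_path, obo, annotations)
        # p(leaf) = 2/20 = 0.1 -> self-similarity of the shared leaf = 0.9
        assert average_similarity([{"A", "B"}], corpus, "BP") == pytest.approx(0.9)

    def test_average_similarity_flat_pair_enumeration(self, tmp_path):
        corpus = self._mk_corpus(tmp_path)
        sets = [{"p0", "p1", "q0"}, {"q1", "q2"}]
        sims = []
        for s in sets:
            for a, b in itertools.combinations(sorted(s), 2):
                v = protein_pair_similarity(a, b, corpus, "BP")
                if v is not None:
                    sims.append(v)
        expected = sum(sims) / len(sims)
        assert average_similarity(sets, corpus, "BP") == pytest.approx(expected)

    def test_colocalization_perfect_and_split(self):
        loc = LocalizationData({"n": {"a", "b", "c", "d"}, "c": {"e", "f"}})
        assert colocalization_score([{"a", "b"}, {"e", "f"}], loc) == 1.0
        # cluster of 4 split 2/2 across locations contributes 2/4
        loc2 = LocalizationData({"n": {"a", "b"}, "c": {"x", "y"}})
        assert colocalization_score([{"a", "b", "x", "y"}], loc2) == 0.5

    def test_colocalization_bruteforce_fixture(self):
        loc = LocalizationData(
            {"l1": {"a", "b", "c"}, "l2": {"c", "d"}, "l3": {"e"}}
        )
        clustering = [{"a", "b", "d"}, {"c", "d"}, {"e", "zz"}]
        num = sum(
            max(len(set(c) & O) for O in loc.locations.values()) for c in clustering
        )
        den = sum(len(c) for c in clustering)
        assert colocalization_score(clustering, loc) == pytest.approx(num / den)

    def test_colocalization_empty_rejected(self):
        with pytest.raises(ValidationError):
            colocalization_score([{"a"}], LocalizationData({}))


class TestGoldStandard:
    def test_identical_clustering_perfect(self):
        cat = ComplexCatalogue({"c1": {"a", "b", "c"}, "c2": {"x", "y", "z"}})
        universe = {"a", "b", "c", "x", "y", "z"} | {f"u{i}" for i in range(30)}
        matched, precision, recall, f = match_gold_standard(
            [{"a", "b", "c"}, {"x", "y", "z"}], cat, alpha=0.01, universe=universe
        )
        assert (matched, precision, recall, f) == (2, 1.0, 1.0, 1.0)

    def test_disjoint_clustering_zero_precision(self):
        cat = ComplexCatalogue({"c1": {"a", "b", "c"}})
        matched, precision, recall, f = match_gold_standard(
            [{"x", "y", "z"}], cat, alpha=0.01
        )
        assert matched == 0 and precision == 0.0 and recall == 0.0 and f == 0.0

    def test_matches_direct_pvalue_screen(self):
        cat = ComplexCatalogue({"c1": {"a", "b", "c", "d"}})
        universe = {"a", "b", "c", "d"} | {f"u{i}" for i in range(20)}
        cluster = {"a", "b", "c", "u0"}
        p = enrichment_pvalue(len(universe), 4, 4, 3)
        matched, precision, recall, _ = match_gold_standard(
            [cluster], cat, alpha=0.01, universe=universe
        )
        assert (matched == 1) == (p < 0.01)
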