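import math

import numpy as np
import pytest

from hporank.ontology import AnnotationSet, compute_ic
from hporank.scoring import (MatchClass, WeightConfig, match_class,
                             score_all_genes, score_gene)
from oracle_utils import brute_force_score, build_graph, random_dag

LN4 = math.log(4)


@pytest.fixture()
def chain_ic(chain_graph):
    # 4 genes; B annotated once -> IC(B) = ln 4
    ann = AnnotationSet({"G1": {"B"}, "G2": {"A"}, "G3": {"A"}, "G4": {"A"}})
    return ann, compute_ic(chain_graph, ann, propagate=False)


class TestMatchClass:
    def test_direct(self, chain_graph):
        assert match_class(chain_graph, {"B"}, "B") == MatchClass.DIRECT

    def test_patient_term_more_general_is_ancestor(self, chain_graph):
        # gene annotated with B; patient reports A (an ancestor of B)
        assert match_class(chain_graph, {"B"}, "A") == MatchClass.ANCESTOR

    def test_patient_term_more_specific_is_descendant(self, chain_graph):
        assert match_class(chain_graph, {"A"}, "B") == MatchClass.DESCENDANT

    def test_unrelated_term_is_none(self, diamond_graph):
        assert match_class(diamond_graph, {"A"}, "B") == MatchClass.NONE

    def test_direct_takes_precedence(self, chain_graph):
        # A is both annotated (direct) and an ancestor of annotated B
        assert match_class(chain_graph, {"A", "B"}, "A") == MatchClass.DIRECT


class TestScoreGene:
    def test_direct_match_hand_value(self, chain_graph, chain_ic):
        ann, ic = chain_ic
        bd = score_gene(chain_graph, ic, "G1", {"B"}, ["B"])
        assert bd.total == pytest.approx(5 * LN4)  # 6.9315
        assert bd.rows[0].match == MatchClass.DIRECT

    def test_descendant_match_hand_value(self, chain_graph, chain_ic):
        ann, ic = chain_ic
        bd = score_gene(chain_graph, ic, "G2", {"A"}, ["B"])
        assert bd.total == pytest.approx(0.05 * LN4)  # 0.0693

    def test_ancestor_match_hand_value(self, chain_graph, chain_ic):
        ann, ic = chain_ic
        bd = score_gene(chain_graph, ic, "G1", {"B"}, ["A"])
        assert bd.total == pytest.approx(2 * -math.log(3 / 4))

    def test_no_match_scores_zero(self, diamond_graph):
        ann = AnnotationSet({"G1": {"A"}, "G2": {"B"}})
        ic = compute_ic(diamond_graph, ann, propagate=False)
        assert score_gene(diamond_graph, ic, "G1", {"A"}, ["B"]).total == 0.0

    def test_pathogenic_bonus(self, chain_graph, chain_ic):
        _, ic = chain_ic
        w = WeightConfig(w_known_pathogenic=3.0)
        bd = score_gene(chain_graph, ic, "G1", {"B"}, ["B"], w,
                        has_known_pathogenic_variant=True)
        assert bd.pathogenic_bonus == 3.0
        assert bd.total == pytest.approx(5 * LN4 + 3.0)

    def test_term_without_ic_contributes_zero(self, chain_graph):
        ann = AnnotationSet({"G1": {"B"}})
        ic = compute_ic(chain_graph, ann, propagate=False)  # root, A absent
        bd = score_gene(chain_graph, ic, "G1", {"B"}, ["A", "B"])
        row_a = next(r for r in bd.rows if r.term == "A")
        assert row_a.contribution == 0.0

    def test_breakdown_total_is_sum_of_parts(self, chain_graph, chain_ic):
        _, ic = chain_ic
        bd = score_gene(chain_graph, ic, "G1", {"B"}, ["A", "B", "root"])
        assert bd.total == pytest.approx(sum(r.contribution for r in bd.rows))


def _random_instance(rng):
    n = int(rng.integers(3, 26))
    parents = random_dag(rng, n)
    graph = build_graph(parents)
    terms = sorted(parents)
    n_genes = int(rng.integers(1, 11))
    g2t = {f"G{i}": {terms[int(j)] for j in
                     rng.choice(n, size=int(rng.integers(1, 4)), replace=False)}
           for i in range(n_genes)}
    ann = AnnotationSet(g2t)
    ic = compute_ic(graph, ann, propagate=True)
    patient = [terms[int(j)] for j in
               rng.choice(n, size=int(rng.integers(1, 6)), replace=True)]
    return parents, graph, ann, ic, patient


def test_matches_brute_force_oracle_on_random_triples():
    """score_gene must equal exhaustive pair enumeration with explicit
    path search on random (ontology, annotation, patient) triples."""
    rng = np.random.default_rng(11)
    w = WeightConfig()
    for _ in range(60):
        parents, graph, ann, ic, patient = _random_instance(rng)
        for gene, gts in ann.gene_to_terms.items():
            expected = brute_force_score(parents, dict(ic.ic), set(gts),
                                         patient, w.w_direct, w.w_ancestor,
                                         w.w_descendant)
            got = score_gene(graph, ic, gene, gts, patient, w).total
            assert got == pytest.approx(expected, abs=1e-10)


class TestWeightProperties:
    def test_increasing_direct_weight_never_decreases_scores(self):
        rng = np.random.default_rng(5)
        _, graph, ann, ic, patient = _random_instance(rng)
        lo = WeightConfig(w_direct=1)
        hi = WeightConfig(w_direct=10)
        for gene, gts in ann.gene_to_terms.items():
            assert (score_gene(graph, ic, gene, gts, patient, hi).total
                    >= score_gene(graph, ic, gene, gts, patient, lo).total)

    def test_all_zero_weights_give_zero_scores(self, chain_graph, chain_ic):
        _, ic = chain_ic
        w = WeightConfig(0, 0, 0, 0)
        assert score_gene(chain_graph, ic, "G1", {"B"}, ["A", "B"], w).total == 0.0

    def test_unmatched_patient_term_changes_nothing(self, diamond_graph):
        ann = AnnotationSet({"G1": {"A"}, "G2": {"B"}})
        ic = compute_ic(diamond_graph, ann, propagate=False)
        base = score_gene(diamond_graph, ic, "G1", {"A"}, ["A"]).total
        plus = score_gene(diamond_graph, ic, "G1", {"A"}, ["A", "B"]).total
        assert plus == base

    def test_direct_match_with_positive_ic_strictly_increases(self, chain_graph,
                                                              chain_ic):
        _, ic = chain_ic
        base = score_gene(chain_graph, ic, "G1", {"B", "A"}, ["A"]).total
        plus = score_gene(chain_graph, ic, "G1", {"B", "A"}, ["A", "B"]).total
        assert plus > base

    def test_scale_equivariance_preserves_scores_and_ranks(self):
        rng = np.random.default_rng(9)
        _, graph, ann, ic, patient = _random_instance(rng)
        w1 = WeightConfig(5, 2, 0.05)
        w3 = WeightConfig(15, 6, 0.15)
        genes = sorted(ann.gene_to_terms)
        s1 = [score_gene(graph, ic, g, ann.gene_to_terms[g], patient, w1).total
              for g in genes]
        s3 = [score_gene(graph, ic, g, ann.gene_to_terms[g], patient, w3).total
              for g in genes]
        assert s3 == pytest.approx([3 * s for s in s1])
        assert np.argsort(s1).tolist() == np.argsort(s3).tolist()


class TestScoreAllGenes:
    def test_direct_match_gene_ranks_strictly_highest(self, chain_graph):
        ann = AnnotationSet({"HIT": {"B"}, "MISS1": {"A"}, "MISS2": {"A"}})
        ic = compute_ic(chain_graph, ann, propagate=True)
        scores = score_all_genes(chain_graph, ic, ann.gene_to_terms,
                                 ["HIT", "MISS1", "MISS2"], ["B"])
        assert scores["HIT"].total > max(scores["MISS1"].total,
                                         scores["MISS2"].total)

    def test_empty_candidate_set(self, chain_graph, chain_ic):
        ann, ic = chain_ic
        assert score_all_genes(chain_graph, ic, ann.gene_to_terms, [], ["B"]) == {}

    def test_unannotated_candidates_kept_with_zero_score(self, chain_graph,
                                                         chain_ic):
        ann, ic = chain_ic
        scores = score_all_genes(chain_graph, ic, ann.gene_to_terms,
                                 ["G1", "NOVEL"], ["B"])
        assert scores["NOVEL"].total == 0.0

    def test_identical_annotations_give_identical_breakdowns(self, chain_graph,
                                                             chain_ic):
        _, ic = chain_ic
        g2t = {"GA": frozenset({"B"}), "GB": frozenset({"B"})}
        scores = score_all_genes(chain_graph, ic, g2t, ["GA", "GB"], ["A", "B"])
        assert scores["GA"].total == scores["GB"].total
        assert [r.match for r in scores["GA"].rows] == \
               [r.match for r in scores["GB"].rows]
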