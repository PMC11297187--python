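import pytest

from bxdseeker.evidence_integration import (CandidateGene, GeneCluster,
                                            call_adjacent_clusters,
                                            intersect_candidates,
                                            name_cluster_genes,
                                            type_cluster_architectures)
from bxdseeker.genome_model import GeneRecord, StrainGenome


def _reference(n_genes=25, contig="c1"):
    genes = []
    pos = 0
    for i in range(n_genes):
        genes.append(GeneRecord(f"g{i}", contig, pos, pos + 9, "+", "ATGAAATAA"))
        pos += 20
    return StrainGenome("ref", {contig: "A" * pos}, genes)


def _candidates(indices, reference):
    return [CandidateGene(f"g{i}", True, False, False,
                          reference.genes[0].contig_id, i) for i in indices]


class TestVenn:
    def test_enumerated_example(self):
        venn, cands = intersect_candidates({"1", "2", "3"}, {"2", "3", "4"},
                                           {"3", "4", "5"})
        assert venn["all_three"] == 1
        assert venn["kmer_family"] == 1
        assert venn["kmer_de"] == 0
        assert venn["family_de"] == 1
        assert venn["kmer_only"] == 1
        assert venn["family_only"] == 0
        assert venn["de_only"] == 1
        assert sum(venn.values()) == len({"1", "2", "3", "4", "5"})
        assert len(cands) == 5

    def test_identical_sets(self):
        venn, _ = intersect_candidates({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert venn["all_three"] == 2
        assert sum(v for k, v in venn.items() if k != "all_three") == 0

    def test_disjoint_sets(self):
        venn, _ = intersect_candidates({"a"}, {"b"}, {"c"})
        assert venn == {"kmer_only": 1, "family_only": 1, "de_only": 1,
                        "kmer_family": 0, "kmer_de": 0, "family_de": 0,
                        "all_three": 0}

    def test_two_set_mode(self):
        venn, cands = intersect_candidates({"a", "b"}, {"b"}, None)
        assert venn["kmer_family"] == 1
        assert venn["de_only"] == 0
        assert all(not c.from_de for c in cands)

    def test_candidate_needs_evidence(self):
        with pytest.raises(ValueError):
            CandidateGene("g", False, False, False)


class TestAdjacency:
    def test_gap_tolerant_run(self):
        ref = _reference()
        clusters = call_adjacent_clusters(_candidates([5, 6, 7, 9, 20], ref),
                                          ref, max_gap=1, min_genes=3)
        assert len(clusters) == 1
        assert clusters[0].gene_ids == ["g5", "g6", "g7", "g9"]

    def test_strict_adjacency(self):
        ref = _reference()
        clusters = call_adjacent_clusters(_candidates([1, 2, 3], ref), ref,
                                          max_gap=0, min_genes=3)
        assert len(clusters) == 1
        assert clusters[0].gene_ids == ["g1", "g2", "g3"]

    def test_min_genes_unmet(self):
        ref = _reference()
        assert call_adjacent_clusters(_candidates([1, 2, 3, 4], ref), ref,
                                      max_gap=0, min_genes=5) == []

    def test_infinite_gap_merges_contig(self):
        ref = _reference()
        clusters = call_adjacent_clusters(_candidates([0, 10, 24], ref), ref,
                                          max_gap=10**9, min_genes=3)
        assert len(clusters) == 1
        assert clusters[0].size == 3

    def test_unknown_candidate_rejected(self):
        ref = _reference()
        with pytest.raises(ValueError):
            call_adjacent_clusters([CandidateGene("nope", True, False, False)],
                                   ref)

    def test_invariant_to_gene_relabelling(self):
        ref = _reference()
        renamed = StrainGenome("ref2", dict(ref.contigs),
                               [GeneRecord(f"x{g.gene_id}", g.contig_id,
                                           g.start, g.end, g.strand, g.nt_seq)
                                for g in ref.genes])
        c1 = call_adjacent_clusters(_candidates([3, 4, 5], ref), ref)
        c2 = call_adjacent_clusters(
            [CandidateGene(f"xg{i}", True, False, False) for i in (3, 4, 5)],
            renamed)
        assert [g.replace("x", "") for g in c2[0].gene_ids] == c1[0].gene_ids


class TestNaming:
    def test_fifteen_genes_named_a_through_o(self):
        cluster = GeneCluster("c1", [f"g{i}" for i in range(15)])
        name_cluster_genes(cluster)
        assert [cluster.names[f"g{i}"] for i in range(15)] == \
               [f"bxd{ch}" for ch in "ABCDEFGHIJKLMNO"]

    def test_two_genes(self):
        cluster = name_cluster_genes(GeneCluster("c1", ["x", "y"]))
        assert list(cluster.names.values()) == ["bxdA", "bxdB"]

    def test_alphabet_rollover(self):
        cluster = name_cluster_genes(GeneCluster("c1",
                                                 [f"g{i}" for i in range(27)]))
        assert cluster.names["g25"] == "bxdZ"
        assert cluster.names["g26"] == "bxdAA"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            name_cluster_genes(GeneCluster("c1", []))


class TestArchitectureTyping:
    def test_identical_sequences_share_type(self):
        types = type_cluster_architectures({"s1": ["f1", "f2", "f3"],
                                            "s2": ["f1", "f2", "f3"]})
        assert types["s1"] == types["s2"] == "I"

    def test_reversal_invariance(self):
        types = type_cluster_architectures({"s1": ["f1", "f2", "f3"],
                                            "s2": ["f3", "f2", "f1"]})
        assert types["s1"] == types["s2"]

    def test_insertion_makes_new_type(self):
        base = ["f1", "f2", "f3"]
        extended = ["f1", "x1", "x2", "x3", "x4", "x5", "f2", "f3"]
        types = type_cluster_architectures({"s1": base, "s2": base,
                                            "s3": extended})
        assert types["s1"] == types["s2"] == "I"
        assert types["s3"] == "II"

    def test_types_ordered_by_class_size(self):
        types = type_cluster_architectures({
            "a": ["f1"], "b": ["f2"], "c": ["f2"], "d": ["f2"],
        })
        assert types["b"] == "I"     # the larger class gets type I
        assert types["a"] == "II"

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            type_cluster_architectures({"s1": ["f1", ""]})
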