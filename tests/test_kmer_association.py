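import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import revcomp_genomeset
from bxdseeker._aligner import nt_identity
from bxdseeker.genome_model import (GeneRecord, GenomeSet, StrainGenome,
                                    reverse_complement)
from bxdseeker.kmer_association import (KmerParams, associate_from_matrix,
                                        build_kmer_matrix, canonical_kmers,
                                        centroid_hit_lists, decode_kmer,
                                        encode_kmers, greedy_cluster_genes,
                                        map_high_kmers_to_genes)
from bxdseeker.stats import benjamini_hochberg, fisher_exact_2x2, presence_fisher

nt_seqs = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestCanonicalKmers:
    def test_enumerated_example(self):
        assert canonical_kmers("ACGTA", 4) == {"ACGT", "CGTA"}

    def test_windows_with_n_skipped(self):
        assert canonical_kmers("ACNGT", 3) == set()

    @given(nt_seqs)
    def test_reverse_complement_invariance(self, seq):
        k = 5
        assert canonical_kmers(seq, k) == canonical_kmers(reverse_complement(seq), k)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80),
           st.integers(min_value=1, max_value=12))
    def test_packed_encoding_matches_string_implementation(self, seq, k):
        """The fast 2-bit path and the plain string path agree exactly."""
        from_strings = canonical_kmers(seq, k)
        from_codes = {decode_kmer(int(c), k) for c in encode_kmers(seq, k)}
        assert from_codes == from_strings


def _one_gene_strain(sid, seq):
    return StrainGenome(sid, {f"{sid}_c": seq},
                        [GeneRecord(f"{sid}_g", f"{sid}_c", 0, len(seq), "+", seq)])


def _tiny_panel():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    shared = "".join(bases[rng.integers(0, 4, 60)])
    unique = "".join(bases[rng.integers(0, 4, 60)])
    pos = _one_gene_strain("P1", shared)
    neg = _one_gene_strain("N1", unique)
    return GenomeSet([pos, neg], {"P1": "positive", "N1": "negative"})


class TestKmerMatrix:
    def test_disjoint_strains_block_diagonal(self):
        gs = _tiny_panel()
        m = build_kmer_matrix(gs, KmerParams(k=21))
        assert m.presence.sum(axis=1).max() == 1   # no kmer shared
        assert (m.scores != 0).all()
        assert set(np.unique(m.scores)) <= {-1, 1}

    def test_score_bounds(self, default_matrix, default_panel):
        genomeset, _ = default_panel
        n_pos, n_neg = len(genomeset.positives), len(genomeset.negatives)
        assert default_matrix.scores.min() >= -n_neg
        assert default_matrix.scores.max() <= n_pos

    def test_shared_kmer_scoring_arithmetic(self):
        seq = "ACGTACGTACGTACGTACGTACGTA"
        strains = [_one_gene_strain(sid, seq) for sid in ("P1", "P2", "N1")]
        gs = GenomeSet(strains, {"P1": "positive", "P2": "positive",
                                 "N1": "negative"})
        m = build_kmer_matrix(gs, KmerParams(k=21))
        assert (m.scores == 2 - 1).all()

    def test_memory_guard(self, small_panel):
        genomeset, _ = small_panel
        with pytest.raises(MemoryError):
            build_kmer_matrix(genomeset, KmerParams(max_distinct_kmers=10))


class TestHighKmerMapping:
    def test_unattainable_score_gives_empty_list(self, small_panel):
        genomeset, _ = small_panel
        n_pos = len(genomeset.positives)
        m = build_kmer_matrix(genomeset)
        genes = map_high_kmers_to_genes(m, genomeset, genomeset.strain_ids[0],
                                        KmerParams(min_score=n_pos + 1))
        assert genes == []

    def test_planted_cluster_genes_recovered(self, small_panel):
        genomeset, truth = small_panel
        ref = truth.carriers[0]
        m = build_kmer_matrix(genomeset)
        genes = map_high_kmers_to_genes(m, genomeset, ref,
                                        KmerParams(min_score=len(genomeset.positives)))
        assert set(truth.planted_gene_ids[ref]) <= set(genes)


class TestGreedyClustering:
    def test_identical_pair_plus_outlier(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 90)])
        outlier = "".join(bases[rng.integers(0, 4, 90)])
        assert nt_identity(a, outlier) < 0.7   # oracle check of the fixture
        clusters = greedy_cluster_genes([("a1", a), ("a2", a), ("b", outlier)], 0.7)
        assert len(clusters) == 2
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_threshold_one_separates_distinct(self):
        seqs = [("x", "ACGTACGTACGT"), ("y", "ACGTACGTACGA"), ("z", "TTTTACGTACGT")]
        clusters = greedy_cluster_genes(seqs, 1.0)
        assert len(clusters) == 3

    def test_single_input(self):
        clusters = greedy_cluster_genes([("only", "ACGTACGT")], 0.7)
        assert len(clusters) == 1
        assert clusters[0].members == ["only"]

    def test_every_input_assigned_once(self, small_panel):
        genomeset, _ = small_panel
        seqs = [(g.gene_id, g.nt_seq)
                for g in genomeset.strains[0].genes[:20]]
        clusters = greedy_cluster_genes(seqs, 0.7)
        assigned = [m for c in clusters for m in c.members]
        assert sorted(assigned) == sorted(gid for gid, _ in seqs)


class TestCentroidHits:
    def test_identical_gene_in_many_strains(self, small_panel):
        genomeset, truth = small_panel
        ref = truth.carriers[0]
        gid = truth.planted_gene_ids[ref][0]
        seq = genomeset.strain(ref).gene(gid).nt_seq
        clusters = greedy_cluster_genes([(gid, seq)], 0.7)
        all_genes = [(sid, g.gene_id, g.nt_seq)
                     for sid in genomeset.strain_ids
                     for g in genomeset.strain(sid).genes]
        hits = centroid_hit_lists(clusters, all_genes)
        strains_hit = {s for s, _ in hits[gid]}
        assert strains_hit == set(truth.carriers)
        assert (ref, gid) in hits[gid]

    def test_unrelated_centroid_hits_only_itself(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        lone = "".join(bases[rng.integers(0, 4, 120)])
        other = "".join(bases[rng.integers(0, 4, 120)])
        clusters = greedy_cluster_genes([("lone", lone)], 0.7)
        hits = centroid_hit_lists(clusters, [("s1", "lone", lone),
                                             ("s2", "other", other)])
        assert hits["lone"] == [("s1", "lone")]


class TestFisher:
    def test_perfect_association_closed_form(self):
        from math import comb
        _odds, p = fisher_exact_2x2(16, 0, 0, 23, alternative="greater")
        assert p == pytest.approx(1 / comb(39, 16), rel=1e-12)

    def test_ubiquitous_feature_uninformative(self):
        _odds, p = fisher_exact_2x2(16, 0, 23, 0)
        assert p == 1.0

    def test_two_sided_matches_enumeration(self):
        """Sweep of small tables against exact integer-arithmetic enumeration."""
        from math import comb
        for r1 in range(0, 13):
            for r2 in range(0, 13):
                if r1 + r2 == 0:
                    continue
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        k = a + c
                        lo, hi = max(0, k - r2), min(k, r1)
                        w_obs = comb(r1, a) * comb(r2, c)
                        total = sum(comb(r1, x) * comb(r2, k - x)
                                    for x in range(lo, hi + 1)
                                    if comb(r1, x) * comb(r2, k - x) <= w_obs)
                        expected = total / comb(r1 + r2, k)
                        _o, p = fisher_exact_2x2(a, r1 - a, c, r2 - c)
                        assert p == pytest.approx(expected, abs=1e-12)

    def test_presence_fisher_table_margins(self, small_panel):
        genomeset, truth = small_panel
        res = presence_fisher(truth.carriers, genomeset, unit_id="cluster")
        assert res.a + res.b == len(genomeset.positives)
        assert res.c + res.d == len(genomeset.negatives)
        assert 0 <= res.p <= 1


class TestBenjaminiHochberg:
    def test_worked_vector(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        assert (benjamini_hochberg(p) >= p).all()


class TestAssociationInvariance:
    def test_reverse_complementing_genomes_changes_nothing(self, small_panel):
        genomeset, truth = small_panel
        ref = truth.carriers[0]
        fwd = build_kmer_matrix(genomeset)
        rev = build_kmer_matrix(revcomp_genomeset(genomeset))
        assert np.array_equal(fwd.kmer_codes, rev.kmer_codes)
        assert np.array_equal(fwd.presence, rev.presence)
        rep_f = associate_from_matrix(fwd, genomeset, ref)
        rep_r = associate_from_matrix(rev, revcomp_genomeset(genomeset), ref)
        assert rep_f.significant_genes == rep_r.significant_genes
        assert sorted(rep_f.high_kmer_genes) == sorted(rep_r.high_kmer_genes)
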