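"""Kmer-based genotype-phenotype association.

The pipeline mirrors a microbial-GWAS screen built from presence/absence of
canonical 21-mers:

1. every strain's scaffolds (or genes) are decomposed into unique canonical
   kmers and merged into one boolean kmer-by-strain matrix;
2. each kmer is scored ``(#positive strains containing it) - (#negative
   strains containing it)``;
3. reference-strain genes containing at least one high-scoring kmer are
   collected and greedily clustered at a 70% identity cut-off;
4. each centroid is searched against all genes of all strains to build a
   per-centroid hit list (shared-kmer containment plus alignment identity);
5. strain-level presence of each hit list is tested against the phenotype
   with Fisher's exact test, Benjamini-Hochberg corrected across centroids.

Kmers are held as 2-bit-packed integers in sorted numpy arrays, so the whole
matrix for a ~40-genome bacterial panel fits comfortably in memory; any
window containing an ambiguous base (N) is skipped, matching exact-match
kmer counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aligner import nt_identity
from .genome_model import GenomeSet, GenomeModelError, gene_sequences, reverse_complement
from .stats import AssociationResult, adjust_results, presence_fisher

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass
class KmerParams:
    """Tunable knobs of the kmer association pipeline."""

    k: int = 21
    min_score: int = 7
    cluster_identity: float = 0.70
    hit_min_identity: float = 0.70
    hit_min_containment: float = 0.10
    alpha: float = 0.05           # BH level reported alongside
    sig_p: float = 0.05           # raw-p threshold for the significant gene list
    alternative: str = "two-sided"
    canonical: bool = True
    region: str = "scaffold"      # or "genes": restrict counting to gene regions
    max_distinct_kmers: int = 200_000_000

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        for name in ("cluster_identity", "hit_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.region not in ("scaffold", "genes"):
            raise ValueError("region must be 'scaffold' or 'genes'")


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Unique canonical kmers of ``seq`` (windows containing N are skipped).

    Canonical means the lexicographic minimum of a window and its reverse
    complement; sequences and their reverse complements therefore yield
    identical sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = seq.upper()
    out: set[str] = set()
    for i in range(len(s) - k + 1):
        window = s[i:i + k]
        if "N" in window:
            continue
        rc = reverse_complement(window)
        out.add(min(window, rc))
    return out


def encode_kmers(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """Sorted unique 2-bit-packed (canonical) kmer codes of a sequence."""
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31] for 64-bit packing")
    b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (b >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    b64 = b.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b64[j:j + n]
    if canonical:
        comp = (np.uint64(3) - b64) & np.uint64(3)
        rc = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            rc |= comp[j:j + n] << np.uint64(2 * j)
        codes = np.minimum(fwd, rc)
    else:
        codes = fwd
    return np.unique(codes[valid])


def decode_kmer(code: int, k: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


@dataclass
class KmerMatrix:
    """Boolean canonical-kmer x strain presence matrix with phenotype scores."""

    k: int
    kmer_codes: np.ndarray          # sorted uint64, one per distinct kmer
    strain_ids: list[str]
    presence: np.ndarray            # bool, shape (n_kmers, n_strains)
    scores: np.ndarray = field(default=None)  # int16, per kmer

    @property
    def n_kmers(self) -> int:
        return int(self.kmer_codes.size)

    def kmer_strings(self, indices: np.ndarray | None = None) -> list[str]:
        codes = self.kmer_codes if indices is None else self.kmer_codes[indices]
        return [decode_kmer(int(c), self.k) for c in codes]

    def score_against(self, genomeset: GenomeSet) -> np.ndarray:
        """Phenotype scores (#positives carrying - #negatives carrying)."""
        ids = self.strain_ids
        pos = np.array([genomeset.phenotype[s] == "positive" for s in ids])
        if not hasattr(self, "_row_total") or self._row_total is None:
            self._row_total = self.presence.sum(axis=1).astype(np.int32)
        n_pos = self.presence[:, pos].sum(axis=1).astype(np.int32)
        return (2 * n_pos - self._row_total).astype(np.int16)

    def high_scoring(self, min_score: int) -> np.ndarray:
        """Sorted codes of kmers with score >= min_score."""
        if self.scores is None:
            raise ValueError("scores not computed")
        return self.kmer_codes[self.scores >= min_score]


def build_kmer_matrix(genomeset: GenomeSet, params: KmerParams | None = None) -> KmerMatrix:
    """Union all strains' canonical kmer sets into one presence matrix."""
    params = params or KmerParams()
    if not genomeset.strains:
        raise GenomeModelError("empty genome set")
    total_bases = sum(len(c) for s in genomeset.strains for c in s.contigs.values())
    if total_bases > params.max_distinct_kmers:
        raise MemoryError(
            f"estimated {total_bases} distinct kmers exceeds cap "
            f"{params.max_distinct_kmers}; raise max_distinct_kmers to proceed"
        )
    per_strain: list[np.ndarray] = []
    for strain in genomeset.strains:
        if params.region == "scaffold":
            seqs = strain.contigs.values()
        else:
            seqs = (g.nt_seq for g in strain.genes)
        parts = [encode_kmers(s, params.k, params.canonical) for s in seqs]
        codes = (np.unique(np.concatenate(parts)) if parts
                 else np.empty(0, dtype=np.uint64))
        per_strain.append(codes)
    universe = np.unique(np.concatenate(per_strain)) if per_strain else \
        np.empty(0, dtype=np.uint64)
    presence = np.zeros((universe.size, len(per_strain)), dtype=bool)
    for j, codes in enumerate(per_strain):
        presence[np.searchsorted(universe, codes), j] = True
    matrix = KmerMatrix(params.k, universe, list(genomeset.strain_ids), presence)
    matrix.scores = matrix.score_against(genomeset)
    return matrix


def map_high_kmers_to_genes(matrix: KmerMatrix, genomeset: GenomeSet,
                            reference_strain: str,
                            params: KmerParams | None = None) -> list[str]:
    """Reference-strain genes containing >=1 kmer scoring >= min_score."""
    params = params or KmerParams()
    reference = genomeset.strain(reference_strain)
    high = matrix.high_scoring(params.min_score)
    hits: list[str] = []
    if high.size == 0:
        return hits
    for gene in reference.genes:
        codes = encode_kmers(gene.nt_seq, params.k, params.canonical)
        if codes.size == 0:
            continue
        idx = np.searchsorted(high, codes)
        idx[idx == high.size] = 0
        if (high[idx] == codes).any():
            hits.append(gene.gene_id)
    return hits


@dataclass
class CentroidCluster:
    centroid_id: str
    centroid_seq: str
    members: list[str]


def greedy_cluster_genes(gene_seqs: list[tuple[str, str]],
                         identity_threshold: float) -> list[CentroidCluster]:
    """Greedy length-sorted centroid clustering at a global-identity cut-off.

    Sequences are processed longest first; each joins the earliest centroid
    it matches at >= ``identity_threshold`` (semi-global alignment identity),
    otherwise it founds a new centroid.  Every input is assigned exactly once.
    """
    if not gene_seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(gene_seqs)),
                   key=lambda i: (-len(gene_seqs[i][1]), i))
    clusters: list[CentroidCluster] = []
    for i in order:
        gid, seq = gene_seqs[i]
        for cluster in clusters:
            if nt_identity(seq, cluster.centroid_seq) >= identity_threshold:
                cluster.members.append(gid)
                break
        else:
            clusters.append(CentroidCluster(gid, seq, [gid]))
    return clusters


def gene_kmer_sets(all_genes: list[tuple[str, str, str]],
                   params: KmerParams | None = None,
                   ) -> dict[tuple[str, str], np.ndarray]:
    """Sorted canonical kmer codes per (strain_id, gene_id), reusable across searches."""
    params = params or KmerParams()
    return {(sid, gid): encode_kmers(seq, params.k, params.canonical)
            for sid, gid, seq in all_genes}


def _shared_count(sorted_a: np.ndarray, sorted_b: np.ndarray) -> int:
    """|a intersect b| for two sorted unique code arrays."""
    if sorted_a.size == 0 or sorted_b.size == 0:
        return 0
    idx = np.searchsorted(sorted_a, sorted_b)
    idx[idx == sorted_a.size] = 0
    return int((sorted_a[idx] == sorted_b).sum())


def centroid_hit_lists(centroids: list[CentroidCluster],
                       all_genes: list[tuple[str, str, str]],
                       params: KmerParams | None = None,
                       kmer_cache: dict[tuple[str, str], np.ndarray] | None = None,
                       ) -> dict[str, list[tuple[str, str]]]:
    """Homology hit list per centroid across every gene of every strain.

    A gene is a hit when it shares >= ``hit_min_containment`` of the
    centroid's canonical kmers and aligns at >= ``hit_min_identity`` global
    identity - a deterministic stand-in for a stringent blastn search.
    ``kmer_cache`` (from :func:`gene_kmer_sets`) avoids re-encoding the gene
    kmer sets across repeated searches.
    """
    params = params or KmerParams()
    if not centroids:
        raise ValueError("no centroids")
    cent_kmers = {c.centroid_id: encode_kmers(c.centroid_seq, params.k,
                                              params.canonical)
                  for c in centroids}
    hits: dict[str, list[tuple[str, str]]] = {c.centroid_id: [] for c in centroids}
    for strain_id, gene_id, nt_seq in all_genes:
        if kmer_cache is not None:
            gene_kmers = kmer_cache[(strain_id, gene_id)]
        else:
            gene_kmers = encode_kmers(nt_seq, params.k, params.canonical)
        for c in centroids:
            ck = cent_kmers[c.centroid_id]
            if ck.size == 0:
                continue
            if _shared_count(gene_kmers, ck) / ck.size < params.hit_min_containment:
                continue
            if nt_identity(nt_seq, c.centroid_seq) >= params.hit_min_identity:
                hits[c.centroid_id].append((strain_id, gene_id))
    return hits


@dataclass
class KmerAssociationReport:
    high_kmer_genes: list[str]
    centroids: list[CentroidCluster]
    hit_lists: dict[str, list[tuple[str, str]]]
    results: list[AssociationResult]
    significant_genes: list[str]


def associate_from_matrix(matrix: KmerMatrix, genomeset: GenomeSet,
                          reference_strain: str,
                          params: KmerParams | None = None,
                          kmer_cache: dict[tuple[str, str], np.ndarray] | None = None,
                          ) -> KmerAssociationReport:
    """Steps 2-5 of the pipeline given a prebuilt kmer matrix.

    Re-scores the matrix against the phenotype of ``genomeset``, so label
    permutations can reuse one matrix.
    """
    params = params or KmerParams()
    genomeset.check_association_ready()
    matrix.scores = matrix.score_against(genomeset)
    high_genes = map_high_kmers_to_genes(matrix, genomeset, reference_strain, params)
    if not high_genes:
        return KmerAssociationReport([], [], {}, [], [])
    reference = genomeset.strain(reference_strain)
    seqs = [(gid, reference.gene(gid).nt_seq) for gid in high_genes]
    centroids = greedy_cluster_genes(seqs, params.cluster_identity)
    hit_lists = centroid_hit_lists(centroids, gene_sequences(genomeset), params,
                                   kmer_cache=kmer_cache)
    results = []
    for c in centroids:
        strains = {sid for sid, _ in hit_lists[c.centroid_id]}
        results.append(presence_fisher(strains, genomeset,
                                       alternative=params.alternative,
                                       unit_id=c.centroid_id))
    adjust_results(results)
    significant = {r.unit_id for r in results if r.p < params.sig_p}
    sig_genes = sorted({gid for c in centroids if c.centroid_id in significant
                        for gid in c.members})
    return KmerAssociationReport(high_genes, centroids, hit_lists, results, sig_genes)


def run_kmer_association(genomeset: GenomeSet, reference_strain: str,
                         params: KmerParams | None = None) -> KmerAssociationReport:
    """Full kmer genotype-phenotype association against a reference strain."""
    params = params or KmerParams()
    matrix = build_kmer_matrix(genomeset, params)
    return associate_from_matrix(matrix, genomeset, reference_strain, params)
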