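"""Evidence integration and gene-cluster calling.

Combines candidate gene sets from the kmer, gene-family, and differential-
expression screens on a reference genome, reports the three-way Venn
breakdown, calls gene clusters as adjacency runs of candidates in reference
gene order, names cluster genes alphabetically (bxdA, bxdB, ...), and types
cluster architectures across strains by their family-label sequence
(reversal-invariant).  ``run_full_pipeline`` orchestrates the whole chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .diffexpr_lite import CountMatrix, DEResult, de_gene_ids, de_test
from .family_association import (FamilyCallParams, GeneFamily,
                                 build_families_denovo, family_reference_genes,
                                 unique_specific_families)
from .genome_model import GenomeSet, StrainGenome
from .genome_model import gene_sequences
from .kmer_association import (KmerParams, associate_from_matrix,
                               build_kmer_matrix, gene_kmer_sets,
                               run_kmer_association)
from .stats import AssociationResult


@dataclass
class CandidateGene:
    gene_id: str
    from_kmer: bool
    from_family: bool
    from_de: bool
    contig_id: str = ""
    order_index: int = -1

    def __post_init__(self) -> None:
        if not (self.from_kmer or self.from_family or self.from_de):
            raise ValueError(f"candidate {self.gene_id} has no evidence flag")


@dataclass
class GeneCluster:
    contig_id: str
    gene_ids: list[str]                      # candidates in genomic order
    names: dict[str, str] = field(default_factory=dict)
    flags: dict[str, CandidateGene] = field(default_factory=dict)
    architecture_type: str | None = None

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def intersect_candidates(kmer_set: Sequence[str], family_set: Sequence[str],
                         de_set: Sequence[str] | None = None,
                         reference: StrainGenome | None = None,
                         ) -> tuple[dict[str, int], list[CandidateGene]]:
    """Three-way Venn breakdown and the flagged union of candidate sets.

    With ``de_set=None`` the Venn degenerates to two sets (all regions
    involving DE are zero).  If a reference genome is supplied the
    candidates carry their contig and gene-order coordinates.
    """
    a, b = set(kmer_set), set(family_set)
    c = set(de_set) if de_set is not None else set()
    venn = {
        "kmer_only": len(a - b - c),
        "family_only": len(b - a - c),
        "de_only": len(c - a - b),
        "kmer_family": len((a & b) - c),
        "kmer_de": len((a & c) - b),
        "family_de": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    position: dict[str, tuple[str, int]] = {}
    if reference is not None:
        by_contig: dict[str, int] = {}
        for g in reference.genes:
            idx = by_contig.get(g.contig_id, 0)
            position[g.gene_id] = (g.contig_id, idx)
            by_contig[g.contig_id] = idx + 1
    candidates = []
    for gid in sorted(a | b | c):
        contig, idx = position.get(gid, ("", -1))
        if reference is not None and gid not in position:
            raise ValueError(f"candidate {gid} not found in reference strain")
        candidates.append(CandidateGene(gid, gid in a, gid in b, gid in c,
                                        contig, idx))
    return venn, candidates


def call_adjacent_clusters(candidates: list[CandidateGene],
                           reference: StrainGenome,
                           max_gap: int = 2,
                           min_genes: int = 3) -> list[GeneCluster]:
    """Maximal adjacency runs of candidate genes in reference gene order.

    Within a contig, consecutive candidates belong to the same run when at
    most ``max_gap`` non-candidate genes separate them; runs with at least
    ``min_genes`` candidates are returned, largest first.
    """
    order: dict[str, tuple[str, int]] = {}
    counters: dict[str, int] = {}
    for g in reference.genes:
        idx = counters.get(g.contig_id, 0)
        order[g.gene_id] = (g.contig_id, idx)
        counters[g.contig_id] = idx + 1
    by_contig: dict[str, list[tuple[int, CandidateGene]]] = {}
    for cand in candidates:
        if cand.gene_id not in order:
            raise ValueError(f"candidate {cand.gene_id} not in reference strain")
        contig, idx = order[cand.gene_id]
        by_contig.setdefault(contig, []).append((idx, cand))
    clusters: list[GeneCluster] = []
    for contig, items in by_contig.items():
        items.sort(key=lambda x: x[0])
        run: list[CandidateGene] = []
        prev_idx: int | None = None
        def flush() -> None:
            if len(run) >= min_genes:
                clusters.append(GeneCluster(
                    contig, [c.gene_id for c in run],
                    flags={c.gene_id: c for c in run}))
        for idx, cand in items:
            if prev_idx is not None and idx - prev_idx - 1 > max_gap:
                flush()
                run = []
            run.append(cand)
            prev_idx = idx
        flush()
    clusters.sort(key=lambda c: (-c.size, c.contig_id))
    return clusters


def _letters(n: int) -> str:
    """1 -> A, 26 -> Z, 27 -> AA, ... (bijective base 26)."""
    out = ""
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def name_cluster_genes(cluster: GeneCluster, prefix: str = "bxd") -> GeneCluster:
    """Assign ``prefix`` + A, B, ... names to cluster genes in genomic order."""
    if not cluster.gene_ids:
        raise ValueError("cannot name an empty cluster")
    cluster.names = {gid: f"{prefix}{_letters(i + 1)}"
                     for i, gid in enumerate(cluster.gene_ids)}
    return cluster


def _roman(n: int) -> str:
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
                (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
                (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for value, sym in numerals:
        while n >= value:
            out += sym
            n -= value
    return out


def type_cluster_architectures(labelled_clusters: Mapping[str, Sequence[str]],
                               ) -> dict[str, str]:
    """Group clusters into architecture types by family-label sequence.

    Two clusters share a type when their family-label sequences are
    identical or full reversals of one another (strand/orientation
    invariance).  Types are labelled with roman numerals by decreasing
    class size, ties broken by first occurrence.
    """
    canon: dict[str, tuple[str, ...]] = {}
    for key, labels in labelled_clusters.items():
        labels = tuple(labels)
        if not labels or any(not lab for lab in labels):
            raise ValueError(f"cluster {key} has missing family labels")
        canon[key] = min(labels, tuple(reversed(labels)))
    first_seen: dict[tuple[str, ...], int] = {}
    sizes: dict[tuple[str, ...], int] = {}
    for i, key in enumerate(labelled_clusters):
        c = canon[key]
        sizes[c] = sizes.get(c, 0) + 1
        first_seen.setdefault(c, i)
    ranked = sorted(sizes, key=lambda c: (-sizes[c], first_seen[c]))
    type_of = {c: _roman(i + 1) for i, c in enumerate(ranked)}
    return {key: type_of[canon[key]] for key in labelled_clusters}


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineConfig:
    kmer: KmerParams = field(default_factory=KmerParams)
    family: FamilyCallParams = field(default_factory=FamilyCallParams)
    protein_identity: float = 0.5
    max_gap: int = 2
    min_genes: int = 3
    name_prefix: str = "bxd"
    candidate_mode: str = "union"     # or "intersection"
    de_alpha: float = 0.05


@dataclass
class PipelineReport:
    reference_strain: str
    kmer_genes: list[str]
    family_genes: list[str]
    de_genes: list[str] | None
    venn: dict[str, int]
    candidates: list[CandidateGene]
    clusters: list[GeneCluster]
    architecture_types: dict[str, str]
    kmer_results: list[AssociationResult]
    family_results: list[tuple[GeneFamily, AssociationResult]]
    de_results: list[DEResult] | None
    status: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference_strain": self.reference_strain,
            "kmer_genes": self.kmer_genes,
            "family_genes": self.family_genes,
            "de_genes": self.de_genes,
            "venn": self.venn,
            "clusters": [
                {"contig": c.contig_id, "genes": c.gene_ids, "names": c.names,
                 "architecture_type": c.architecture_type}
                for c in self.clusters
            ],
            "architecture_types": self.architecture_types,
            "status": self.status,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def run_full_pipeline(genomeset: GenomeSet, reference_strain: str,
                      counts: CountMatrix | None = None,
                      de_results: list[DEResult] | None = None,
                      families: list[GeneFamily] | None = None,
                      config: PipelineConfig | None = None) -> PipelineReport:
    """Run kmer, family, and (optional) DE screens, then call clusters.

    ``families`` may come from an external orthogroup table; otherwise the
    internal greedy protein clustering builds them.  ``counts`` or an
    already computed ``de_results`` list enables the DE leg; with neither,
    the Venn is computed over two sets and the pipeline completes in
    degraded mode.
    """
    config = config or PipelineConfig()
    status: dict[str, str] = {}
    reference = genomeset.strain(reference_strain)

    kmer_report = run_kmer_association(genomeset, reference_strain, config.kmer)
    kmer_genes = kmer_report.significant_genes
    status["kmer"] = "ok"

    if families is None:
        families = build_families_denovo(genomeset, config.protein_identity)
        status["family"] = "ok (de novo families)"
    else:
        status["family"] = "ok (external families)"
    called = unique_specific_families(families, genomeset, config.family)
    family_genes = family_reference_genes(called, reference_strain)

    de_list: list[DEResult] | None = de_results
    if de_list is None and counts is not None:
        de_list = de_test(counts, alpha=config.de_alpha)
    de_set = de_gene_ids(de_list) if de_list is not None else None
    status["de"] = "ok" if de_set is not None else "skipped"

    venn, candidates = intersect_candidates(kmer_genes, family_genes, de_set,
                                            reference=reference)
    if config.candidate_mode == "intersection":
        n_sets = 2 if de_set is None else 3
        candidates = [c for c in candidates
                      if (c.from_kmer + c.from_family + c.from_de) == n_sets]
    clusters = call_adjacent_clusters(candidates, reference,
                                      max_gap=config.max_gap,
                                      min_genes=config.min_genes)
    for cluster in clusters:
        name_cluster_genes(cluster, config.name_prefix)

    # architecture typing across strains via the families of the top cluster
    arch_types: dict[str, str] = {}
    if clusters:
        gene_to_family = {gid: fam.family_id
                          for fam in families
                          for gids in fam.members.values() for gid in gids}
        cluster_fams = {gene_to_family[g] for g in clusters[0].gene_ids
                        if g in gene_to_family}
        labelled: dict[str, list[str]] = {}
        for strain in genomeset.strains:
            hits = [(i, gene_to_family[g.gene_id])
                    for i, g in enumerate(strain.genes)
                    if gene_to_family.get(g.gene_id) in cluster_fams]
            if len(hits) < config.min_genes:
                continue
            # largest adjacency run of cluster-family genes in this strain
            runs: list[list[str]] = [[]]
            prev = None
            for idx, fam in hits:
                if prev is not None and idx - prev - 1 > config.max_gap:
                    runs.append([])
                runs[-1].append(fam)
                prev = idx
            best = max(runs, key=len)
            if len(best) >= config.min_genes:
                labelled[strain.strain_id] = best
        if labelled:
            arch_types = type_cluster_architectures(labelled)
            if reference_strain in arch_types:
                clusters[0].architecture_type = arch_types[reference_strain]
    status["clusters"] = f"{len(clusters)} called"

    return PipelineReport(reference_strain, kmer_genes, family_genes, de_set,
                          venn, candidates, clusters, arch_types,
                          kmer_report.results, called, de_list, status)


def null_cluster_calibration(genomeset: GenomeSet, reference_strain: str,
                             permutation_seeds: Sequence[int],
                             config: PipelineConfig | None = None,
                             families: list[GeneFamily] | None = None,
                             matrix=None) -> list[int]:
    """Cluster counts under random phenotype relabellings.

    The kmer matrix and gene families depend only on sequences, so they are
    built once and every permutation redoes only the phenotype-dependent
    stages (kmer scoring, association, family calling, adjacency).  Returns
    the number of clusters called for each permutation seed; a well
    calibrated pipeline calls none for almost all permutations.
    """
    config = config or PipelineConfig()
    reference = genomeset.strain(reference_strain)
    if matrix is None:
        matrix = build_kmer_matrix(genomeset, config.kmer)
    if families is None:
        families = build_families_denovo(genomeset, config.protein_identity)
    kmer_cache = gene_kmer_sets(gene_sequences(genomeset), config.kmer)
    labels = [genomeset.phenotype[s] for s in genomeset.strain_ids]
    counts = []
    for seed in permutation_seeds:
        rng = np.random.default_rng(seed)
        perm = list(labels)
        rng.shuffle(perm)
        permuted = GenomeSet(genomeset.strains,
                             dict(zip(genomeset.strain_ids, perm)))
        krep = associate_from_matrix(matrix, permuted, reference_strain,
                                     config.kmer, kmer_cache=kmer_cache)
        called = unique_specific_families(families, permuted, config.family)
        fam_genes = family_reference_genes(called, reference_strain)
        _venn, candidates = intersect_candidates(krep.significant_genes,
                                                 fam_genes, None,
                                                 reference=reference)
        clusters = call_adjacent_clusters(candidates, reference,
                                          max_gap=config.max_gap,
                                          min_genes=config.min_genes)
        counts.append(len(clusters))
    return counts
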