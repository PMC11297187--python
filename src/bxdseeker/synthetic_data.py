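"""Synthetic genome panels with a planted trait-linked gene cluster.

The generator emulates the study design the association pipeline assumes: a
panel of closely related bacterial strains (default 16 trait-positive, 23
negative), each genome a single contig of protein-coding genes separated by
short intergenic spacers.  Background genes descend from shared ancestral
sequences (core genes in every strain, accessory genes in random subsets
independent of phenotype, so they act as true-negative decoys); each strain's
copy is mutated independently at a configurable per-site substitution rate.
A contiguous block of ``cluster_size`` dedicated genes is inserted at a
random position in every trait-positive strain (modulo drop/gain noise), so
with noise 0 cluster presence is a perfect classifier of the phenotype.

All randomness flows from one ``numpy`` generator seeded by ``SimParams.seed``;
identical parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr_lite import CountMatrix
from .genome_model import GeneRecord, GenomeSet, StrainGenome, reverse_complement

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    n_pos: int = 16
    n_neg: int = 23
    genes_per_genome: int = 300
    gene_len_mean: int = 900
    core_fraction: float = 0.8
    per_site_divergence: float = 0.02
    cluster_size: int = 15
    cluster_noise_drop: float = 0.0
    cluster_noise_gain: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one strain per phenotype class")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if self.cluster_size > self.genes_per_genome:
            raise ValueError("cluster_size exceeds genes_per_genome")
        for name in ("core_fraction", "per_site_divergence",
                     "cluster_noise_drop", "cluster_noise_gain"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """The generator's record of what was planted where."""

    phenotype: dict[str, str]
    carriers: list[str]
    planted_gene_ids: dict[str, list[str]]      # per carrier, in genomic order
    cluster_position: dict[str, tuple[str, tuple[int, int]]]  # (contig, index range)
    gene_families: dict[str, dict[str, str]]    # strain -> gene_id -> ancestral family
    de_gene_ids: list[str] = field(default_factory=list)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[rng.integers(0, 4, size=3)])
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = {ord(b): i for i, b in enumerate("ACGT")}
    codes = np.array([idx[x] for x in arr], dtype=np.int64)
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()))
    codes[hit] = (codes[hit] + shift) % 4
    return "".join(_BASES[codes])


def simulate_genome_set(params: SimParams | None = None) -> tuple[GenomeSet, GroundTruth]:
    """Generate the strain panel and its ground truth."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)

    n_core = int(round(params.core_fraction * params.genes_per_genome))
    n_acc = params.genes_per_genome - n_core

    # ancestral repertoire: sequences, strands and accessory carriage rates
    mean_codons = max(100, params.gene_len_mean // 3)
    def ancestral(label_prefix: str, count: int) -> list[tuple[str, str, str]]:
        out = []
        for i in range(count):
            n_codons = int(np.clip(rng.normal(mean_codons, mean_codons / 6),
                                   60, 2 * mean_codons))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append((f"{label_prefix}{i + 1:04d}", _random_cds(rng, n_codons), strand))
        return out

    core_genes = ancestral("core", n_core)
    acc_genes = ancestral("acc", n_acc)
    acc_carry_p = rng.uniform(0.3, 0.9, size=n_acc)
    cluster_genes = ancestral("bxd", params.cluster_size)

    strain_ids = [f"POS{i + 1:02d}" for i in range(params.n_pos)] + \
                 [f"NEG{i + 1:02d}" for i in range(params.n_neg)]
    phenotype = {sid: ("positive" if sid.startswith("POS") else "negative")
                 for sid in strain_ids}

    carriers = []
    for sid in strain_ids:
        if phenotype[sid] == "positive":
            if rng.random() >= params.cluster_noise_drop:
                carriers.append(sid)
        else:
            if rng.random() < params.cluster_noise_gain:
                carriers.append(sid)

    strains: list[StrainGenome] = []
    truth = GroundTruth(phenotype=phenotype, carriers=carriers,
                        planted_gene_ids={}, cluster_position={}, gene_families={})

    for sid in strain_ids:
        present: list[tuple[str, str, str]] = list(core_genes)
        keep = rng.random(n_acc) < acc_carry_p
        present += [acc_genes[i] for i in range(n_acc) if keep[i]]
        if sid in carriers:
            insert_at = int(rng.integers(0, len(present) + 1))
            present = present[:insert_at] + cluster_genes + present[insert_at:]
        contig_id = f"{sid}_c1"
        parts: list[str] = []
        genes: list[GeneRecord] = []
        families: dict[str, str] = {}
        pos = 0
        planted: list[str] = []
        for ordinal, (family, anc_seq, strand) in enumerate(present, start=1):
            spacer_len = int(rng.integers(20, 201))
            spacer = "".join(_BASES[rng.integers(0, 4, size=spacer_len)])
            parts.append(spacer)
            pos += spacer_len
            seq = _mutate(rng, anc_seq, params.per_site_divergence)
            gene_id = f"{sid}_g{ordinal:04d}"
            start, end = pos, pos + len(seq)
            parts.append(seq if strand == "+" else reverse_complement(seq))
            pos = end
            genes.append(GeneRecord(gene_id, contig_id, start, end, strand, seq))
            families[gene_id] = family
            if family.startswith("bxd"):
                planted.append(gene_id)
        tail = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(20, 201)))])
        parts.append(tail)
        contig = "".join(parts)
        # fill in translations
        from .genome_model import translate_cds
        for g in genes:
            g.aa_seq, g.has_internal_stop = translate_cds(g.nt_seq)
        strains.append(StrainGenome(sid, {contig_id: contig}, genes))
        truth.gene_families[sid] = families
        if planted:
            ids_in_order = [g.gene_id for g in strains[-1].genes]
            idxs = sorted(ids_in_order.index(gid) for gid in planted)
            truth.planted_gene_ids[sid] = [ids_in_order[i] for i in idxs]
            truth.cluster_position[sid] = (contig_id, (idxs[0], idxs[-1]))

    genomeset = GenomeSet(strains, phenotype)
    if carriers:
        ref = carriers[0]
        truth.de_gene_ids = list(truth.planted_gene_ids[ref])
    return genomeset, truth


def simulate_count_matrix(genomeset: GenomeSet, truth: GroundTruth,
                          n_reps_per_condition: int = 4,
                          lfc_cluster: float = 3.0,
                          dispersion: float = 0.05,
                          seed: int = 0,
                          reference_strain: str | None = None) -> CountMatrix:
    """Negative-binomial counts for the reference strain's genes.

    Baseline means are log-normal; under the treatment condition the planted
    cluster genes' means are multiplied by ``2**lfc_cluster``.  Dispersion is
    the NB overdispersion (variance = mu + dispersion * mu^2); dispersion 0
    degenerates to Poisson.
    """
    if n_reps_per_condition < 2:
        raise ValueError("need at least 2 replicates per condition")
    reference_strain = reference_strain or (truth.carriers[0] if truth.carriers else None)
    if reference_strain is None or reference_strain not in truth.planted_gene_ids:
        raise ValueError("reference strain must carry the planted cluster")
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in genomeset.strain(reference_strain).genes]
    cluster = set(truth.planted_gene_ids[reference_strain])
    truth.de_gene_ids = [g for g in genes if g in cluster]
    base_mu = rng.lognormal(mean=np.log(200), sigma=1.0, size=len(genes))
    samples, conditions = [], {}
    data = np.zeros((len(genes), 2 * n_reps_per_condition), dtype=np.int64)
    col = 0
    for cond in ("control", "MBOA"):
        for rep in range(1, n_reps_per_condition + 1):
            name = f"{cond}_{rep}"
            samples.append(name)
            conditions[name] = cond
            mu = base_mu.copy()
            if cond == "MBOA":
                is_cluster = np.array([g in cluster for g in genes])
                mu[is_cluster] *= 2.0 ** lfc_cluster
            if dispersion <= 0:
                data[:, col] = rng.poisson(mu)
            else:
                n_param = 1.0 / dispersion
                p_param = n_param / (n_param + mu)
                data[:, col] = rng.negative_binomial(n_param, p_param)
            col += 1
    counts = pd.DataFrame(data, index=genes, columns=samples)
    return CountMatrix(counts, conditions)


def simulate_phenotype_assays(genomeset: GenomeSet, truth: GroundTruth,
                              seed: int = 0,
                              control_mboa: float = 500.0,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolite table and growth curves consistent with the phenotype labels.

    Positive strains are drawn to satisfy the strong cut-offs (>90% of MBOA
    degraded, AMPO above 10% of the panel maximum); negatives satisfy the
    non-former cut-offs.  Growth on MBOA as sole carbon source is logistic
    for positives and flat (no carbon) otherwise; a DMSO control treatment
    never grows.  Returns ``(metabolite_table, growth_curves)`` as tidy
    DataFrames.
    """
    rng = np.random.default_rng(seed)
    met_rows = []
    met_rows.append(("NBC", "MBOA", control_mboa, True))
    met_rows.append(("NBC", "AMPO", 0.0, True))
    for sid in genomeset.strain_ids:
        positive = genomeset.phenotype[sid] == "positive"
        if positive:
            mboa = control_mboa * rng.uniform(0.005, 0.08)   # >90% degraded
            ampo = rng.uniform(25.0, 100.0)                   # >10% of max
        else:
            mboa = control_mboa * rng.uniform(0.75, 1.0)      # <30% degraded
            ampo = rng.uniform(0.0, 0.02)                     # <0.1% of max
        met_rows.append((sid, "MBOA", mboa, False))
        met_rows.append((sid, "AMPO", ampo, False))
    metabolites = pd.DataFrame(met_rows,
                               columns=["strain_id", "compound",
                                        "concentration", "is_control"])

    times = np.arange(0.0, 68.0 + 1e-9, 4.0)
    growth_rows = []
    for sid in genomeset.strain_ids:
        positive = genomeset.phenotype[sid] == "positive"
        for treatment in ("MBOA", "DMSO"):
            grows = positive and treatment == "MBOA"
            for rep in range(1, 6):
                if grows:
                    cap = rng.uniform(0.4, 0.6)
                    rate = rng.uniform(0.12, 0.2)
                    midpoint = rng.uniform(16, 28)
                    od = 0.02 + cap / (1 + np.exp(-rate * (times - midpoint)))
                else:
                    od = np.full_like(times, 0.02)
                od = np.clip(od + rng.normal(0, 0.002, size=times.size), 0.001, None)
                for t, o in zip(times, od):
                    growth_rows.append((sid, treatment, rep, float(t), float(o)))
    growth = pd.DataFrame(growth_rows,
                          columns=["strain_id", "treatment", "replicate",
                                   "time_h", "od600"])
    return metabolites, growth
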