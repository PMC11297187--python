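import pytest
from hypothesis import HealthCheck, settings

from bxdseeker import SimParams, simulate_genome_set
from bxdseeker.kmer_association import build_kmer_matrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """A quick 9-strain panel with a planted 5-gene cluster."""
    params = SimParams(n_pos=4, n_neg=5, genes_per_genome=40,
                       gene_len_mean=600, cluster_size=5, seed=7)
    return simulate_genome_set(params)


@pytest.fixture(scope="session")
def default_panel():
    """The full default study design: 16 positive / 23 negative strains."""
    return simulate_genome_set(SimParams())


@pytest.fixture(scope="session")
def default_matrix(default_panel):
    genomeset, _truth = default_panel
    return build_kmer_matrix(genomeset)


def revcomp_genomeset(genomeset):
    """Mirror a genome set: every contig reverse-complemented, genes remapped."""
    from bxdseeker.genome_model import (GeneRecord, GenomeSet, StrainGenome,
                                        reverse_complement)
    strains = []
    for strain in genomeset.strains:
        contigs = {cid: reverse_complement(seq)
                   for cid, seq in strain.contigs.items()}
        genes = []
        for g in strain.genes:
            length = len(strain.contigs[g.contig_id])
            genes.append(GeneRecord(
                g.gene_id, g.contig_id, length - g.end, length - g.start,
                "-" if g.strand == "+" else "+", g.nt_seq, g.aa_seq,
                g.has_internal_stop))
        strains.append(StrainGenome(strain.strain_id, contigs, genes))
    return GenomeSet(strains, dict(genomeset.phenotype))
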