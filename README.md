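# bxdseeker

Comparative-genomics toolkit for discovering trait-linked gene clusters in
bacterial strain panels, built around the workflow that identifies
benzoxazinoid-degradation (*bxd*) gene clusters in maize-root
*Microbacterium* strains: given a panel of annotated genomes labelled with a
binary metabolic phenotype (e.g. AMPO-former vs non-former on the maize
benzoxazinoid MBOA), it combines three independent lines of genomic
evidence and calls the gene cluster responsible.

It is aimed at microbial genomicists who have a phenotyped strain panel and
want a transparent, fully scripted route from genomes + phenotypes to a
named candidate gene cluster — plus the phenotype-classification and
homology-screening helpers that surround that analysis.

## The method

**1. Kmer genotype–phenotype association.** Every genome is decomposed into
unique canonical 21-mers (lexicographic minimum of each window and its
reverse complement), merged into one presence/absence matrix, and each kmer
is scored

```
score(kmer) = #positive genomes containing it − #negative genomes containing it
```

so that for an n⁺/n⁻ panel the score lies in [−n⁻, n⁺]. Reference-strain
genes containing a kmer with score ≥ 7 are greedily clustered at 70%
alignment identity (longest-first, vsearch-style); each centroid is searched
against all genes of all strains (shared-kmer containment ≥ 0.1 plus global
identity ≥ 0.7), and strain-level presence of each hit list is tested
against the phenotype with Fisher's exact test, Benjamini–Hochberg
corrected across centroids.

**2. Gene-family presence–absence.** Orthogroups (an OrthoFinder table, or
an internal greedy protein-clustering stand-in) are tested the same way; a
family is called *unique and specific* when it is present in all positive
and absent from all negative strains (both fractions relaxable).

**3. Differential expression.** A lightweight stand-in (median-of-ratios
size factors, per-gene Welch t-test on log2 normalised counts, BH) marks
genes upregulated under the phenotype-inducing compound; a real DE table
from a dedicated tool can be dropped in instead.

Candidates from the three screens are intersected (seven-region Venn),
mapped to reference gene order, and maximal adjacency runs (≤ 2 intervening
non-candidates, ≥ 3 genes) are called as clusters, named `bxdA`, `bxdB`, …
in genomic order. Cluster architectures across strains are typed by their
family-label sequence, treating a full reversal as the same type.

A synthetic-data module generates genome panels with a planted cluster
(default: 16 positive / 23 negative strains, 300 genes per genome, a
contiguous 15-gene cluster only in positives) plus matching count matrices
and phenotyping assay tables, with full ground truth for validation.

## Worked example

```python
from bxdseeker import (SimParams, simulate_genome_set, simulate_count_matrix,
                       run_full_pipeline)

genomes, truth = simulate_genome_set(SimParams(seed=42))
reference = truth.carriers[0]                  # an AMPO-former, e.g. "POS01"
counts = simulate_count_matrix(genomes, truth, n_reps_per_condition=4,
                               lfc_cluster=3.0, dispersion=0.05, seed=42)
report = run_full_pipeline(genomes, reference, counts=counts)

print(report.venn)
print(len(report.clusters), "cluster(s)")
cluster = report.clusters[0]
print(cluster.gene_ids[0], "->", cluster.names[cluster.gene_ids[0]])
```

prints

```
{'kmer_only': 0, 'family_only': 0, 'de_only': 2, 'kmer_family': 0,
 'kmer_de': 0, 'family_de': 0, 'all_three': 15}
1 cluster(s)
POS01_g0277 -> bxdA
```

i.e. all 15 planted cluster genes are supported by all three evidence
types (two isolated differential-expression false positives remain outside
any cluster), exactly one adjacency cluster is called, and its genes are
named `bxdA` … `bxdO` in genomic order — matching the generator's ground
truth.

The same stages are scriptable from the shell:

```bash
bxdseeker simulate --out panel/ --seed 42
bxdseeker kmer-assoc --genomes panel/ --reference POS01 --out assoc/
```

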