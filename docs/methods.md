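# Methods

This note documents the models, parameter choices, and numerical decisions
behind bxdseeker, and what the synthetic benchmarks do and do not show.

## Data model and conventions

Genomes are held as contig strings (A/C/G/T/N) with ordered gene records.
Coordinates are 0-based half-open internally; GFF3 input and output convert
at the boundary (GFF3 is 1-based inclusive). Minus-strand gene sequences
are stored strand-corrected. Translation uses the bacterial genetic code
(NCBI table 11); a single trailing stop is stripped and internal stops are
flagged rather than dropped, because mutated synthetic genes (and real
pseudogenes) can acquire them. Kmer windows containing N are skipped,
matching the behaviour of exact-match kmer counters.

## Kmer association

Kmers are canonical (minimum of forward and reverse-complement form), so
all statistics are strand-invariant; a flag disables canonicalisation.
Internally kmers are 2-bit packed into unsigned 64-bit integers (k ≤ 31)
and kept in sorted arrays; for the default 39-genome panel (~270 kb per
genome) the matrix holds ~4.8 M distinct 21-mers and fits in a few hundred
MB. A configurable cap on estimated distinct kmers guards against
accidentally feeding full-size assemblies through the in-memory path;
disk-backed counting is out of scope.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| k | 21 | kmer length (8 ≤ k ≤ 31) |
| min_score | 7 | phenotype-score threshold for "high-scoring" kmers |
| cluster_identity | 0.70 | greedy centroid clustering cut-off |
| hit_min_identity | 0.70 | centroid→gene homology cut-off |
| hit_min_containment | 0.10 | shared-kmer prefilter for hits |
| sig_p | 0.05 | raw-p threshold defining the significant gene list |
| alpha | 0.05 | BH level reported alongside |

The score threshold 7 is kept as a free parameter; it is meaningful
relative to a 16/23 design (upper bound 16). Kmer scoring uses presence
only, never multiplicity. The significant gene list uses the raw Fisher
p < 0.05 by default, with BH-adjusted values always reported alongside;
both thresholds are configurable. Fisher sidedness defaults to two-sided
(`alternative="greater"` gives the enrichment-only reading).

Alignment identity everywhere on the nucleotide side is identical columns /
alignment columns of a global alignment with free end gaps (match +1,
mismatch −1, gap open −2, extend −1) — a vsearch-like, fully specified
scheme. The centroid→gene search is a deterministic stand-in for a
stringent nucleotide BLAST: a gene must share ≥ 10% of the centroid's
kmers and align at ≥ 70% identity. Identity computations are memoized, as
association pipelines and permutation calibrations revisit the same pairs.

Fisher's exact test builds the 2×2 phenotype × presence table at strain
level. One-sided tails come from the hypergeometric survival/cumulative
functions; the two-sided p sums point probabilities no larger than the
observed one (minimum-likelihood rule, with the standard 1 + 1e-7
tie tolerance for floating-point equal probabilities), evaluated
vectorised over the table support. This agrees with exhaustive
integer-arithmetic enumeration to < 1e-15 for every table with both
margins ≤ 30 (swept in the test suite).

## Gene families

External OrthoFinder-style tables are accepted directly. The internal
stand-in clusters all proteins greedily (longest first) at a global
amino-acid identity threshold (default 0.5, BLOSUM62, gap open −11 extend
−1, free end gaps). To avoid ~10⁶ pairwise alignments, a candidate
centroid must share ≥ 10% of the sequence's amino-acid 5-mers before an
alignment is attempted; at ≥ 50% identity true members share far more than
that, while unrelated proteins of a few hundred residues share essentially
none, so the screen only suppresses alignments that could not succeed.
This is a de novo family builder for pipelines without external orthology
tools, not a phylogenetic orthology method: paralogs are merged into one
family if they meet the identity threshold.

"Unique and specific" is operationalised as present in ≥ 100% of positive
strains and ≤ 0% of negative strains (both relaxable); presence means copy
number ≥ 1, and copy-number variation is reported but not tested, since
the association unit is presence.

## Differential expression stand-in

Counts are normalised with median-of-ratios size factors (geometric-mean
reference over genes positive in every sample). Each gene gets a Welch
t-test on log2(normalised + 1), BH correction across genes, and the log2
fold change is the difference of condition means on that scale. This is
deliberately not a negative-binomial GLM: no dispersion shrinkage, outlier
handling, or independent filtering. Its contract is planted-signal
recovery on synthetic counts (≥ 90% of genes planted at log2 fold change 3
with dispersion 0.05 and 4 replicates per condition, with < 1 false
positive per 300 null genes), and an external DE table can replace it for
real data. Size factors are only identified up to a common constant:
scaling one sample rescales factor ratios exactly, while absolute factors
shift by the reference's movement.

Degenerate genes (zero variance in both groups) get p = 1 when the group
means agree and p = 0 when they differ exactly; all-zero genes have fold
change 0 and are never called.

## Evidence integration and cluster calling

Candidates default to the union of the three screens (configurable to the
intersection); the full seven-region Venn breakdown is always reported.
"Adjacent" is quantified as: consecutive candidates on a contig may be
separated by at most `max_gap = 2` non-candidate genes, and a cluster needs
`min_genes = 3` candidates — tolerant of one or two genes missed by every
screen. Both knobs are exposed. Cluster genes are named prefix + A…Z,
then AA, AB, … in genomic order.

Architecture types are equivalence classes of family-label sequences,
treating a fully reversed sequence as identical (orientation invariance);
labels are roman numerals ordered by decreasing class size, ties by first
occurrence. Chemical phenotype is not part of the equivalence relation.
Per-strain cluster instances are located as the largest adjacency run of
genes belonging to the called cluster's families.

## Phenotype classification and growth statistics

Degradation of a compound relative to the no-bacteria control is
percent-degraded = 100·(1 − sample/control): strong above 90%, non below
30%, weak in the closed band between (the stated cut-offs are strict
inequalities that cannot tile the line, so both boundaries land in weak;
the same convention puts the 0.1% and 10% boundaries of the
AMPO-former classification in weak). Growth is summarised as the
trapezoidal area under the OD600 curve; treatment benefit divides each
treatment replicate by the strain's mean control AUC and tests the ratios
against 1 with a one-sample t-test (optionally on the log scale), BH
across strains. The carbon-equivalence helper converts a compound
concentration to the glucose concentration with the same carbon content
(conc·carbons/6, rounded to the nearest µM; 500 µM of an 8-carbon compound
→ 667 µM glucose). Strain abundance in a community profile sums the
relative abundances of ASVs whose global-alignment identity to the
strain's 16S marker strictly exceeds 99%.

## Protein homology screening

Protein alignments use BLOSUM62 with gap open −11, extend −1. Identity is
identical columns / alignment columns and similarity is positive-scoring
columns / alignment columns; gap columns count in the denominator only, so
identity ≤ similarity always. The best-hit screen categorises each target
genome by the maximal similarity over its proteome: high at ≥ 60%,
low-or-absent below 25% (or no protein at all), intermediate between.

The screen's default alignment is global with free end gaps rather than
purely local: a local alignment of two unrelated proteins is typically a
short segment whose per-column similarity is high (measured 31–86% for
random 300-residue pairs), which would defeat the low-or-absent category —
in a classical sequence search the e-value filter performs that role,
and e-value statistics are out of scope here. Under the end-gap-free
global mode random pairs measure < 15% similarity while true homologs of
comparable length score as expected. `mode="local"` remains available for
exploratory use.

## Synthetic data generator

The generator emulates the study design the pipeline assumes:

* 16 positive / 23 negative strains (defaults), one contig each;
* 300 background genes per genome: 80% core (all strains) and 20%
  accessory, each accessory gene carried independently with a
  per-gene rate drawn from U(0.3, 0.9) — independent of phenotype, so
  accessory families are true negatives for the association tests;
* ancestral coding sequences are ATG + random non-stop codons + TAA,
  lengths ≈ N(900, 150) nt; each strain's copy is mutated independently by
  substitutions at 0.02/site (≈ 4% pairwise divergence, i.e. ≈ 96%
  nucleotide identity between orthologs — comfortably inside the 70%
  clustering threshold and outside random-sequence identity);
* a 15-gene cluster from separate ancestral sequences inserted as one
  contiguous block at a random inter-gene position in every carrier
  (positives, modulo configurable drop/gain noise), so adjacency calling is
  tested independently of position;
* random intergenic spacers of 20–200 nt; per-gene strands random but
  shared across strains.

Substitution-only mutation keeps gene lengths stable, making identity ≈
1 − divergence and the clustering-threshold analysis tractable. Counts are
negative-binomial (variance = µ + φµ², log-normal baseline means, cluster
genes × 2^lfc under treatment, Poisson in the φ → 0 limit); the default
planted log2 fold change of 3 is a choice exposed as a parameter, since
"significantly upregulated" fixes no effect size. Assay tables are drawn
to satisfy the strong cut-offs for positives and the non cut-offs for
negatives, with logistic growth on the test carbon source for positives
only. Everything is driven by one seeded generator; identical parameters
give byte-identical output.

What passing on this generator does **not** show: robustness to
rearrangement, horizontal transfer, indels, assembly fragmentation,
annotation error, partial-penetrance phenotypes, or expression dispersion
misspecified far from the NB model. The noise knobs (cluster drop/gain,
divergence, dispersion) probe the first steps in those directions only.

## Problem sizes used in the checks

The end-to-end benchmarks run the full default design (39 genomes ×
~270 kb, ~4.8 M distinct 21-mers); the null calibration re-runs the
phenotype-dependent stages for 100 label permutations against the cached
kmer matrix and family set (the matrix and families depend only on the
sequences, so this is the identical computation); DE calibration uses 50
simulated count matrices per regime; the Fisher oracle sweep enumerates
all 246,015 tables with both margins ≤ 30.
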