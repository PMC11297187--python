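"""Core data model for annotated bacterial genome panels.

A :class:`GenomeSet` bundles a panel of strain genomes (contig sequences +
ordered gene annotations) with a binary phenotype label per strain (e.g.
AMPO-former vs non-former).  Coordinates are 0-based half-open internally;
GFF3 input/output converts at the boundary.  Translation uses the bacterial
genetic code (NCBI table 11).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

POSITIVE = "positive"
NEGATIVE = "negative"

_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeModelError(ValueError):
    """Raised for malformed genome, annotation, or phenotype inputs."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (alphabet ACGTN)."""
    s = seq.upper()
    bad = set(s) - _NT
    if bad:
        raise GenomeModelError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


def translate_cds(nt_seq: str) -> tuple[str, bool]:
    """Translate a CDS with the bacterial code (table 11).

    Returns ``(aa_seq, has_internal_stop)``.  A single trailing stop codon is
    stripped; internal stops are kept as ``*`` and flagged rather than
    silently dropped.
    """
    s = nt_seq.upper()
    if len(s) % 3 != 0:
        raise GenomeModelError(f"CDS length {len(s)} is not a multiple of 3")
    bad = set(s) - set("ACGT")
    if bad:
        raise GenomeModelError(f"invalid nucleotide(s) {sorted(bad)} in CDS")
    aa = str(Seq(s).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa, "*" in aa


@dataclass
class GeneRecord:
    """A single annotated gene on a contig.

    ``start``/``end`` are a 0-based half-open interval on the forward strand;
    ``nt_seq`` is strand-corrected (reverse-complemented for minus-strand
    genes) and ``aa_seq`` its table-11 translation when available.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str = ""
    has_internal_stop: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeModelError(f"gene {self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise GenomeModelError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.nt_seq and len(self.nt_seq) != self.end - self.start:
            raise GenomeModelError(
                f"gene {self.gene_id}: sequence length {len(self.nt_seq)} != "
                f"interval length {self.end - self.start}"
            )


@dataclass
class StrainGenome:
    strain_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeModelError(f"duplicate gene id {g.gene_id} in {self.strain_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise GenomeModelError(
                    f"gene {g.gene_id} references unknown contig {g.contig_id}"
                )
            if g.end > len(self.contigs[g.contig_id]):
                raise GenomeModelError(
                    f"gene {g.gene_id} extends past end of contig {g.contig_id}"
                )
        self.genes.sort(key=lambda g: (g.contig_id, g.start))

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class GenomeSet:
    strains: list[StrainGenome]
    phenotype: dict[str, str]

    def __post_init__(self) -> None:
        ids = [s.strain_id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise GenomeModelError("duplicate strain ids")
        for sid in ids:
            if sid not in self.phenotype:
                raise GenomeModelError(f"phenotype missing for strain {sid}")
        for sid, ph in self.phenotype.items():
            if sid not in set(ids):
                raise GenomeModelError(f"phenotype entry for unknown strain {sid}")
            if ph not in (POSITIVE, NEGATIVE):
                raise GenomeModelError(f"phenotype for {sid} must be positive/negative")

    @property
    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains]

    @property
    def positives(self) -> list[str]:
        return [s for s in self.strain_ids if self.phenotype[s] == POSITIVE]

    @property
    def negatives(self) -> list[str]:
        return [s for s in self.strain_ids if self.phenotype[s] == NEGATIVE]

    def strain(self, strain_id: str) -> StrainGenome:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s
        raise KeyError(strain_id)

    def check_association_ready(self) -> None:
        if not self.positives or not self.negatives:
            raise GenomeModelError(
                "association requires at least one strain of each phenotype class"
            )


# ---------------------------------------------------------------------------
# I/O


def _extract_gene(contigs: Mapping[str, str], gene_id: str, contig_id: str,
                  start: int, end: int, strand: str) -> GeneRecord:
    if contig_id not in contigs:
        raise GenomeModelError(f"feature {gene_id} references unknown contig {contig_id}")
    contig = contigs[contig_id]
    if start < 0 or end > len(contig):
        raise GenomeModelError(f"feature {gene_id} out of contig bounds")
    nt = contig[start:end]
    if strand == "-":
        nt = reverse_complement(nt)
    aa, internal = "", False
    if len(nt) % 3 == 0 and not (set(nt) - set("ACGT")):
        aa, internal = translate_cds(nt)
    return GeneRecord(gene_id, contig_id, start, end, strand, nt, aa, internal)


def _parse_gff3(path: Path, contigs: Mapping[str, str], feature_type: str) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    counter = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeModelError(f"{path}: malformed GFF3 line: {line[:60]}")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            attributes = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    attributes[key.strip()] = val.strip()
            counter += 1
            gene_id = attributes.get("ID", f"{path.stem}_{ftype}_{counter}")
            # GFF3 is 1-based inclusive; internal convention 0-based half-open
            genes.append(_extract_gene(contigs, gene_id, seqid,
                                       int(start1) - 1, int(end1), strand))
    return genes


def read_phenotype_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``strain_id<TAB>phenotype``."""
    phenotype: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "strain_id" not in reader.fieldnames \
                or "phenotype" not in reader.fieldnames:
            raise GenomeModelError(f"{path}: expected columns strain_id, phenotype")
        for row in reader:
            phenotype[row["strain_id"]] = row["phenotype"]
    return phenotype


def read_genome_set(fasta_paths: Mapping[str, str | Path],
                    gff_paths: Mapping[str, str | Path],
                    phenotype_table: str | Path,
                    feature_type: str = "CDS") -> GenomeSet:
    """Load per-strain FASTA + GFF3 files and a phenotype TSV into a GenomeSet."""
    phenotype = read_phenotype_table(phenotype_table)
    strains = []
    for strain_id, fasta in fasta_paths.items():
        if strain_id not in gff_paths:
            raise GenomeModelError(f"no GFF3 path for strain {strain_id}")
        if strain_id not in phenotype:
            raise GenomeModelError(f"phenotype missing for strain {strain_id}")
        contigs = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(fasta), "fasta")}
        genes = _parse_gff3(Path(gff_paths[strain_id]), contigs, feature_type)
        strains.append(StrainGenome(strain_id, contigs, genes))
    relevant = {sid: ph for sid, ph in phenotype.items()
                if sid in {s.strain_id for s in strains}}
    return GenomeSet(strains, relevant)


def write_genome_set(genomeset: GenomeSet, out_dir: str | Path,
                     feature_type: str = "CDS") -> None:
    """Write per-strain FASTA/GFF3 plus ``phenotypes.tsv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for strain in genomeset.strains:
        records = [SeqRecord(Seq(seq), id=cid, description="")
                   for cid, seq in strain.contigs.items()]
        SeqIO.write(records, str(out / f"{strain.strain_id}.fasta"), "fasta")
        with open(out / f"{strain.strain_id}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in strain.genes:
                fh.write("\t".join([
                    g.contig_id, "bxdseeker", feature_type,
                    str(g.start + 1), str(g.end), ".", g.strand, "0",
                    f"ID={g.gene_id}",
                ]) + "\n")
    with open(out / "phenotypes.tsv", "w") as fh:
        fh.write("strain_id\tphenotype\n")
        for sid in genomeset.strain_ids:
            fh.write(f"{sid}\t{genomeset.phenotype[sid]}\n")


def load_genome_dir(directory: str | Path, feature_type: str = "CDS") -> GenomeSet:
    """Load a directory written by :func:`write_genome_set`."""
    d = Path(directory)
    fastas = sorted(d.glob("*.fasta"))
    fasta_paths = {p.stem: p for p in fastas}
    gff_paths = {p.stem: d / f"{p.stem}.gff3" for p in fastas}
    return read_genome_set(fasta_paths, gff_paths, d / "phenotypes.tsv",
                           feature_type=feature_type)


def gene_sequences(genomeset: GenomeSet,
                   strain_ids: Iterable[str] | None = None) -> list[tuple[str, str, str]]:
    """Flatten to (strain_id, gene_id, nt_seq) tuples for downstream search."""
    selected = list(strain_ids) if strain_ids is not None else genomeset.strain_ids
    out = []
    for sid in selected:
        for g in genomeset.strain(sid).genes:
            out.append((sid, g.gene_id, g.nt_seq))
    return out
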