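"""Gene-family (orthogroup) presence-absence association.

Families come either from an external OrthoFinder-style table or from an
internal greedy protein-clustering stand-in, and are tested for association
with the phenotype by Fisher's exact test on strain-level presence, with a
"unique and specific" call for families present in (essentially) all
positive strains and absent from (essentially) all negative strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._aligner import aa_identity
from .genome_model import GenomeSet
from .stats import AssociationResult, adjust_results, presence_fisher


@dataclass
class GeneFamily:
    family_id: str
    members: dict[str, list[str]]   # strain_id -> gene ids (copy number = len)

    def copy_number(self, strain_id: str) -> int:
        return len(self.members.get(strain_id, []))

    def present_strains(self) -> set[str]:
        return {s for s, genes in self.members.items() if genes}


@dataclass
class FamilyCallParams:
    specific_max_neg_fraction: float = 0.0
    unique_min_pos_fraction: float = 1.0
    alpha: float = 0.05
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        for name in ("specific_max_neg_fraction", "unique_min_pos_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def read_orthogroup_table(path: str | Path,
                          genomeset: GenomeSet | None = None) -> list[GeneFamily]:
    """Read an OrthoFinder ``Orthogroups.tsv`` dialect.

    First column is the orthogroup id, remaining columns one per strain with
    comma-separated gene ids; empty cells mean copy number zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    strain_cols = list(df.columns[1:])
    if genomeset is not None:
        unknown = set(strain_cols) - set(genomeset.strain_ids)
        if unknown:
            raise ValueError(f"unknown strain column(s): {sorted(unknown)}")
    families = []
    seen_genes: dict[str, str] = {}
    for _, row in df.iterrows():
        fid = row.iloc[0]
        members: dict[str, list[str]] = {}
        for col in strain_cols:
            genes = [g.strip() for g in str(row[col]).split(",") if g.strip()]
            for g in genes:
                if g in seen_genes:
                    raise ValueError(
                        f"gene {g} appears in both {seen_genes[g]} and {fid}")
                seen_genes[g] = fid
                if genomeset is not None:
                    genomeset.strain(col).gene(g)   # raises KeyError if absent
            members[col] = genes
        families.append(GeneFamily(str(fid), members))
    return families


def write_orthogroup_table(families: list[GeneFamily], strain_ids: list[str],
                           path: str | Path) -> None:
    rows = []
    for fam in families:
        row = {"Orthogroup": fam.family_id}
        for sid in strain_ids:
            row[sid] = ", ".join(fam.members.get(sid, []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_families_denovo(genomeset: GenomeSet,
                          protein_identity: float = 0.5) -> list[GeneFamily]:
    """Greedy centroid clustering of all proteins into families.

    Length-sorted greedy clustering at a global amino-acid identity
    threshold.  Candidate centroids are pre-screened by shared 5-mer
    content (a sequence must share >= 10% of its 5-mers with a centroid
    before alignment is attempted); at the identity levels this threshold
    targets, true members always pass the screen while unrelated proteins
    almost never trigger an alignment.
    """
    entries: list[tuple[str, str, str]] = []   # (strain, gene, aa)
    for strain in genomeset.strains:
        for g in strain.genes:
            if not g.aa_seq:
                raise ValueError(f"gene {g.gene_id} has no translation")
            entries.append((strain.strain_id, g.gene_id, g.aa_seq))
    order = sorted(range(len(entries)), key=lambda i: (-len(entries[i][2]), i))

    def kmers(seq: str, k: int = 5) -> frozenset[str]:
        return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))

    centroid_seqs: list[str] = []
    centroid_members: list[list[tuple[str, str]]] = []
    kmer_index: dict[str, list[int]] = {}
    for i in order:
        sid, gid, aa = entries[i]
        mers = kmers(aa)
        counts: dict[int, int] = {}
        for m in mers:
            for ci in kmer_index.get(m, ()):
                counts[ci] = counts.get(ci, 0) + 1
        threshold = max(3, int(0.1 * len(mers)))
        candidates = sorted(ci for ci, n in counts.items() if n >= threshold)
        assigned = False
        for ci in candidates:
            if aa_identity(aa, centroid_seqs[ci]) >= protein_identity:
                centroid_members[ci].append((sid, gid))
                assigned = True
                break
        if not assigned:
            ci = len(centroid_seqs)
            centroid_seqs.append(aa)
            centroid_members.append([(sid, gid)])
            for m in mers:
                kmer_index.setdefault(m, []).append(ci)
    families = []
    for ci, members in enumerate(centroid_members):
        by_strain: dict[str, list[str]] = {}
        for sid, gid in members:
            by_strain.setdefault(sid, []).append(gid)
        families.append(GeneFamily(f"OG{ci + 1:07d}", by_strain))
    return families


def associate_families(families: list[GeneFamily], genomeset: GenomeSet,
                       params: FamilyCallParams | None = None,
                       ) -> list[AssociationResult]:
    """Fisher's exact presence test per family, BH-corrected across families."""
    params = params or FamilyCallParams()
    genomeset.check_association_ready()
    results = [presence_fisher(fam.present_strains() & set(genomeset.strain_ids),
                               genomeset, alternative=params.alternative,
                               unit_id=fam.family_id)
               for fam in families]
    return adjust_results(results)


def unique_specific_families(families: list[GeneFamily], genomeset: GenomeSet,
                             params: FamilyCallParams | None = None,
                             ) -> list[tuple[GeneFamily, AssociationResult]]:
    """Families unique and specific to the positive phenotype class.

    A family is called when the fraction of negative strains carrying it is
    at most ``specific_max_neg_fraction`` and the fraction of positive
    strains carrying it is at least ``unique_min_pos_fraction`` (defaults:
    all positives, no negatives).  Each returned family carries its Fisher
    result with BH adjustment computed across *all* families.
    """
    params = params or FamilyCallParams()
    results = associate_families(families, genomeset, params)
    pos, neg = set(genomeset.positives), set(genomeset.negatives)
    called = []
    for fam, res in zip(families, results):
        present = fam.present_strains()
        frac_pos = len(present & pos) / len(pos)
        frac_neg = len(present & neg) / len(neg)
        if frac_neg <= params.specific_max_neg_fraction and \
                frac_pos >= params.unique_min_pos_fraction:
            called.append((fam, res))
    return called


def family_reference_genes(called: list[tuple[GeneFamily, AssociationResult]],
                           reference_strain: str) -> list[str]:
    """Reference-strain gene ids belonging to the called families."""
    out: list[str] = []
    for fam, _res in called:
        out.extend(fam.members.get(reference_strain, []))
    return sorted(set(out))
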