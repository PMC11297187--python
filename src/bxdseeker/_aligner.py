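"""Shared pairwise-alignment helpers.

All identity/similarity numbers in this package come through here so that
every module uses one fixed, documented scoring scheme:

* nucleotide: match +1, mismatch -1, gap open -2, gap extend -1, global
  with free end gaps (semi-global, vsearch-like);
* protein: BLOSUM62, gap open -11, gap extend -1, global (free end gaps)
  or local.

Identity is identical columns / alignment columns; similarity (protein) is
positively scoring columns / alignment columns.  Gap columns count in the
denominator and never as identical or positive.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps: glocal alignment, as in greedy centroid clustering tools
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


@lru_cache(maxsize=None)
def _aa_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    if mode == "global":
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    return aligner


@lru_cache(maxsize=200_000)
def nt_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the best semi-global DNA alignment.

    Memoized: association pipelines and permutation calibrations revisit the
    same sequence pairs many times.
    """
    if not a or not b:
        return 0.0
    aln = _nt_aligner().align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return counts.identities / aln.length


@lru_cache(maxsize=100_000)
def aa_alignment_stats(a: str, b: str, mode: str = "global") -> tuple[float, float, float, int]:
    """Align two proteins; return (identity%, similarity%, score, columns).

    Similarity counts columns whose BLOSUM62 score is positive (identities
    included); both percentages use total alignment columns as denominator.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    aligner = _aa_aligner(mode)
    for seq in (a, b):
        for res in seq:
            if res not in _BLOSUM62.alphabet:
                raise ValueError(f"invalid residue {res!r}")
    alns = aligner.align(a, b)
    aln = alns[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ncols = len(row_a)
    if ncols == 0:
        return 0.0, 0.0, float(aln.score), 0
    ident = 0
    positive = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if _BLOSUM62[x, y] > 0:
            positive += 1
    return (100.0 * ident / ncols, 100.0 * positive / ncols, float(aln.score), ncols)


def aa_identity(a: str, b: str) -> float:
    """Global-alignment protein identity as a fraction in [0, 1]."""
    ident_pct, _, _, _ = aa_alignment_stats(a, b, mode="global")
    return ident_pct / 100.0
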