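"""Protein homology screening.

Pairwise protein alignment with BLOSUM62 identity/similarity and a
best-hit screen of a query protein (e.g. the lactonase BxdA) across whole
proteomes, binning each target genome into high (similarity >= 60%),
intermediate, or low-or-absent (< 25% or no hit) presence categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._aligner import aa_alignment_stats


@dataclass
class AlignmentResult:
    aligned_columns: int
    identity: float      # % identical columns
    similarity: float    # % positively scoring columns (BLOSUM62)
    score: float


@dataclass
class ScreenResult:
    strain_id: str
    best_gene: str | None
    identity: float
    similarity: float
    category: str        # high / intermediate / low_or_absent


def align_pair(a: str, b: str, mode: str = "global") -> AlignmentResult:
    """Align two proteins (BLOSUM62, gap open 11, extend 1).

    Identity and similarity use total alignment columns as denominator; gap
    columns count as neither identical nor positive.
    """
    identity, similarity, score, ncols = aa_alignment_stats(a, b, mode=mode)
    return AlignmentResult(ncols, identity, similarity, score)


def categorize(similarity: float | None,
               thresholds: tuple[float, float] = (60.0, 25.0)) -> str:
    high, low = thresholds
    if similarity is None or similarity < low:
        return "low_or_absent"
    if similarity >= high:
        return "high"
    return "intermediate"


def best_hit_screen(query: str,
                    proteomes: Mapping[str, Sequence[tuple[str, str]]],
                    thresholds: tuple[float, float] = (60.0, 25.0),
                    mode: str = "global") -> dict[str, ScreenResult]:
    """Best-similarity hit of ``query`` in each strain's proteome.

    ``proteomes`` maps strain id to (gene_id, aa_seq) pairs.  Ties on
    similarity break by higher alignment score, then lexicographic gene id.
    Strains with an empty proteome report low_or_absent with no hit.

    The default end-gap-free global alignment keeps the per-column
    similarity of unrelated sequence pairs far below the low cut-off; pure
    local alignment (``mode="local"``) is available but can assign high
    per-column similarity to very short spurious alignments, a role the
    e-value filter plays in a classical sequence search.
    """
    if not query:
        raise ValueError("empty query protein")
    out: dict[str, ScreenResult] = {}
    for strain_id, proteins in proteomes.items():
        best: tuple[float, float, str, float] | None = None  # sim, score, gid, ident
        for gene_id, aa in sorted(proteins, key=lambda x: x[0]):
            if not aa:
                continue
            result = align_pair(query, aa, mode=mode)
            key = (result.similarity, result.score)
            if best is None or key > (best[0], best[1]):
                best = (result.similarity, result.score, gene_id, result.identity)
        if best is None:
            out[strain_id] = ScreenResult(strain_id, None, 0.0, 0.0, "low_or_absent")
        else:
            sim, _score, gid, ident = best
            out[strain_id] = ScreenResult(strain_id, gid, ident, sim,
                                          categorize(sim, thresholds))
    return out
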