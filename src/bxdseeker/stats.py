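"""Association statistics shared by the kmer and gene-family pipelines.

``presence_fisher`` builds the 2x2 phenotype-by-presence table for a set of
strains carrying a feature and computes Fisher's exact test.  The two-sided
p sums hypergeometric point probabilities no larger than the observed one
(the standard minimum-likelihood rule); one-sided tails come straight from
the hypergeometric survival/cumulative functions.  Benjamini-Hochberg
adjustment is delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome_model import GenomeSet


@dataclass
class AssociationResult:
    """Fisher's exact test of one feature's presence against the phenotype.

    Table layout::

                      present  absent
        positive         a        b
        negative         c        d
    """

    unit_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    p_adj: float = float("nan")

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> tuple[float, float]:
    """Odds ratio and exact hypergeometric p for a 2x2 table.

    ``alternative`` is ``two-sided`` or ``greater`` (enrichment of presence
    in the positive class).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    n = r1 + r2
    k = a + c
    if n == 0:
        raise ValueError("empty table")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    if alternative == "greater":
        p = float(hypergeom.sf(a - 1, n, r1, k))
    elif alternative == "less":
        p = float(hypergeom.cdf(a, n, r1, k))
    elif alternative == "two-sided":
        lo, hi = max(0, k - r2), min(k, r1)
        xs = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(xs, n, r1, k)
        p_obs = pmf[a - lo]
        # tie tolerance for floating-point equal point probabilities
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return odds, min(1.0, max(0.0, p))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (FDR)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def presence_fisher(hit_strains: Iterable[str], genomeset: GenomeSet,
                    alternative: str = "two-sided",
                    unit_id: str = "") -> AssociationResult:
    """Fisher's exact test of strain-level presence against the phenotype."""
    genomeset.check_association_ready()
    strains = set(genomeset.strain_ids)
    present = set(hit_strains)
    unknown = present - strains
    if unknown:
        raise ValueError(f"hit strains not in genome set: {sorted(unknown)}")
    pos = set(genomeset.positives)
    neg = set(genomeset.negatives)
    a = len(present & pos)
    b = len(pos - present)
    c = len(present & neg)
    d = len(neg - present)
    odds, p = fisher_exact_2x2(a, b, c, d, alternative=alternative)
    return AssociationResult(unit_id, a, b, c, d, odds, p)


def adjust_results(results: list[AssociationResult]) -> list[AssociationResult]:
    """BH-adjust p-values across a family of association results, in place."""
    if results:
        adj = benjamini_hochberg([r.p for r in results])
        for r, q in zip(results, adj):
            r.p_adj = float(q)
    return results
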