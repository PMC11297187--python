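"""Lightweight differential-expression stage.

A documented stand-in for a full negative-binomial GLM workflow: counts are
normalised with median-of-ratios size factors and each gene is tested with a
Welch t-test on ``log2(normalised + 1)``, Benjamini-Hochberg corrected.  Its
only contract is recovery of planted signal on synthetic counts; an external
DE table (gene_id, lfc, padj) produced by a dedicated tool can be dropped in
instead for real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg


@dataclass
class CountMatrix:
    """Integer gene-by-sample counts plus a sample -> condition map."""

    counts: pd.DataFrame
    condition: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples_for(self, cond: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == cond]

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        meta = pd.DataFrame({"sample": list(self.counts.columns),
                             "condition": [self.condition[s] for s in self.counts.columns]})
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(counts, dict(zip(meta["sample"], meta["condition"])))


@dataclass
class DEResult:
    gene_id: str
    log2_fold_change: float
    p: float
    p_adj: float
    is_de: bool


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors.

    The reference profile is the per-gene geometric mean over genes with
    strictly positive counts in every sample; each sample's factor is the
    median of its count/reference ratios over those genes.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    positive = (df > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with positive counts in every sample")
    sub = df.loc[positive].astype(float)
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0))


def de_test(counts: CountMatrix, alpha: float = 0.05,
            lfc_min: float = 0.0) -> list[DEResult]:
    """Per-gene Welch t-test on log2 size-factor-normalised counts.

    Log2 fold change is (treatment mean - control mean) on the log2 scale;
    genes with zero variance in both groups get p = 1 when the means agree
    (no evidence) and p = 0 when they differ exactly.
    """
    ctrl = counts.samples_for("control")
    trt = [s for s in counts.counts.columns if counts.condition[s] != "control"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 replicates in each condition")
    sf = size_factors(counts)
    norm = counts.counts / sf
    log = np.log2(norm + 1.0)
    x = log[trt].values
    y = log[ctrl].values
    lfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = sps.ttest_ind(x, y, axis=1, equal_var=False)
    degenerate = np.isnan(pvals)
    pvals = np.where(degenerate, np.where(np.isclose(lfc, 0.0), 1.0, 0.0), pvals)
    padj = benjamini_hochberg(pvals)
    results = []
    for gid, l, p, q in zip(counts.counts.index, lfc, pvals, padj):
        is_de = bool(q < alpha and abs(l) >= lfc_min)
        results.append(DEResult(str(gid), float(l), float(p), float(q), is_de))
    return results


def de_gene_ids(results: list[DEResult]) -> list[str]:
    return [r.gene_id for r in results if r.is_de]


def read_external_de_table(path: str | Path, alpha: float = 0.05) -> list[DEResult]:
    """Read a (gene_id, lfc, padj) TSV exported from a dedicated DE tool."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "lfc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"external DE table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        q = float(row["padj"])
        p = float(row["p"]) if "p" in df.columns else q
        out.append(DEResult(str(row["gene_id"]), float(row["lfc"]), p, q,
                            bool(q < alpha)))
    return out


def write_de_table(results: list[DEResult], path: str | Path) -> None:
    pd.DataFrame([{"gene_id": r.gene_id, "lfc": r.log2_fold_change,
                   "p": r.p, "padj": r.p_adj, "is_de": r.is_de}
                  for r in results]).to_csv(path, sep="\t", index=False)
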