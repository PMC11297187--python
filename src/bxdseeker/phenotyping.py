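"""Phenotype classification and growth statistics.

Implements the liquid-assay classification rules for benzoxazinoid
degradation (strong / weak / non relative to a no-bacteria control),
AMPO-former classification relative to the panel maximum, growth-curve AUC
and treatment-vs-control growth-benefit testing, the carbon-equivalent
glucose helper for media design, and 16S-based strain abundance estimation
from ASV tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._aligner import nt_identity
from .stats import benjamini_hochberg


class DegradationClass(str, Enum):
    STRONG = "strong"
    WEAK = "weak"
    NON = "non"


def classify_degrader(sample_conc: float, control_conc: float) -> DegradationClass:
    """Classify degradation of a compound relative to the no-bacteria control.

    Percent degraded is ``100 * (1 - sample/control)``; strong above 90%,
    non below 30%, weak in between (both boundaries fall into weak).
    """
    if control_conc <= 0:
        raise ValueError("control concentration must be positive")
    degraded = 100.0 * (1.0 - sample_conc / control_conc)
    if degraded > 90.0:
        return DegradationClass.STRONG
    if degraded < 30.0:
        return DegradationClass.NON
    return DegradationClass.WEAK


def classify_ampo_former(sample_ampo: float, max_ampo: float) -> DegradationClass:
    """Classify AMPO formation relative to the strongest former in the panel.

    Strong above 10% of the maximum, non below 0.1%, weak in the inclusive
    band between.
    """
    if max_ampo <= 0:
        raise ValueError("maximum AMPO concentration must be positive")
    pct = 100.0 * sample_ampo / max_ampo
    if pct > 10.0:
        return DegradationClass.STRONG
    if pct < 0.1:
        return DegradationClass.NON
    return DegradationClass.WEAK


@dataclass
class GrowthCurve:
    times: np.ndarray   # hours, strictly increasing
    od: np.ndarray      # OD600

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def growth_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the growth curve (OD x hours)."""
    if curve.times.size < 2:
        raise ValueError("need at least 2 time points")
    return float(np.trapezoid(curve.od, curve.times))


def growth_benefit_test(auc_treatment: Mapping[str, Sequence[float]],
                        auc_control: Mapping[str, Sequence[float]],
                        log_ratios: bool = False) -> pd.DataFrame:
    """Per-strain growth benefit of a treatment relative to its control.

    Each treatment replicate is normalised by the strain's mean control AUC;
    the resulting ratios are tested against 1 with a one-sample t-test
    (optionally on the log scale against 0) and BH-adjusted across strains.
    """
    rows = []
    for sid in auc_treatment:
        treat = np.asarray(auc_treatment[sid], dtype=float)
        ctrl = np.asarray(auc_control[sid], dtype=float)
        if treat.size < 2 or ctrl.size < 2:
            raise ValueError(f"strain {sid}: need >= 2 replicates per arm")
        ctrl_mean = ctrl.mean()
        if ctrl_mean == 0:
            raise ValueError(f"strain {sid}: zero control mean")
        ratios = treat / ctrl_mean
        if log_ratios:
            stat = sps.ttest_1samp(np.log(ratios), 0.0)
        else:
            stat = sps.ttest_1samp(ratios, 1.0)
        p = float(stat.pvalue)
        if np.isnan(p):   # zero-variance ratios exactly at the null value
            p = 1.0
        rows.append({"strain_id": sid, "ratio": float(ratios.mean()), "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = benjamini_hochberg(df["p"].values) if len(df) else []
    return df


def carbon_equivalent_glucose(conc: float, carbons_per_molecule: int) -> int:
    """Glucose concentration carrying the same carbon as ``conc`` of a compound.

    Glucose has 6 carbons, so the equivalent is ``conc * carbons / 6``,
    rounded to the nearest integer (micromolar in, micromolar out).
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if carbons_per_molecule < 1:
        raise ValueError("carbons_per_molecule must be >= 1")
    return int(round(conc * carbons_per_molecule / 6.0))


def estimate_strain_abundance(strain_marker_seq: str,
                              asv_table: Iterable[tuple[str, float]]) -> float:
    """Community abundance of a strain from a 16S ASV table.

    Sums the relative abundances (%) of all ASVs whose global-alignment
    identity to the strain's marker sequence strictly exceeds 99%.
    """
    total = 0.0
    for asv_seq, abundance in asv_table:
        if not 0 <= abundance <= 100:
            raise ValueError("relative abundances must lie in [0, 100]")
        if nt_identity(strain_marker_seq, asv_seq) > 0.99:
            total += abundance
    return total


# ---------------------------------------------------------------------------
# table-level helpers


def classify_metabolite_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply both classification rules to a tidy metabolite table.

    Expects columns ``strain_id, compound, concentration, is_control`` with
    one no-bacteria-control (NBC) level per compound.  Returns one row per
    strain with ``mboa_class`` (degradation of MBOA vs NBC) and
    ``ampo_class`` (AMPO relative to the panel maximum).
    """
    required = {"strain_id", "compound", "concentration", "is_control"}
    if not required.issubset(table.columns):
        raise ValueError(f"metabolite table needs columns {sorted(required)}")
    nbc = table[table["is_control"]]
    mboa_ctrl = nbc.loc[nbc["compound"] == "MBOA", "concentration"]
    if len(mboa_ctrl) != 1:
        raise ValueError("expected exactly one MBOA no-bacteria control")
    control = float(mboa_ctrl.iloc[0])
    samples = table[~table["is_control"]]
    ampo = samples[samples["compound"] == "AMPO"].set_index("strain_id")["concentration"]
    mboa = samples[samples["compound"] == "MBOA"].set_index("strain_id")["concentration"]
    max_ampo = float(ampo.max())
    rows = []
    for sid in mboa.index:
        rows.append({
            "strain_id": sid,
            "mboa_class": classify_degrader(float(mboa[sid]), control).value,
            "ampo_class": classify_ampo_former(float(ampo.get(sid, 0.0)), max_ampo).value,
        })
    return pd.DataFrame(rows)


def growth_aucs_from_table(growth: pd.DataFrame,
                           treatment: str) -> dict[str, list[float]]:
    """Per-strain replicate AUCs for one treatment from a tidy curve table."""
    out: dict[str, list[float]] = {}
    sub = growth[growth["treatment"] == treatment]
    for (sid, _rep), grp in sub.groupby(["strain_id", "replicate"]):
        grp = grp.sort_values("time_h")
        curve = GrowthCurve(grp["time_h"].values, grp["od600"].values)
        out.setdefault(sid, []).append(growth_auc(curve))
    return out
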