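"""Efficiency-corrected 3C-qPCR quantification.

Primer-pair amplification efficiency E is estimated from a genomic-DNA
standard curve: ordinary least squares of Ct on log10(dilution) gives the
slope s, and E = 10^(-1/s) - 1 (E = 1 means perfect per-cycle doubling).
Primer pairs outside the 90-110% efficiency window fail QC.  Template
abundance is then the efficiency-corrected relative quantity
RQ = (1 + E)^(-Ct), normalized to the anchor self-ligation product to give
interaction frequencies, and summarized as mean +/- SEM across biological
replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["primer_pair_id", "sample_id", "replicate", "dilution", "ct"]


class QpcrError(ValueError):
    """Invalid qPCR input (degenerate curve, missing anchor, ...)."""


@dataclass(frozen=True)
class StandardCurve:
    """Fitted standard curve and derived amplification efficiency."""

    primer_pair_id: str
    slope: float  # Ct per log10(dilution)
    intercept: float
    r_squared: float
    efficiency: float  # E, as a fraction (1.0 == 100%)
    passed_qc: bool


def fit_standard_curve(
    dilutions: Sequence[float],
    cts: Sequence[float],
    primer_pair_id: str = "",
    qc_lo: float = 0.90,
    qc_hi: float = 1.10,
) -> StandardCurve:
    """OLS of Ct on log10(dilution); E = 10^(-1/slope) - 1.

    QC passes iff qc_lo <= E <= qc_hi (bounds inclusive).  Requires at least
    three distinct dilutions and a negative slope (Ct must rise as template
    is diluted).
    """
    d = np.asarray(dilutions, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if d.shape != ct.shape:
        raise QpcrError("dilutions and cts differ in length")
    if np.any(d <= 0):
        raise QpcrError("dilutions must be positive")
    if len(np.unique(d)) < 3:
        raise QpcrError("need >= 3 distinct dilutions for a standard curve")
    fit = stats.linregress(np.log10(d), ct)
    if fit.slope >= 0:
        raise QpcrError(
            f"{primer_pair_id or 'curve'}: non-amplifying curve "
            f"(slope {fit.slope:.4g} >= 0)"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        primer_pair_id=primer_pair_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
        passed_qc=qc_lo <= efficiency <= qc_hi,
    )


def relative_quantity(ct: float, efficiency: float) -> float:
    """Efficiency-corrected relative quantity RQ = (1+E)^(-Ct)."""
    if efficiency <= 0:
        raise QpcrError(f"efficiency must be > 0, got {efficiency}")
    return (1.0 + efficiency) ** (-ct)


def normalize_to_anchor(
    rq_by_region: Mapping[str, float], anchor_region_id: str
) -> Dict[str, float]:
    """Divide every region's RQ by the anchor self-ligation RQ (anchor -> 1)."""
    if anchor_region_id not in rq_by_region:
        raise QpcrError(f"anchor region {anchor_region_id!r} missing")
    anchor = rq_by_region[anchor_region_id]
    if anchor <= 0:
        raise QpcrError(f"anchor RQ must be > 0, got {anchor}")
    return {region: rq / anchor for region, rq in rq_by_region.items()}


@dataclass(frozen=True)
class InteractionFrequency:
    region_id: str
    mean: float
    sem: Optional[float]  # None when n == 1
    n: int
    normalized_to: str


def summarize_replicates(
    values: Sequence[float],
    region_id: str = "",
    normalized_to: str = "",
) -> InteractionFrequency:
    """Mean and SEM (n-1 sample sd / sqrt(n)) across biological replicates."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise QpcrError("no replicate values")
    sem = None if v.size == 1 else float(np.std(v, ddof=1) / math.sqrt(v.size))
    return InteractionFrequency(
        region_id=region_id,
        mean=float(np.mean(v)),
        sem=sem,
        n=int(v.size),
        normalized_to=normalized_to,
    )


@dataclass(frozen=True)
class RatioEstimate:
    ratio: float
    sem: Optional[float]


def _ratio_with_sem(
    num: InteractionFrequency, den: InteractionFrequency
) -> RatioEstimate:
    if den.mean == 0:
        raise QpcrError(f"flank region {den.region_id!r} has zero mean")
    r = num.mean / den.mean
    if num.sem is None or den.sem is None:
        return RatioEstimate(r, None)
    # first-order (delta-method) propagation for a ratio of independent means
    rel = math.sqrt((num.sem / num.mean) ** 2 + (den.sem / den.mean) ** 2)
    return RatioEstimate(r, abs(r) * rel)


def compare_promoter_flank(
    promoter: InteractionFrequency,
    upstream: InteractionFrequency,
    downstream: InteractionFrequency,
) -> Dict[str, RatioEstimate]:
    """Promoter / flank interaction-frequency ratios with propagated SEM."""
    return {
        "promoter_vs_upstream": _ratio_with_sem(promoter, upstream),
        "promoter_vs_downstream": _ratio_with_sem(promoter, downstream),
    }


def read_ct_table(path) -> pd.DataFrame:
    """Ct table TSV: primer_pair_id, sample_id, replicate, dilution (or NA), ct."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise QpcrError(f"{path}: missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise QpcrError(f"{path}: non-positive Ct values")
    return df


def fit_curves_from_table(
    ct_table: pd.DataFrame, qc_lo: float = 0.90, qc_hi: float = 1.10
) -> Dict[str, StandardCurve]:
    """Fit one standard curve per primer pair from the dilution-series rows."""
    std = ct_table[ct_table["dilution"].notna()]
    if std.empty:
        raise QpcrError("no dilution-series rows in Ct table")
    curves: Dict[str, StandardCurve] = {}
    for pid, grp in std.groupby("primer_pair_id"):
        curves[str(pid)] = fit_standard_curve(
            grp["dilution"].to_numpy(), grp["ct"].to_numpy(),
            primer_pair_id=str(pid), qc_lo=qc_lo, qc_hi=qc_hi,
        )
    return curves


def quantify(
    ct_table: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    anchor_primer_pair_id: str,
    technical_average: str = "ct",
) -> Dict[str, InteractionFrequency]:
    """Anchor-normalized interaction frequencies per primer pair (region).

    Sample rows (dilution NA) are used; ``sample_id`` identifies the
    biological replicate and ``replicate`` the technical replicate.
    Technical replicates are averaged on the Ct scale by default
    (``technical_average='rq'`` averages RQ instead); anchor normalization
    happens within each biological replicate before summarization, so
    within-replicate pairing is preserved.
    """
    if technical_average not in ("ct", "rq"):
        raise QpcrError("technical_average must be 'ct' or 'rq'")
    samples = ct_table[ct_table["dilution"].isna()]
    if samples.empty:
        raise QpcrError("no sample rows (dilution NA) in Ct table")
    per_replicate: Dict[str, Dict[str, float]] = {}
    for (sample_id, pid), grp in samples.groupby(["sample_id", "primer_pair_id"]):
        pid = str(pid)
        if pid not in curves:
            raise QpcrError(f"no standard curve for primer pair {pid!r}")
        eff = curves[pid].efficiency
        if technical_average == "ct":
            rq = relative_quantity(float(grp["ct"].mean()), eff)
        else:
            rq = float(
                np.mean([relative_quantity(c, eff) for c in grp["ct"]])
            )
        per_replicate.setdefault(str(sample_id), {})[pid] = rq
    normalized: Dict[str, list] = {}
    for sample_id, rq_by_region in per_replicate.items():
        for region, value in normalize_to_anchor(
            rq_by_region, anchor_primer_pair_id
        ).items():
            normalized.setdefault(region, []).append(value)
    return {
        region: summarize_replicates(
            values, region_id=region, normalized_to=anchor_primer_pair_id
        )
        for region, values in normalized.items()
    }
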