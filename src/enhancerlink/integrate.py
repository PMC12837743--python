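"""Enhancer target-gene nomination: differential expression x 4C contacts.

A gene is a candidate target of the viewpoint enhancer when it is (step 1)
significantly down-regulated after enhancer deletion and (step 2) lies
within, or near, a genomic region that interacts reproducibly with the
viewpoint above the RPM threshold.  Thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .fourc import InteractionCall

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "log2fc", "pvalue", "padj"]


class IntegrateError(ValueError):
    """Invalid differential-expression or nomination input."""


@dataclass(frozen=True)
class DERecord:
    """One gene's coordinates with log2 fold-change and (adjusted) p-value."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    log2fc: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntegrateError(f"{self.gene_id}: start >= end")
        for name, value in (("pvalue", self.pvalue), ("padj", self.padj)):
            if not 0.0 <= value <= 1.0:
                raise IntegrateError(f"{self.gene_id}: {name}={value} outside [0,1]")


@dataclass
class CandidateGene:
    gene_id: str
    supporting_fragment_ids: List[int]
    best_min_rpm: float
    distance_class: str  # "cis" or "trans"
    distance_to_bait: Optional[float]


def read_de_table(path) -> List[DERecord]:
    """Read the DE TSV (gene_id, chrom, start, end, strand, log2fc, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise IntegrateError(f"{path}: missing columns {sorted(missing)}")
    return [
        DERecord(
            gene_id=str(r.gene_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), strand=str(r.strand), log2fc=float(r.log2fc),
            pvalue=float(r.pvalue), padj=float(r.padj),
        )
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: Sequence[DERecord], path) -> None:
    pd.DataFrame([vars(r) for r in records])[DE_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def filter_de(
    records: Iterable[DERecord],
    direction: str,
    fc_cut: Optional[float] = 1.3,
    padj_cut: float = 0.05,
) -> Set[str]:
    """Gene ids passing the directional DE filter (strict inequalities).

    ``fc_cut`` is a magnitude; ``None`` means sign-only (any down- or
    up-regulation), used for padj-only set definitions.
    """
    if fc_cut is not None and fc_cut <= 0:
        raise IntegrateError("fc_cut must be a positive magnitude")
    if direction not in ("up", "down"):
        raise IntegrateError(f"direction must be 'up' or 'down', got {direction!r}")
    cut = 0.0 if fc_cut is None else fc_cut
    out: Set[str] = set()
    for rec in records:
        if not rec.padj < padj_cut:
            continue
        if direction == "down" and rec.log2fc < -cut:
            out.add(rec.gene_id)
        elif direction == "up" and rec.log2fc > cut:
            out.add(rec.gene_id)
    return out


def assign_calls_to_genes(
    calls: Sequence[InteractionCall],
    genes: Sequence[DERecord],
    window: int = 50_000,
) -> Dict[str, List[InteractionCall]]:
    """Map gene_id -> calls overlapping [start - window, end + window)."""
    if window < 0:
        raise IntegrateError("window must be >= 0")
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        lo = max(0, gene.start - window)
        hi = gene.end + window
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene.gene_id)
    support: Dict[str, List[InteractionCall]] = {}
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(call.start, call.end):
            support.setdefault(iv.data, []).append(call)
    return support


def nominate_targets(
    de_records: Sequence[DERecord],
    calls: Sequence[InteractionCall],
    fc_cut: float = 1.3,
    padj_cut: float = 0.05,
    rpm_cut: float = 50.0,
    window: int = 50_000,
) -> List[CandidateGene]:
    """Two-step filter: down-regulated genes supported by an interaction call.

    A supporting call must have minimum across-replicate RPM > ``rpm_cut``.
    Output is sorted by best supporting RPM descending, ties by gene_id.
    Trans-supported genes are nominated identically to cis.
    """
    down = filter_de(de_records, "down", fc_cut=fc_cut, padj_cut=padj_cut)
    support = assign_calls_to_genes(calls, de_records, window=window)
    candidates: List[CandidateGene] = []
    for gene in de_records:
        if gene.gene_id not in down:
            continue
        strong = [c for c in support.get(gene.gene_id, []) if c.min_rpm > rpm_cut]
        if not strong:
            continue
        best = max(strong, key=lambda c: c.min_rpm)
        candidates.append(
            CandidateGene(
                gene_id=gene.gene_id,
                supporting_fragment_ids=sorted(c.fragment_id for c in strong),
                best_min_rpm=best.min_rpm,
                distance_class="cis" if best.is_cis else "trans",
                distance_to_bait=best.distance_to_bait,
            )
        )
    candidates.sort(key=lambda c: (-c.best_min_rpm, c.gene_id))
    return candidates


def write_candidates(candidates: Sequence[CandidateGene], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tbest_min_rpm\tdistance_class\tdistance_to_bait\t"
            "supporting_fragment_ids\n"
        )
        for c in candidates:
            dist = "NA" if c.distance_to_bait is None else f"{c.distance_to_bait:.1f}"
            frags = ",".join(str(f) for f in c.supporting_fragment_ids)
            fh.write(
                f"{c.gene_id}\t{c.best_min_rpm:.6f}\t{c.distance_class}\t{dist}\t"
                f"{frags}\n"
            )


@dataclass(frozen=True)
class GeneSetSpec:
    """A thresholded DE gene-set definition (direction + cuts)."""

    direction: str
    padj_cut: float = 0.05
    fc_cut: Optional[float] = None  # None: padj (and sign) only


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_common: int
    members: frozenset


def overlap_gene_sets(
    spec_a: GeneSetSpec,
    spec_b: GeneSetSpec,
    de_a: Sequence[DERecord],
    de_b: Optional[Sequence[DERecord]] = None,
) -> OverlapResult:
    """Sizes and intersection of two thresholded DE gene sets.

    When the two tables cover different gene universes a warning is logged
    and the intersection is taken over shared gene ids.
    """
    if de_b is None:
        de_b = de_a
    universe_a = {r.gene_id for r in de_a}
    universe_b = {r.gene_id for r in de_b}
    if universe_a != universe_b:
        logger.warning(
            "gene universes differ (%d vs %d ids); intersecting over %d shared",
            len(universe_a), len(universe_b), len(universe_a & universe_b),
        )
    set_a = filter_de(de_a, spec_a.direction, spec_a.fc_cut, spec_a.padj_cut)
    set_b = filter_de(de_b, spec_b.direction, spec_b.fc_cut, spec_b.padj_cut)
    common = set_a & set_b
    return OverlapResult(len(set_a), len(set_b), len(common), frozenset(common))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise IntegrateError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise IntegrateError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]
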