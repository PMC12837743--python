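"""Allele-specific transcription-factor motif scoring at a SNP.

A JASPAR-style position frequency matrix is converted to probabilities with
an equally-split pseudocount, and every motif-length window overlapping the
SNP is scored on both strands as a sum of log2 odds against the background.
The report compares the best-scoring window for the reference vs the
alternate allele; a positive delta means the alternate allele is the better
binding site.  Also provides the ChIP-qPCR percent-input / fold-enrichment
arithmetic used to compare alleles experimentally.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import motifs as bio_motifs

from ._util import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MotifError(ValueError):
    """Invalid PWM or scoring input."""


@dataclass
class PWMModel:
    """Position weight matrix with background and pseudocount.

    ``counts`` is 4 x L (rows A, C, G, T).  Column probabilities are
    (count + pseudocount/4) / (column sum + pseudocount).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise MotifError("counts must have 4 rows (A, C, G, T)")
        if self.counts.shape[1] < 4:
            raise MotifError("motif length must be >= 4")
        if np.any(self.counts < 0):
            raise MotifError("negative counts")
        if self.pseudocount <= 0:
            raise MotifError("pseudocount must be > 0")
        if self.background.shape != (4,) or not math.isclose(
            float(self.background.sum()), 1.0, rel_tol=1e-9
        ):
            raise MotifError("background must be 4 probabilities summing to 1")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    @property
    def probabilities(self) -> np.ndarray:
        colsum = self.counts.sum(axis=0, keepdims=True)
        return (self.counts + self.pseudocount / 4.0) / (colsum + self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), 4 x L."""
        return np.log2(self.probabilities / self.background[:, None])

    def reverse_complement(self) -> "PWMModel":
        return PWMModel(
            name=f"{self.name}_rc",
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )


def load_jaspar_pfm(
    path_or_text,
    pseudocount: float = 0.8,
    background: Optional[Sequence[float]] = None,
) -> PWMModel:
    """Parse a JASPAR PFM file (bracketed or plain four-row dialect).

    Accepts a ``>ID name`` header followed by four count rows in A/C/G/T
    order, either ``A [ 1 2 ... ]`` style or bare whitespace-separated
    numbers.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(path_or_text)
    if "[" in text:
        motif = bio_motifs.read(io.StringIO(text), "jaspar")
        name = motif.name or motif.matrix_id or "motif"
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        name = "motif"
        if lines and lines[0].startswith(">"):
            header = lines.pop(0)[1:].split()
            name = header[-1] if header else "motif"
        rows = []
        for ln in lines:
            parts = ln.split()
            if parts and parts[0].upper() in _BASE_INDEX and len(parts) > 1:
                parts = parts[1:]
            rows.append(" ".join(parts))
        if len(rows) != 4:
            raise MotifError(f"expected 4 count rows, found {len(rows)}")
        motif = bio_motifs.read(io.StringIO("\n".join(rows) + "\n"), "pfm")
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    if np.any(counts < 0):
        raise MotifError("negative counts in PFM")
    kwargs = {}
    if background is not None:
        kwargs["background"] = np.asarray(background, dtype=float)
    return PWMModel(name=name, counts=counts, pseudocount=pseudocount, **kwargs)


def write_jaspar_pfm(pwm: PWMModel, path, matrix_id: str = "MA0000.0") -> None:
    with open(path, "w") as fh:
        fh.write(f">{matrix_id} {pwm.name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in pwm.counts[i])
            fh.write(f"{base} [ {vals} ]\n")


def score_window(pwm: PWMModel, window: str) -> float:
    """Sum of log2 odds for one L-length window (forward orientation)."""
    if len(window) != pwm.length:
        raise MotifError("window length does not match motif length")
    lo = pwm.log_odds
    total = 0.0
    for j, base in enumerate(window):
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise MotifError(f"cannot score base {base!r}")
        total += lo[idx, j]
    return float(total)


@dataclass(frozen=True)
class AlleleScoreReport:
    snp_id: str
    allele_ref: str
    allele_alt: str
    best_score_ref: float
    best_score_alt: float
    best_window_ref: Tuple[int, str]  # (context offset, strand)
    best_window_alt: Tuple[int, str]
    delta: float  # alt - ref, in bits


def _best_overlapping_score(
    pwm: PWMModel, seq: str, snp_offset: int
) -> Tuple[float, Tuple[int, str]]:
    L = pwm.length
    best: Optional[Tuple[float, Tuple[int, str]]] = None
    n_skipped = 0
    n_windows = 0
    for offset in range(snp_offset - L + 1, snp_offset + 1):
        window = seq[offset : offset + L]
        n_windows += 2
        for strand in "+-":
            w = window if strand == "+" else revcomp(window)
            if "N" in w:
                n_skipped += 1
                continue
            score = score_window(pwm, w)
            if best is None or score > best[0]:
                best = (score, (offset, strand))
    if best is None:
        raise MotifError("all windows overlapping the SNP contain N")
    return best


def score_alleles(
    pwm: PWMModel,
    context: str,
    snp_offset: int,
    ref_base: str,
    alt_base: str,
    snp_id: str = "",
) -> AlleleScoreReport:
    """Best motif score overlapping the SNP for each allele, both strands.

    The context must be long enough that every motif-length window
    overlapping the SNP exists (snp_offset >= L-1 and at least L bases from
    the SNP to the context end), and must carry ``ref_base`` at the SNP.
    """
    context = context.upper()
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    L = pwm.length
    if not 0 <= snp_offset < len(context):
        raise MotifError("SNP offset outside context")
    if snp_offset < L - 1 or len(context) - snp_offset < L:
        raise MotifError(
            f"context too short: need {L - 1} bases left and {L - 1} right of the SNP"
        )
    if context[snp_offset] != ref_base:
        raise MotifError(
            f"context carries {context[snp_offset]!r} at the SNP, not "
            f"ref allele {ref_base!r}"
        )
    results = {}
    for allele in (ref_base, alt_base):
        seq = context[:snp_offset] + allele + context[snp_offset + 1 :]
        results[allele] = _best_overlapping_score(pwm, seq, snp_offset)
    score_ref, window_ref = results[ref_base]
    score_alt, window_alt = results[alt_base]
    return AlleleScoreReport(
        snp_id=snp_id,
        allele_ref=ref_base,
        allele_alt=alt_base,
        best_score_ref=score_ref,
        best_score_alt=score_alt,
        best_window_ref=window_ref,
        best_window_alt=window_alt,
        delta=score_alt - score_ref,
    )


def chip_fold_enrichment(
    ct_ip_target: float,
    ct_input_target: float,
    ct_ip_ctrl: float,
    ct_input_ctrl: float,
    input_dilution_factor: float = 50.0,
) -> float:
    """ChIP-qPCR fold enrichment of a target condition over a control.

    Percent input per condition is 100 * 2^((Ct_input - log2(dilution)) -
    Ct_IP); the fold is the ratio of percent inputs.  The dilution factor is
    the fraction of chromatin set aside as input (e.g. 2% input -> 50).
    """
    if input_dilution_factor <= 0:
        raise MotifError("input dilution factor must be > 0")
    for name, ct in (
        ("ct_ip_target", ct_ip_target), ("ct_input_target", ct_input_target),
        ("ct_ip_ctrl", ct_ip_ctrl), ("ct_input_ctrl", ct_input_ctrl),
    ):
        if ct <= 0:
            raise MotifError(f"{name} must be > 0")
    log2_df = math.log2(input_dilution_factor)
    pct_target = 100.0 * 2.0 ** ((ct_input_target - log2_df) - ct_ip_target)
    pct_ctrl = 100.0 * 2.0 ** ((ct_input_ctrl - log2_df) - ct_ip_ctrl)
    return pct_target / pct_ctrl


def snp_in_intervals(
    chrom: str,
    position: int,
    intervals: Sequence[Tuple[str, int, int, str]],
) -> Tuple[bool, List[str]]:
    """Whether the SNP falls in any half-open interval; returns matching ids.

    ``intervals`` are (chrom, start, end, name) tuples, BED semantics
    (start <= position < end).
    """
    hits = [
        name
        for ichrom, start, end, name in intervals
        if ichrom == chrom and start <= position < end
    ]
    return (bool(hits), hits)


def read_bed_intervals(path) -> List[Tuple[str, int, int, str]]:
    out: List[Tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MotifError(f"{path}: line {lineno}: expected >= 3 columns")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out
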