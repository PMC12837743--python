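"""Seeded generators for every input the pipeline consumes, with ground truth.

The default scenario emulates a viewpoint 4C experiment on a two-chromosome
toy genome: contacts from the bait fragment decay with genomic distance in
cis, a sparse uniform background covers trans fragments, and a few planted
peak fragments carry strongly elevated contact weight.  Matching DE tables
plant down-regulated target genes over the peak fragments among null genes,
and Ct tables are generated from known primer efficiencies.  All generators
are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._util import stable_label_seed
from .fragmap import (
    BaitSpec,
    CVIQI,
    DPNII,
    FragmentMap,
    ReferenceSet,
    digest_genome,
    write_fragment_map,
)
from .fourc import ReadPair
from .integrate import DE_COLUMNS, DERecord, benjamini_hochberg, write_de_table
from .motif import PWMModel, write_jaspar_pfm
from .qpcr3c import CT_COLUMNS

BASES = np.array(list("ACGT"))


class SynthError(ValueError):
    """Invalid simulation parameters."""


# ---------------------------------------------------------------------------
# genome


def make_genome(
    seed: int,
    chrom_lengths: Mapping[str, int],
    motif_spacing: int = 400,
) -> ReferenceSet:
    """Uniform random genome with a GATC site injected every ~motif_spacing bp.

    Random sequence already carries GATC every ~256 bp on average; the
    injected sites guarantee a well-populated fragment map even in
    GATC-poor stretches.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    sequences: Dict[str, str] = {}
    for chrom, length in chrom_lengths.items():
        if length < 10_000:
            raise SynthError(f"{chrom}: length {length} < 10 kb")
        arr = rng.choice(BASES, size=length)
        for pos in range(motif_spacing, length - 4, motif_spacing):
            arr[pos : pos + 4] = list("GATC")
        sequences[chrom] = "".join(arr)
    return ReferenceSet(sequences)


# ---------------------------------------------------------------------------
# contact profile and 4C library


@dataclass
class ContactProfile:
    """Contact propensity of every fragment with the bait.

    Non-peak cis fragments follow a polymer-like decay
    (1 + |d|/cis_scale_bp)^(-cis_decay_exponent) of midpoint distance d to
    the SNP; trans fragments share a small uniform background; peak
    fragments get explicit weights.  The bait fragment itself never emits a
    partner.
    """

    bait_fragment_id: int
    peaks: List[Tuple[int, float]]
    cis_decay_exponent: float = 3.0
    cis_scale_bp: float = 2_500.0
    trans_background: float = 1e-5
    cis_background_scale: float = 1.0  # 0 disables the cis background entirely

    def __post_init__(self) -> None:
        if self.cis_decay_exponent <= 0 or self.cis_scale_bp <= 0:
            raise SynthError("decay exponent and scale must be > 0")
        if self.trans_background < 0 or self.cis_background_scale < 0:
            raise SynthError("background levels must be >= 0")
        if any(w <= 0 for _, w in self.peaks):
            raise SynthError("peak weights must be > 0")

    def weights(self, fragmap: FragmentMap, bait_position: int) -> np.ndarray:
        bait_chrom = fragmap[self.bait_fragment_id].chrom
        w = np.zeros(len(fragmap))
        for frag in fragmap:
            if frag.fragment_id == self.bait_fragment_id:
                continue
            if frag.chrom == bait_chrom:
                d = abs(frag.midpoint - bait_position)
                w[frag.fragment_id] = self.cis_background_scale * (
                    1.0 + d / self.cis_scale_bp
                ) ** (-self.cis_decay_exponent)
            else:
                w[frag.fragment_id] = self.trans_background
        for fid, weight in self.peaks:
            w[fid] = weight
        w[self.bait_fragment_id] = 0.0
        return w

    def probabilities(self, fragmap: FragmentMap, bait_position: int) -> np.ndarray:
        w = self.weights(fragmap, bait_position)
        total = w.sum()
        if total <= 0:
            raise SynthError("contact profile has zero total weight")
        return w / total


def simulate_fragment_counts(
    profile: ContactProfile,
    fragmap: FragmentMap,
    bait_position: int,
    n_pairs: int,
    seed: int,
) -> np.ndarray:
    """Multinomial partner-fragment counts at library depth ``n_pairs``.

    Fast path equivalent to sampling a read library and tallying the partner
    fragment of every pair; used for depth-matched recovery statistics
    without read-level simulation.
    """
    if n_pairs < 1:
        raise SynthError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_pairs, profile.probabilities(fragmap, bait_position))


def simulate_4c_library(
    refs: ReferenceSet,
    fragmap: FragmentMap,
    bait: BaitSpec,
    profile: ContactProfile,
    n_pairs: int,
    seed: int,
    replicate_id: str = "rep1",
    read_len: int = 150,
    bait_remnant_len: int = 10,
) -> List[ReadPair]:
    """Draw a paired-end viewpoint library from the contact profile.

    Read 1 carries the reading primer, then the bait-side remnant up to the
    first-cutter site, then continues across the ligation junction into the
    partner fragment (which begins at its restriction cut).  Read 2 is a
    prefix of the partner fragment.  Deterministic per (seed, replicate_id).
    """
    if n_pairs < 1:
        raise SynthError("n_pairs must be >= 1")
    if bait.bait_fragment_id is None:
        bait.resolve(fragmap)
    rng = np.random.default_rng([seed, stable_label_seed(replicate_id)])
    p = profile.probabilities(fragmap, bait.position)
    partner_ids = rng.choice(len(p), size=n_pairs, p=p)

    bait_frag = fragmap[bait.bait_fragment_id]
    bait_seq = refs[bait_frag.chrom][bait_frag.start : bait_frag.end]
    remnant = bait_seq[-bait_remnant_len:] if bait_remnant_len > 0 else ""
    head = bait.reading_primer + remnant
    partner_budget = max(read_len - len(head), 0)

    frag_seq_cache: Dict[int, str] = {}
    pairs: List[ReadPair] = []
    for i, fid in enumerate(partner_ids):
        fid = int(fid)
        if fid not in frag_seq_cache:
            frag = fragmap[fid]
            frag_seq_cache[fid] = refs[frag.chrom][frag.start : frag.end]
        partner = frag_seq_cache[fid]
        read1 = (head + partner[:partner_budget])[:read_len]
        read2 = partner[:read_len]
        pairs.append(ReadPair(read1, read2, f"{replicate_id}_pair{i}"))
    return pairs


def write_fastq_pairs(pairs: Sequence[ReadPair], fastq1, fastq2) -> None:
    """Plain-text paired FASTQ with constant base qualities."""
    with open(fastq1, "w") as fh1, open(fastq2, "w") as fh2:
        for pair in pairs:
            fh1.write(f"@{pair.pair_id}/1\n{pair.read1}\n+\n{'I' * len(pair.read1)}\n")
            fh2.write(f"@{pair.pair_id}/2\n{pair.read2}\n+\n{'I' * len(pair.read2)}\n")


# ---------------------------------------------------------------------------
# differential expression


def simulate_de_table(
    n_genes: int,
    targets: Sequence[Tuple[str, float]],
    seed: int,
    fragmap: Optional[FragmentMap] = None,
    peak_fragment_ids: Optional[Sequence[int]] = None,
    null_chrom: str = "chr1",
    null_chrom_length: int = 1_000_000,
    gene_length: int = 2_000,
    fc_guard: float = 1.4,
) -> List[DERecord]:
    """DE table with planted down-regulated targets among null genes.

    Null genes: log2FC ~ N(0, 0.2), p ~ U(0, 1).  Target genes: log2FC ~
    N(true_fc, 0.3) rejection-sampled to stay below ``-fc_guard`` (so the
    planted effect always clears the nomination cut), p ~ U(0, 1e-5).
    Adjusted p-values are Benjamini-Hochberg over the whole table.  Each
    target is placed exactly over its peak fragment; null genes are placed
    to avoid the peak fragments.
    """
    if len(targets) > n_genes:
        raise SynthError("more targets than genes")
    rng = np.random.default_rng(seed)
    peak_ids = list(peak_fragment_ids or [])
    if targets and fragmap is not None and len(peak_ids) < len(targets):
        raise SynthError("need one peak fragment per target gene")

    rows: List[dict] = []
    peak_intervals: List[Tuple[str, int, int]] = []
    for i, (gene_id, true_fc) in enumerate(targets):
        log2fc = rng.normal(true_fc, 0.3)
        while log2fc > -fc_guard:
            log2fc = rng.normal(true_fc, 0.3)
        pval = float(rng.uniform(0, 1e-5))
        if fragmap is not None:
            frag = fragmap[peak_ids[i]]
            chrom, start, end = frag.chrom, frag.start, frag.end
            peak_intervals.append((chrom, start, end))
        else:
            chrom, start = null_chrom, 10_000 + 100_000 * i
            end = start + gene_length
        rows.append(
            dict(gene_id=gene_id, chrom=chrom, start=start, end=end,
                 strand=str(rng.choice(["+", "-"])), log2fc=float(log2fc),
                 pvalue=pval)
        )

    n_null = n_genes - len(targets)
    if fragmap is not None:
        null_chroms = fragmap.chroms()
        lengths = fragmap.chrom_lengths
    else:
        null_chroms, lengths = [null_chrom], {null_chrom: null_chrom_length}
    for i in range(n_null):
        chrom = null_chroms[int(rng.integers(len(null_chroms)))]
        limit = lengths[chrom] - gene_length
        while True:
            start = int(rng.integers(0, max(limit, 1)))
            end = start + gene_length
            clash = any(
                chrom == pc and start < pe and pc_start < end
                for pc, pc_start, pe in peak_intervals
            )
            if not clash:
                break
        rows.append(
            dict(gene_id=f"NULL{i:04d}", chrom=chrom, start=start, end=end,
                 strand=str(rng.choice(["+", "-"])),
                 log2fc=float(rng.normal(0.0, 0.2)),
                 pvalue=float(rng.uniform(0.0, 1.0)))
        )

    padj = benjamini_hochberg([r["pvalue"] for r in rows])
    return [
        DERecord(padj=float(adj), **row) for row, adj in zip(rows, padj)
    ]


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct_table(
    curves: Mapping[str, Tuple[float, float]],
    dilutions: Sequence[float],
    template_amounts: Mapping[str, float],
    noise_sd: float = 0.1,
    seed: int = 0,
    n_curve_reps: int = 3,
) -> pd.DataFrame:
    """Ct table with dilution-series rows plus sample rows.

    ``curves`` maps primer_pair_id -> (true efficiency E, intercept);
    Ct = intercept - log(template) / log(1 + E) + N(0, noise_sd^2), so a
    noise-free series is exactly collinear in log10(dilution) with slope
    -1/log10(1+E).  ``template_amounts`` maps sample_id -> relative template
    amount applied to every primer pair.
    """
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    for pid, (eff, intercept) in curves.items():
        if eff <= 0:
            raise SynthError(f"{pid}: efficiency must be > 0")
        log_base = math.log10(1.0 + eff)
        for rep in range(1, n_curve_reps + 1):
            for dil in dilutions:
                if dil <= 0:
                    raise SynthError("dilutions must be > 0")
                ct = intercept - math.log10(dil) / log_base
                ct += float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                rows.append(
                    dict(primer_pair_id=pid, sample_id="std", replicate=rep,
                         dilution=dil, ct=ct)
                )
        for sample_id, amount in template_amounts.items():
            if amount <= 0:
                raise SynthError("template amounts must be > 0")
            ct = intercept - math.log10(amount) / log_base
            ct += float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            rows.append(
                dict(primer_pair_id=pid, sample_id=sample_id, replicate=1,
                     dilution=np.nan, ct=ct)
            )
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# ---------------------------------------------------------------------------
# motif fixture


def make_sox_like_pwm(name: str = "SOX4like") -> PWMModel:
    """A synthetic SOX-family-like PWM with consensus AACAAT.

    Strongly informative columns (count 18 for the consensus base, 2 spread
    over the rest) so that breaking the consensus at one position costs a
    clear log-odds margin.
    """
    consensus = "AACAAT"
    counts = np.full((4, len(consensus)), 2.0 / 3.0)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for j, base in enumerate(consensus):
        counts[:, j] = 2.0 / 3.0
        counts[base_index[base], j] = 18.0
    return PWMModel(name=name, counts=counts)


# ---------------------------------------------------------------------------
# full scenario


@dataclass
class SimTruth:
    """Ground truth of a generated scenario."""

    peak_fragment_ids: List[int]
    target_gene_ids: List[str]
    true_efficiencies: Dict[str, float]
    motif_delta_sign: int  # sign of (alt - ref) best motif score
    bait_chrom: str
    bait_position: int
    bait_fragment_id: int


@dataclass
class Scenario:
    """Generated scenario: file paths plus in-memory objects and truth."""

    name: str
    seed: int
    out_dir: Path
    refs: ReferenceSet
    fragmap: FragmentMap
    bait: BaitSpec
    profile: ContactProfile
    truth: SimTruth
    paths: Dict[str, object]
    de_records: List[DERecord]


def _fragment_near(
    fragmap: FragmentMap, chrom: str, position: int, min_len: int = 60
):
    """The fragment at ``position``, or the next one at least ``min_len`` long."""
    frag = fragmap.fragment_at(chrom, position)
    frags = fragmap.fragments_for(chrom)
    idx = frags.index(frag)
    while frags[idx].length < min_len and idx + 1 < len(frags):
        idx += 1
    return frags[idx]


DEFAULT_PRIMER_EFFICIENCIES = {
    "pp_promoter": 0.95,
    "pp_anchor": 1.00,
    "pp_upstream": 1.05,
    "pp_failqc": 0.85,
}


def make_scenario(
    out_dir,
    name: str = "default",
    seed: int = 42,
    n_pairs: int = 100_000,
    n_genes: int = 200,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    peak_weight_multiplier: float = 50.0,
    primer_len: int = 20,
) -> Scenario:
    """Generate every pipeline input with known ground truth.

    Default: chr1 = 1 Mb with the bait at 300 kb, chr2 = 0.5 Mb; two cis
    peaks 50 kb and 400 kb from the bait and one trans peak on chr2; each
    peak weighted ``peak_weight_multiplier`` times the cis background level
    at 50 kb (so every peak is at least that multiple of its local
    background); two replicate libraries of ``n_pairs`` pairs; 200 genes
    with 3 planted targets over the peak fragments; four qPCR primer pairs
    with true efficiencies {0.95, 1.00, 1.05, 0.85} of which the last must
    fail the 90-110% QC window; and a SOX-like PFM whose consensus is
    completed by the alternate (risk) allele.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom_lengths = dict(chrom_lengths or {"chr1": 1_000_000, "chr2": 500_000})
    bait_chrom = next(iter(chrom_lengths))

    refs = make_genome(seed, chrom_lengths)
    fragmap = digest_genome(refs, DPNII)

    bait_frag = _fragment_near(fragmap, bait_chrom, 300_000, min_len=primer_len + 40)
    bait_position = int(bait_frag.midpoint)
    bait_seq = refs[bait_chrom][bait_frag.start : bait_frag.end]
    # reading primer: bait-fragment sequence just upstream of the fragment's
    # 3' restriction site, leaving a 10 bp remnant before the junction
    primer = bait_seq[-(primer_len + 10) : -10]
    bait = BaitSpec(
        chrom=bait_chrom,
        position=bait_position,
        reading_primer=primer,
        exclusion_radius_fragments=2,
    ).resolve(fragmap)

    other_chroms = [c for c in chrom_lengths if c != bait_chrom]
    trans_chrom = other_chroms[0]
    peak_positions = [
        (bait_chrom, bait_position + 50_000),
        (bait_chrom, bait_position + 400_000),
        (trans_chrom, chrom_lengths[trans_chrom] // 2),
    ]
    peak_frags = [
        _fragment_near(fragmap, chrom, pos, min_len=60)
        for chrom, pos in peak_positions
    ]
    profile_probe = ContactProfile(bait.bait_fragment_id, peaks=[])
    ref_background = (
        1.0 + 50_000.0 / profile_probe.cis_scale_bp
    ) ** (-profile_probe.cis_decay_exponent)
    peak_weight = peak_weight_multiplier * ref_background
    profile = ContactProfile(
        bait_fragment_id=bait.bait_fragment_id,
        peaks=[(f.fragment_id, peak_weight) for f in peak_frags],
    )

    paths: Dict[str, object] = {}
    fasta = out_dir / "genome.fa"
    refs.to_fasta(fasta)
    paths["genome_fasta"] = fasta
    bed = out_dir / "fragments.bed"
    write_fragment_map(fragmap, bed)
    paths["fragment_map_bed"] = bed

    fastqs: Dict[str, Tuple[Path, Path]] = {}
    for rep in ("rep1", "rep2"):
        pairs = simulate_4c_library(
            refs, fragmap, bait, profile, n_pairs, seed, replicate_id=rep
        )
        fq1 = out_dir / f"{rep}_R1.fastq"
        fq2 = out_dir / f"{rep}_R2.fastq"
        write_fastq_pairs(pairs, fq1, fq2)
        fastqs[rep] = (fq1, fq2)
    paths["fastq"] = fastqs

    target_ids = [f"TARGET{i + 1}" for i in range(len(peak_frags))]
    de_records = simulate_de_table(
        n_genes=n_genes,
        targets=[(gid, -2.0) for gid in target_ids],
        seed=seed + 1,
        fragmap=fragmap,
        peak_fragment_ids=[f.fragment_id for f in peak_frags],
    )
    de_path = out_dir / "de_table.tsv"
    write_de_table(de_records, de_path)
    paths["de_table"] = de_path

    curve_truth = {
        pid: (eff, 20.0) for pid, eff in DEFAULT_PRIMER_EFFICIENCIES.items()
    }
    ct = simulate_ct_table(
        curves=curve_truth,
        dilutions=[1.0, 0.1, 0.01, 0.001, 0.0001],
        template_amounts={"bio1": 1.0, "bio2": 0.9, "bio3": 1.1},
        noise_sd=0.05,
        seed=seed + 2,
    )
    ct_path = out_dir / "ct_table.tsv"
    ct.to_csv(ct_path, sep="\t", index=False, na_rep="NA")
    paths["ct_table"] = ct_path

    pwm = make_sox_like_pwm()
    pfm_path = out_dir / "sox_like.pfm"
    write_jaspar_pfm(pwm, pfm_path)
    paths["pfm"] = pfm_path

    truth = SimTruth(
        peak_fragment_ids=[f.fragment_id for f in peak_frags],
        target_gene_ids=target_ids,
        true_efficiencies=DEFAULT_PRIMER_EFFICIENCIES.copy(),
        motif_delta_sign=1,
        bait_chrom=bait_chrom,
        bait_position=bait_position,
        bait_fragment_id=bait.bait_fragment_id,
    )
    manifest = {
        "name": name,
        "seed": seed,
        "n_pairs": n_pairs,
        "bait": {
            "chrom": bait.chrom,
            "position": bait.position,
            "reading_primer": bait.reading_primer,
            "fragment_id": bait.bait_fragment_id,
            "exclusion_radius_fragments": bait.exclusion_radius_fragments,
        },
        "paths": {
            "genome_fasta": fasta.name,
            "fragment_map_bed": bed.name,
            "de_table": de_path.name,
            "ct_table": ct_path.name,
            "pfm": pfm_path.name,
            "fastq": {
                rep: [fq1.name, fq2.name] for rep, (fq1, fq2) in fastqs.items()
            },
        },
        "truth": {
            "peak_fragment_ids": truth.peak_fragment_ids,
            "target_gene_ids": truth.target_gene_ids,
            "true_efficiencies": truth.true_efficiencies,
            "motif_delta_sign": truth.motif_delta_sign,
        },
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["manifest"] = manifest_path

    return Scenario(
        name=name, seed=seed, out_dir=out_dir, refs=refs, fragmap=fragmap,
        bait=bait, profile=profile, truth=truth, paths=paths,
        de_records=de_records,
    )
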