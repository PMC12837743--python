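"""Viewpoint 4C-seq read processing and interaction calling.

The assay circularizes the bait restriction fragment with whichever fragment
it contacted; inverse PCR with a bait-anchored reading primer then reads
across the ligation junction into the partner fragment.  Processing is:

1. demultiplex paired reads on the reading-primer prefix and trim it;
2. digest the trimmed capture in silico with the restriction enzymes, so the
   bait remnant and the partner piece separate at the junction;
3. place each piece on the reference (toy exact matcher, or SAM from an
   external aligner);
4. accumulate placements per restriction fragment and scale to reads per
   million (RPM);
5. call interacting fragments: RPM above threshold in every biological
   replicate, outside the bait exclusion zone, flagged cis/trans.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from ._util import hamming_prefix, revcomp
from .fragmap import BaitSpec, EnzymeSpec, FragmentMap, ReferenceSet, find_cut_positions

logger = logging.getLogger(__name__)


class FourCError(ValueError):
    """4C pipeline input or state error."""


@dataclass(frozen=True)
class ReadPair:
    read1: str
    read2: str
    pair_id: str

    def __post_init__(self) -> None:
        if not self.read1 or not self.read2:
            raise FourCError(f"pair {self.pair_id}: empty read")


@dataclass(frozen=True)
class CapturedFragmentSeq:
    """Primer-trimmed capture sequence and which mate carried the primer."""

    pair_id: str
    sequence: str
    origin: int  # 1 or 2


@dataclass
class DemuxStats:
    kept: int = 0
    no_primer: int = 0
    both_primer: int = 0
    empty_after_trim: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.no_primer + self.both_primer + self.empty_after_trim


def demultiplex_and_trim(
    pairs: Iterable[ReadPair],
    bait: BaitSpec,
    max_mismatch: int = 0,
) -> Tuple[List[CapturedFragmentSeq], DemuxStats]:
    """Split read pairs on the reading primer and trim it.

    A pair is kept iff exactly one mate begins with the reading primer
    (Hamming distance <= ``max_mismatch`` over the primer length, anchored at
    the read start).  The primer prefix is removed from that mate and the
    remainder is the capture; pairs where neither or both mates match are
    discarded and counted.
    """
    primer = bait.reading_primer
    stats = DemuxStats()
    captures: List[CapturedFragmentSeq] = []
    for pair in pairs:
        m1 = hamming_prefix(pair.read1.upper(), primer) <= max_mismatch
        m2 = hamming_prefix(pair.read2.upper(), primer) <= max_mismatch
        if m1 and m2:
            stats.both_primer += 1
            continue
        if not m1 and not m2:
            stats.no_primer += 1
            continue
        read, origin = (pair.read1, 1) if m1 else (pair.read2, 2)
        remainder = read.upper()[len(primer) :]
        if not remainder:
            stats.empty_after_trim += 1
            continue
        captures.append(CapturedFragmentSeq(pair.pair_id, remainder, origin))
        stats.kept += 1
    logger.info(
        "demultiplex: kept %d / %d pairs (%d no primer, %d both mates, %d empty)",
        stats.kept, stats.total, stats.no_primer, stats.both_primer,
        stats.empty_after_trim,
    )
    return captures, stats


def digest_read(
    sequence: str | CapturedFragmentSeq,
    enzymes: Sequence[EnzymeSpec],
    min_len: int = 20,
) -> List[str]:
    """Split a capture at every enzyme cut position; drop pieces < min_len."""
    if min_len < 1:
        raise FourCError("min_len must be >= 1")
    seq = sequence.sequence if isinstance(sequence, CapturedFragmentSeq) else sequence
    seq = seq.upper()
    cuts: set[int] = set()
    for enzyme in enzymes:
        cuts.update(find_cut_positions(seq, enzyme))
    bounds = sorted(c for c in cuts if 0 < c < len(seq))
    pieces = []
    prev = 0
    for cut in bounds + [len(seq)]:
        piece = seq[prev:cut]
        if len(piece) >= min_len:
            pieces.append(piece)
        prev = cut
    return pieces


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int  # leftmost aligned base, 0-based
    strand: str  # '+' or '-'
    length: int

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5'-most aligned base of the query."""
        return self.start if self.strand == "+" else self.start + self.length - 1


@dataclass
class PlacementStats:
    placed: int = 0
    ambiguous: int = 0
    unplaced: int = 0


def _occurrences(genome_seq: str, query: str, limit: int) -> List[int]:
    """Start positions of ``query`` in ``genome_seq`` (at most ``limit``)."""
    out: List[int] = []
    i = genome_seq.find(query)
    while i != -1:
        out.append(i)
        if len(out) >= limit:
            break
        i = genome_seq.find(query, i + 1)
    return out


def place_sequences(
    seqs: Iterable[str],
    refs: ReferenceSet,
    min_seed_len: int = 15,
    _cache: Optional[Dict[str, Optional[Placement]]] = None,
) -> Tuple[List[Placement], PlacementStats]:
    """Place sequences that occur exactly once in the genome (both strands).

    Sequences with two or more occurrences (either orientation) are discarded
    as ambiguous; absent or too-short sequences are discarded as unplaced.
    Results are memoized per distinct sequence (``_cache`` may be shared
    across calls to amortize repeated captures).
    """
    stats = PlacementStats()
    placements: List[Placement] = []
    cache = _cache if _cache is not None else {}
    for seq in seqs:
        seq = seq.upper()
        if seq in cache:
            hit = cache[seq]
        else:
            hit = _place_one(seq, refs, min_seed_len)
            cache[seq] = hit
        if hit is None:
            stats.unplaced += 1
        elif hit == "ambiguous":
            stats.ambiguous += 1
        else:
            placements.append(hit)
            stats.placed += 1
    return placements, stats


def _place_one(seq: str, refs: ReferenceSet, min_seed_len: int):
    if len(seq) < min_seed_len:
        return None
    rc = revcomp(seq)
    hits: List[Placement] = []
    for chrom, genome_seq in refs.sequences.items():
        for pos in _occurrences(genome_seq, seq, limit=2):
            hits.append(Placement(chrom, pos, "+", len(seq)))
            if len(hits) > 1:
                return "ambiguous"
        # a palindromic sequence matches identically on both strands at the
        # same locus; count that as one placement, not an ambiguity
        if rc != seq:
            for pos in _occurrences(genome_seq, rc, limit=2):
                hits.append(Placement(chrom, pos, "-", len(seq)))
                if len(hits) > 1:
                    return "ambiguous"
    return hits[0] if hits else None


def load_placements_sam(path, refs: ReferenceSet, min_mapq: int = 1) -> List[Placement]:
    """Primary mapped SAM records as placements (1-based SAM -> 0-based)."""
    placements: List[Placement] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in refs:
                raise FourCError(f"SAM reference {name!r} not in reference set")
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.reference_name not in refs:
                raise FourCError(f"SAM reference {rec.reference_name!r} unknown")
            length = rec.reference_length or rec.query_length or 1
            placements.append(
                Placement(
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    length,
                )
            )
    return placements


@dataclass
class FragmentCoverage:
    """Per-fragment read counts and RPM for one replicate library."""

    replicate_id: str
    counts: Dict[int, int]
    rpm: Dict[int, float]
    total_assigned: int


def coverage_per_fragment(
    placements: Sequence[Placement],
    fragmap: FragmentMap,
    replicate_id: str = "rep1",
) -> FragmentCoverage:
    """Assign each placement to the fragment holding its 5'-most base.

    RPM scales counts by 10^6 / total assigned placements, so RPM sums to
    10^6 per library.
    """
    counts: Counter = Counter()
    for pl in placements:
        frag = fragmap.fragment_at(pl.chrom, pl.five_prime)
        counts[frag.fragment_id] += 1
    total = sum(counts.values())
    if total == 0:
        raise FourCError("no placements assigned; RPM undefined")
    rpm = {fid: c / total * 1e6 for fid, c in counts.items()}
    return FragmentCoverage(replicate_id, dict(counts), rpm, total)


@dataclass
class InteractionCall:
    fragment_id: int
    chrom: str
    start: int
    end: int
    rpm_per_replicate: List[float]
    is_cis: bool
    distance_to_bait: Optional[float]  # signed, call midpoint - SNP; cis only
    reproducible: bool = True

    @property
    def min_rpm(self) -> float:
        return min(self.rpm_per_replicate)


def call_interactions(
    covs: Sequence[FragmentCoverage],
    bait: BaitSpec,
    fragmap: FragmentMap,
    rpm_threshold: float = 50.0,
) -> List[InteractionCall]:
    """Fragments with RPM above threshold in *every* replicate.

    The bait fragment and fragments within ``exclusion_radius_fragments`` of
    it (same chromosome) are excluded: they carry self-ligation/undigested
    signal, not genuine contacts.
    """
    if len(covs) < 2:
        raise FourCError("interaction calling requires >= 2 replicates")
    if bait.bait_fragment_id is None:
        bait = bait.resolve(fragmap)
    bait_frag = fragmap[bait.bait_fragment_id]
    excluded = set()
    for frag in fragmap.fragments_for(bait.chrom):
        if abs(frag.fragment_id - bait.bait_fragment_id) <= bait.exclusion_radius_fragments:
            excluded.add(frag.fragment_id)

    candidate_ids = set(covs[0].rpm)
    for cov in covs[1:]:
        candidate_ids &= set(cov.rpm)
    calls: List[InteractionCall] = []
    for fid in sorted(candidate_ids):
        if fid in excluded:
            continue
        rpms = [cov.rpm[fid] for cov in covs]
        if not all(r > rpm_threshold for r in rpms):
            continue
        frag = fragmap[fid]
        is_cis = frag.chrom == bait_frag.chrom
        distance = frag.midpoint - bait.position if is_cis else None
        calls.append(
            InteractionCall(
                fragment_id=fid,
                chrom=frag.chrom,
                start=frag.start,
                end=frag.end,
                rpm_per_replicate=rpms,
                is_cis=is_cis,
                distance_to_bait=distance,
            )
        )
    return calls


@dataclass(frozen=True)
class CisTransSummary:
    n_total: int
    n_cis: int
    n_trans: int
    pct_cis: float
    pct_trans: float


def summarize_cis_trans(calls: Sequence[InteractionCall]) -> CisTransSummary:
    """Counts and percentages (2 decimals) of cis vs trans calls."""
    if not calls:
        raise FourCError("no interaction calls to summarize")
    n_cis = sum(1 for c in calls if c.is_cis)
    n_total = len(calls)
    n_trans = n_total - n_cis
    return CisTransSummary(
        n_total=n_total,
        n_cis=n_cis,
        n_trans=n_trans,
        pct_cis=round(100.0 * n_cis / n_total, 2),
        pct_trans=round(100.0 * n_trans / n_total, 2),
    )


def export_tracks(
    cov: FragmentCoverage,
    calls: Sequence[InteractionCall],
    fragmap: FragmentMap,
    bedgraph_path,
    bed_path,
) -> None:
    """Write an RPM bedGraph for one replicate and a BED of calls.

    BED score is the minimum across-replicate RPM capped at 1000 (UCSC score
    range convention).
    """
    with open(bedgraph_path, "w") as fh:
        fh.write(f'track type=bedGraph name="RPM {cov.replicate_id}"\n')
        for frag in fragmap:
            if frag.fragment_id in cov.rpm:
                fh.write(
                    f"{frag.chrom}\t{frag.start}\t{frag.end}\t"
                    f"{cov.rpm[frag.fragment_id]:.6f}\n"
                )
    with open(bed_path, "w") as fh:
        fh.write("# interaction calls: chrom start end fragment_id score strand\n")
        for call in calls:
            score = min(call.min_rpm, 1000.0)
            fh.write(
                f"{call.chrom}\t{call.start}\t{call.end}\t{call.fragment_id}\t"
                f"{score:.1f}\t.\n"
            )


def read_bedgraph(path) -> Dict[Tuple[str, int, int], float]:
    """Read a bedGraph back as {(chrom, start, end): value}."""
    out: Dict[Tuple[str, int, int], float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.split("\t")
            out[(chrom, int(start), int(end))] = float(value)
    return out


def write_calls(calls: Sequence[InteractionCall], path) -> None:
    """Call table TSV: fragment_id, coords, per-replicate RPM, cis flag, distance."""
    n_reps = max((len(c.rpm_per_replicate) for c in calls), default=2)
    rpm_cols = [f"rpm_rep{i + 1}" for i in range(n_reps)]
    with open(path, "w") as fh:
        fh.write(
            "fragment_id\tchrom\tstart\tend\t" + "\t".join(rpm_cols)
            + "\tis_cis\tdistance_to_bait\n"
        )
        for c in calls:
            rpms = "\t".join(f"{r:.6f}" for r in c.rpm_per_replicate)
            dist = "NA" if c.distance_to_bait is None else f"{c.distance_to_bait:.1f}"
            fh.write(
                f"{c.fragment_id}\t{c.chrom}\t{c.start}\t{c.end}\t{rpms}\t"
                f"{int(c.is_cis)}\t{dist}\n"
            )


def read_calls(path) -> List[InteractionCall]:
    calls: List[InteractionCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rpm_idx = [i for i, h in enumerate(header) if h.startswith("rpm_rep")]
        col = {h: i for i, h in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            dist = f[col["distance_to_bait"]]
            calls.append(
                InteractionCall(
                    fragment_id=int(f[col["fragment_id"]]),
                    chrom=f[col["chrom"]],
                    start=int(f[col["start"]]),
                    end=int(f[col["end"]]),
                    rpm_per_replicate=[float(f[i]) for i in rpm_idx],
                    is_cis=bool(int(f[col["is_cis"]])),
                    distance_to_bait=None if dist == "NA" else float(dist),
                )
            )
    return calls


def read_fastq_pairs(fastq1, fastq2) -> List[ReadPair]:
    """Load mate-paired FASTQ files (plain or gzip) as ReadPairs."""
    pairs: List[ReadPair] = []
    with pysam.FastxFile(str(fastq1)) as fh1, pysam.FastxFile(str(fastq2)) as fh2:
        for rec1, rec2 in zip(fh1, fh2):
            pairs.append(ReadPair(rec1.sequence, rec2.sequence, rec1.name))
    return pairs


def process_read_pairs(
    pairs: Iterable[ReadPair],
    refs: ReferenceSet,
    bait: BaitSpec,
    fragmap: FragmentMap,
    enzymes: Sequence[EnzymeSpec],
    replicate_id: str = "rep1",
    max_mismatch: int = 0,
    min_fragment_len: int = 20,
) -> FragmentCoverage:
    """Full per-replicate chain: demultiplex -> digest -> place -> coverage.

    Digestion and placement are memoized per distinct capture sequence, so
    deep libraries over a small genome stay fast.
    """
    captures, _ = demultiplex_and_trim(pairs, bait, max_mismatch=max_mismatch)
    piece_cache: Dict[str, List[Placement]] = {}
    place_cache: Dict[str, Optional[Placement]] = {}
    placements: List[Placement] = []
    for cap in captures:
        if cap.sequence not in piece_cache:
            pieces = digest_read(cap.sequence, enzymes, min_len=min_fragment_len)
            placed, _ = place_sequences(pieces, refs, _cache=place_cache)
            piece_cache[cap.sequence] = placed
        placements.extend(piece_cache[cap.sequence])
    return coverage_per_fragment(placements, fragmap, replicate_id)


def process_fastq(
    fastq1,
    fastq2,
    refs: ReferenceSet,
    bait: BaitSpec,
    fragmap: FragmentMap,
    enzymes: Sequence[EnzymeSpec],
    replicate_id: str = "rep1",
    **kwargs,
) -> FragmentCoverage:
    return process_read_pairs(
        read_fastq_pairs(fastq1, fastq2),
        refs, bait, fragmap, enzymes, replicate_id=replicate_id, **kwargs,
    )
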