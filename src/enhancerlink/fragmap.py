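"""Restriction-fragment maps of reference sequences.

A 4C/3C viewpoint experiment is anchored on the restriction fragment that
contains the SNP of interest; every other fragment of the genome is a
potential interaction partner.  This module digests reference sequences in
silico with a restriction enzyme, producing an ordered fragment map that
tiles each chromosome exactly, and resolves the bait (viewpoint) fragment.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence

from Bio import SeqIO

from ._util import DNA_ALPHABET

logger = logging.getLogger(__name__)


class FragmentMapError(ValueError):
    """Malformed fragment map or digestion input."""


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif plus cut offset.

    ``cut_offset`` is the distance in bp from the motif start to the cut
    position (DpnII cuts ^GATC -> offset 0; CviQI cuts G^TAC -> offset 1).
    """

    name: str
    recognition_motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.recognition_motif.upper()
        object.__setattr__(self, "recognition_motif", motif)
        if len(motif) < 4:
            raise FragmentMapError(f"{self.name}: motif shorter than 4 bp")
        if not set(motif) <= set("ACGT"):
            raise FragmentMapError(
                f"{self.name}: motif {motif!r} contains non-ACGT characters"
            )
        if not 0 <= self.cut_offset <= len(motif):
            raise FragmentMapError(
                f"{self.name}: cut offset {self.cut_offset} outside motif"
            )


#: DpnII cuts ^GATC (blunt-end offset 0 relative to motif start).
DPNII = EnzymeSpec("DpnII", "GATC", 0)
#: CviQI cuts G^TAC.
CVIQI = EnzymeSpec("CviQI", "GTAC", 1)

BUILTIN_ENZYMES: Dict[str, EnzymeSpec] = {e.name: e for e in (DPNII, CVIQI)}


class ReferenceSet:
    """Named DNA sequences (uppercased, alphabet A/C/G/T/N)."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise FragmentMapError("reference set is empty")
        self.sequences: Dict[str, str] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            if not seq:
                raise FragmentMapError(f"reference {name!r} has empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FragmentMapError(
                    f"reference {name!r} contains invalid characters {sorted(bad)}"
                )
            if name in self.sequences:
                raise FragmentMapError(f"duplicate reference name {name!r}")
            self.sequences[name] = seq

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def names(self) -> List[str]:
        return list(self.sequences)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise FragmentMapError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    fragment_id: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FragmentMapError(
                f"fragment {self.fragment_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def find_cut_positions(sequence: str, enzyme: EnzymeSpec) -> List[int]:
    """All cut positions of ``enzyme`` in ``sequence``.

    Overlapping motif occurrences each contribute a cut.  N never matches.
    """
    seq = sequence.upper()
    motif = enzyme.recognition_motif
    cuts: List[int] = []
    i = seq.find(motif)
    while i != -1:
        cuts.append(i + enzyme.cut_offset)
        i = seq.find(motif, i + 1)
    return cuts


class FragmentMap:
    """Ordered restriction fragments tiling each reference exactly."""

    def __init__(self, fragments: Sequence[Fragment], chrom_lengths: Mapping[str, int]):
        self.fragments: List[Fragment] = list(fragments)
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)
        self._by_chrom: Dict[str, List[Fragment]] = {}
        for frag in self.fragments:
            self._by_chrom.setdefault(frag.chrom, []).append(frag)
        self._starts: Dict[str, List[int]] = {}
        for chrom, frags in self._by_chrom.items():
            self._starts[chrom] = [f.start for f in frags]
        self._by_id: Dict[int, Fragment] = {f.fragment_id: f for f in self.fragments}
        self._validate()

    def _validate(self) -> None:
        ids = [f.fragment_id for f in self.fragments]
        if ids != sorted(ids) or len(set(ids)) != len(ids):
            raise FragmentMapError("fragment ids are not unique and ordered")
        for chrom, frags in self._by_chrom.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise FragmentMapError(f"no length recorded for {chrom!r}")
            if frags[0].start != 0 or frags[-1].end != length:
                raise FragmentMapError(f"{chrom}: fragments do not span [0, {length})")
            for prev, cur in zip(frags, frags[1:]):
                if prev.end != cur.start:
                    raise FragmentMapError(
                        f"{chrom}: fragments {prev.fragment_id} and "
                        f"{cur.fragment_id} do not abut"
                    )

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def __getitem__(self, fragment_id: int) -> Fragment:
        try:
            return self._by_id[fragment_id]
        except KeyError:
            raise FragmentMapError(f"no fragment with id {fragment_id}") from None

    def chroms(self) -> List[str]:
        return list(self._by_chrom)

    def fragments_for(self, chrom: str) -> List[Fragment]:
        return self._by_chrom[chrom]

    def fragment_at(self, chrom: str, position: int) -> Fragment:
        """The unique fragment with start <= position < end."""
        if chrom not in self._by_chrom:
            raise FragmentMapError(f"chromosome {chrom!r} not in fragment map")
        if not 0 <= position < self.chrom_lengths[chrom]:
            raise FragmentMapError(
                f"position {position} outside {chrom} "
                f"[0, {self.chrom_lengths[chrom]})"
            )
        idx = bisect.bisect_right(self._starts[chrom], position) - 1
        return self._by_chrom[chrom][idx]


def digest_genome(
    refs: ReferenceSet, enzymes: EnzymeSpec | Iterable[EnzymeSpec]
) -> FragmentMap:
    """Digest every reference with one enzyme (or several jointly).

    Cut positions are all exact motif occurrences (overlaps included) offset
    by the enzyme's cut offset; fragments are the intervals between
    consecutive cuts plus the chromosome ends.  Zero-length fragments
    (a cut at position 0 or at the chromosome end) are dropped.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    enzymes = list(enzymes)
    if not enzymes:
        raise FragmentMapError("no enzymes given")
    fragments: List[Fragment] = []
    next_id = 0
    for chrom, seq in refs.sequences.items():
        cuts: set[int] = set()
        for enzyme in enzymes:
            cuts.update(find_cut_positions(seq, enzyme))
        bounds = sorted(cuts | {0, len(seq)})
        for start, end in zip(bounds, bounds[1:]):
            if end > start:
                fragments.append(Fragment(chrom, start, end, next_id))
                next_id += 1
    return FragmentMap(fragments, refs.lengths)


@dataclass
class BaitSpec:
    """The 4C viewpoint: SNP position plus the bait-anchored reading primer."""

    chrom: str
    position: int
    reading_primer: str
    bait_fragment_id: int | None = None
    exclusion_radius_fragments: int = 2

    def __post_init__(self) -> None:
        self.reading_primer = self.reading_primer.upper()
        if len(self.reading_primer) < 10:
            raise FragmentMapError("reading primer shorter than 10 bp")

    def resolve(self, fragmap: FragmentMap) -> "BaitSpec":
        """Fill in ``bait_fragment_id`` from the fragment map."""
        self.bait_fragment_id = locate_bait(fragmap, self.chrom, self.position)
        return self


def locate_bait(fragmap: FragmentMap, chrom: str, position: int) -> int:
    """Fragment id of the fragment containing ``position``."""
    return fragmap.fragment_at(chrom, position).fragment_id


def write_fragment_map(fragmap: FragmentMap, path) -> None:
    """BED4 output: chrom, start, end, fragment_id."""
    with open(path, "w") as fh:
        for frag in fragmap:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.fragment_id}\n")


def read_fragment_map(path) -> FragmentMap:
    """Read a BED4 fragment map; unsorted rows are re-sorted with a warning."""
    rows: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FragmentMapError(f"{path}: line {lineno}: expected 4 columns")
            try:
                chrom = fields[0]
                start, end, frag_id = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise FragmentMapError(f"{path}: line {lineno}: {exc}") from None
            if start >= end:
                raise FragmentMapError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            rows.append((chrom, start, end, frag_id))
    if not rows:
        raise FragmentMapError(f"{path}: no fragments")
    in_order = all(a[3] < b[3] for a, b in zip(rows, rows[1:]))
    if not in_order:
        logger.warning("%s: fragment rows out of order; re-sorting by id", path)
        rows.sort(key=lambda r: r[3])
    chrom_lengths: Dict[str, int] = {}
    for chrom, _start, end, _fid in rows:
        chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end)
    fragments = [Fragment(c, s, e, f) for c, s, e, f in rows]
    return FragmentMap(fragments, chrom_lengths)
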