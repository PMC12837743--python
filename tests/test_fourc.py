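"""Read demultiplexing, in-silico digestion, placement, coverage and calls."""

import math

import pytest

from enhancerlink.fragmap import (
    BaitSpec,
    CVIQI,
    DPNII,
    ReferenceSet,
    digest_genome,
)
from enhancerlink.fourc import (
    CisTransSummary,
    FourCError,
    FragmentCoverage,
    InteractionCall,
    Placement,
    ReadPair,
    call_interactions,
    coverage_per_fragment,
    demultiplex_and_trim,
    digest_read,
    export_tracks,
    load_placements_sam,
    place_sequences,
    read_bedgraph,
    read_calls,
    summarize_cis_trans,
    write_calls,
)

PRIMER = "ACGTACGTCC"  # 10 bp minimum reading primer
BAIT = BaitSpec("c1", 0, PRIMER)


def _demux(read1, read2, max_mismatch=0):
    caps, stats = demultiplex_and_trim(
        [ReadPair(read1, read2, "p1")], BAIT, max_mismatch=max_mismatch
    )
    return caps, stats


class TestDemultiplex:
    def test_exact_prefix_is_kept_and_trimmed(self):
        caps, stats = _demux(PRIMER + "TTTT", "GGGGGGGG")
        assert [c.sequence for c in caps] == ["TTTT"]
        assert caps[0].origin == 1 and stats.kept == 1

    def test_primer_on_mate2(self):
        caps, _ = _demux("GGGGGGGG", PRIMER + "AAAA")
        assert [c.sequence for c in caps] == ["AAAA"]
        assert caps[0].origin == 2

    def test_internal_primer_is_not_a_match(self):
        caps, stats = _demux("GG" + PRIMER + "TT", "GGGGGGGG")
        assert caps == [] and stats.no_primer == 1

    def test_both_mates_matching_discards_pair(self):
        caps, stats = _demux(PRIMER + "TT", PRIMER + "AA")
        assert caps == [] and stats.both_primer == 1

    def test_hamming_tolerance(self):
        one_off = "ACGAACGTCC"  # 1 mismatch vs PRIMER
        caps, _ = _demux(one_off + "TTTT", "GGGGGGGG", max_mismatch=1)
        assert [c.sequence for c in caps] == ["TTTT"]
        caps, stats = _demux(one_off + "TTTT", "GGGGGGGG", max_mismatch=0)
        assert caps == [] and stats.no_primer == 1


class TestDigestRead:
    @pytest.mark.parametrize(
        "seq,enzymes,min_len,expected",
        [
            ("TTGATCAA", [DPNII], 2, ["TT", "GATCAA"]),
            ("TTTT", [DPNII], 2, ["TTTT"]),
            ("TGATCA", [DPNII], 3, ["GATCA"]),  # leading T dropped by min_len
            ("AAGATCAAGTACAA", [DPNII, CVIQI], 2, ["AA", "GATCAAG", "TACAA"]),
        ],
    )
    def test_examples(self, seq, enzymes, min_len, expected):
        assert digest_read(seq, enzymes, min_len=min_len) == expected

    def test_min_len_must_be_positive(self):
        with pytest.raises(FourCError):
            digest_read("ACGT", [DPNII], min_len=0)


class TestPlacement:
    def test_unique_forward_match(self, small_refs):
        placements, stats = place_sequences(
            ["CCGGATCTTACGTACC"], small_refs, min_seed_len=10
        )
        assert placements == [Placement("c1", 2, "+", 16)]
        assert stats.placed == 1

    def test_reverse_complement_match_on_minus_strand(self, small_refs):
        # revcomp of c1[2:18]
        from enhancerlink._util import revcomp

        seq = revcomp(small_refs["c1"][2:18])
        placements, _ = place_sequences([seq], small_refs, min_seed_len=10)
        assert placements == [Placement("c1", 2, "-", 16)]
        assert placements[0].five_prime == 17

    def test_ambiguous_sequence_discarded(self):
        refs = ReferenceSet({"c1": "ACGTACGTAAAAAACGTACGTA"})
        placements, stats = place_sequences(["ACGTACGTA"], refs, min_seed_len=5)
        assert placements == [] and stats.ambiguous == 1

    def test_absent_sequence_discarded(self, small_refs):
        placements, stats = place_sequences(
            ["TTTTTTTTTTTTTTTT"], small_refs, min_seed_len=10
        )
        assert placements == [] and stats.unplaced == 1


class TestSamIngestion:
    def _write_sam(self, path, records):
        header = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:c1\tLN:27\n@SQ\tSN:c2\tLN:12\n"
        path.write_text(header + "".join(records))

    def test_primary_mapped_records_only(self, tmp_path, small_refs):
        sam = tmp_path / "toy.sam"
        self._write_sam(
            sam,
            [
                "r1\t0\tc1\t3\t60\t8M\t*\t0\t0\tCCGGATCT\tIIIIIIII\n",  # kept
                "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGT\tIIIIIIII\n",  # unmapped
                "r3\t0\tc1\t5\t0\t8M\t*\t0\t0\tGGATCTTA\tIIIIIIII\n",  # MAPQ 0
                "r4\t16\tc2\t2\t60\t6M\t*\t0\t0\tTTTGAT\tIIIIII\n",  # minus strand
            ],
        )
        placements = load_placements_sam(sam, small_refs, min_mapq=1)
        assert placements == [
            Placement("c1", 2, "+", 8),
            Placement("c2", 1, "-", 6),
        ]

    def test_unknown_reference_errors(self, tmp_path, small_refs):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:cX\tLN:100\n"
            "r1\t0\tcX\t3\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(FourCError):
            load_placements_sam(sam, small_refs)


class TestCoverage:
    def test_rpm_linear_scaling(self, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        placements = [Placement("c1", 0, "+", 2)] * 5 + [
            Placement("c1", 6, "+", 4)
        ] * 15
        cov = coverage_per_fragment(placements, fragmap)
        f_first = fragmap.fragment_at("c1", 0).fragment_id
        f_second = fragmap.fragment_at("c1", 6).fragment_id
        assert cov.rpm[f_first] == pytest.approx(250_000)
        assert cov.rpm[f_second] == pytest.approx(750_000)
        assert cov.total_assigned == 20

    def test_single_placement_gets_full_million(self, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        cov = coverage_per_fragment([Placement("c1", 0, "+", 2)], fragmap)
        assert list(cov.rpm.values()) == [pytest.approx(1e6)]

    def test_boundary_placement_goes_to_right_fragment(self):
        refs = ReferenceSet({"c1": "AAGATCTT"})
        fragmap = digest_genome(refs, DPNII)
        cov = coverage_per_fragment([Placement("c1", 2, "+", 4)], fragmap)
        frag = fragmap.fragment_at("c1", 2)
        assert (frag.start, frag.end) == (2, 8)
        assert set(cov.counts) == {frag.fragment_id}

    def test_zero_placements_error(self, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        with pytest.raises(FourCError):
            coverage_per_fragment([], fragmap)

    def test_rpm_conserves_one_million(self, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        placements = [
            Placement("c1", p, "+", 2) for p in (0, 3, 7, 11, 20, 25)
        ] + [Placement("c2", 5, "+", 2)] * 3
        cov = coverage_per_fragment(placements, fragmap)
        assert math.isclose(sum(cov.rpm.values()), 1e6, rel_tol=1e-9)


def _cov(rep, rpm_by_fid):
    total = 1_000_000
    counts = {f: int(r * total / 1e6) for f, r in rpm_by_fid.items()}
    return FragmentCoverage(rep, counts, dict(rpm_by_fid), total)


class TestCallInteractions:
    @pytest.fixture()
    def setup(self):
        refs = ReferenceSet(
            {
                "c1": ("AAAT" * 25 + "GATC") * 40,  # 104 bp fragments
                "c2": ("CCGT" * 25 + "GATC") * 20,
            }
        )
        fragmap = digest_genome(refs, DPNII)
        bait = BaitSpec("c1", 500, "ACGTACGTCC").resolve(fragmap)
        return refs, fragmap, bait

    def test_reproducibility_requires_every_replicate(self, setup):
        _, fragmap, bait = setup
        target = 20
        calls = call_interactions(
            [_cov("r1", {target: 60.0}), _cov("r2", {target: 70.0})],
            bait, fragmap,
        )
        assert [c.fragment_id for c in calls] == [target]
        calls = call_interactions(
            [_cov("r1", {target: 60.0}), _cov("r2", {target: 10.0})],
            bait, fragmap,
        )
        assert calls == []

    def test_bait_exclusion_zone(self, setup):
        _, fragmap, bait = setup
        near = bait.bait_fragment_id + 2
        beyond = bait.bait_fragment_id + 3
        covs = [
            _cov("r1", {near: 900.0, beyond: 900.0}),
            _cov("r2", {near: 900.0, beyond: 900.0}),
        ]
        calls = call_interactions(covs, bait, fragmap)
        assert [c.fragment_id for c in calls] == [beyond]

    def test_cis_trans_flag_and_distance(self, setup):
        _, fragmap, bait = setup
        cis_fid = 30
        trans_fid = fragmap.fragments_for("c2")[5].fragment_id
        covs = [
            _cov("r1", {cis_fid: 100.0, trans_fid: 100.0}),
            _cov("r2", {cis_fid: 100.0, trans_fid: 100.0}),
        ]
        calls = {c.fragment_id: c for c in call_interactions(covs, bait, fragmap)}
        assert calls[cis_fid].is_cis
        frag = fragmap[cis_fid]
        assert calls[cis_fid].distance_to_bait == frag.midpoint - bait.position
        assert not calls[trans_fid].is_cis
        assert calls[trans_fid].distance_to_bait is None

    def test_requires_two_replicates(self, setup):
        _, fragmap, bait = setup
        with pytest.raises(FourCError):
            call_interactions([_cov("r1", {10: 100.0})], bait, fragmap)

    def test_threshold_monotonicity(self, setup):
        _, fragmap, bait = setup
        import numpy as np

        rng = np.random.default_rng(7)
        fids = rng.choice(len(fragmap), size=60, replace=False)
        covs = [
            _cov(rep, {int(f): float(rng.uniform(0, 200)) for f in fids})
            for rep in ("r1", "r2")
        ]
        previous = None
        for threshold in (10.0, 50.0, 100.0, 150.0):
            called = {
                c.fragment_id
                for c in call_interactions(covs, bait, fragmap, threshold)
            }
            if previous is not None:
                assert called <= previous
            previous = called


class TestSummarize:
    def test_observed_cis_trans_split(self):
        calls = [_make_call(i, True) for i in range(416)] + [
            _make_call(500 + i, False) for i in range(138)
        ]
        summary = summarize_cis_trans(calls)
        assert summary == CisTransSummary(554, 416, 138, 75.09, 24.91)

    def test_all_cis(self):
        summary = summarize_cis_trans([_make_call(i, True) for i in range(10)])
        assert (summary.pct_cis, summary.pct_trans) == (100.0, 0.0)

    def test_rounding(self):
        calls = [_make_call(0, True), _make_call(1, False), _make_call(2, False)]
        summary = summarize_cis_trans(calls)
        assert (summary.pct_cis, summary.pct_trans) == (33.33, 66.67)

    def test_empty_errors(self):
        with pytest.raises(FourCError):
            summarize_cis_trans([])


def _make_call(fid, is_cis, rpms=(100.0, 100.0)):
    return InteractionCall(
        fragment_id=fid, chrom="c1" if is_cis else "c2",
        start=fid * 10, end=fid * 10 + 10,
        rpm_per_replicate=list(rpms), is_cis=is_cis,
        distance_to_bait=float(fid) if is_cis else None,
    )


class TestTracksAndTables:
    def test_bedgraph_roundtrip(self, tmp_path, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        placements = [Placement("c1", 0, "+", 2)] * 3 + [Placement("c2", 5, "+", 2)]
        cov = coverage_per_fragment(placements, fragmap)
        bg = tmp_path / "cov.bedgraph"
        export_tracks(cov, [], fragmap, bg, tmp_path / "calls.bed")
        loaded = read_bedgraph(bg)
        by_fid = {
            (f.chrom, f.start, f.end): cov.rpm[f.fragment_id]
            for f in fragmap
            if f.fragment_id in cov.rpm
        }
        assert set(loaded) == set(by_fid)
        for key, value in by_fid.items():
            assert loaded[key] == pytest.approx(value, abs=1e-6)

    def test_empty_bed_has_header_comment(self, tmp_path, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        cov = coverage_per_fragment([Placement("c1", 0, "+", 2)], fragmap)
        bed = tmp_path / "calls.bed"
        export_tracks(cov, [], fragmap, tmp_path / "cov.bedgraph", bed)
        assert bed.read_text().startswith("#")

    def test_bed_score_capped_at_1000(self, tmp_path, small_refs):
        fragmap = digest_genome(small_refs, DPNII)
        cov = coverage_per_fragment([Placement("c1", 0, "+", 2)], fragmap)
        call = _make_call(0, True, rpms=(5000.0, 4000.0))
        bed = tmp_path / "calls.bed"
        export_tracks(cov, [call], fragmap, tmp_path / "cov.bedgraph", bed)
        line = [l for l in bed.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split("\t")[4] == "1000.0"

    def test_call_table_roundtrip(self, tmp_path):
        calls = [_make_call(3, True, (61.5, 72.25)), _make_call(9, False)]
        path = tmp_path / "calls.tsv"
        write_calls(calls, path)
        loaded = read_calls(path)
        assert [c.fragment_id for c in loaded] == [3, 9]
        assert loaded[0].rpm_per_replicate == pytest.approx([61.5, 72.25])
        assert loaded[1].distance_to_bait is None
        assert loaded[0].is_cis and not loaded[1].is_cis
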