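"""Scanner: signatures, clustering, pairing, features and their invariants."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from oracles import naive_metafeatures
from svrec.errors import EmptyInputError, ValidationError
from svrec.formats import GenomicInterval
from svrec.sigscan import (
    BreakpointCluster,
    EstimatedSV,
    ScanConfig,
    SoftclipSignature,
    cluster_breakpoints,
    compute_file_level_features,
    compute_metafeatures,
    compute_rvb_features,
    compute_size_proportions,
    compute_tandem_repeat_proportion,
    extract_softclip_signatures,
    pair_breakpoint_clusters,
)


def sig(bp, side="END", chrom="chr1", read_id="r", clip=50):
    return SoftclipSignature(read_id, chrom, side, clip, bp)


def cluster(rep, side, chrom="chr1", support=1):
    return BreakpointCluster(chrom, side, rep, support)


class TestSignatures:
    @pytest.mark.parametrize(
        "cigar, pos, expected",
        [
            # leading clip: START-side breakpoint at the mapped position
            (((4, 100), (0, 900)), 4999, [("START", 4999, 100)]),
            # trailing clip: END-side breakpoint after the aligned span
            (((0, 900), (4, 100)), 4999, [("END", 5899, 100)]),
            # clips on both ends give two signatures
            (((4, 60), (0, 800), (4, 140)), 100, [("START", 100, 60), ("END", 900, 140)]),
            # no clip, or clip below threshold
            (((0, 1000),), 4999, []),
            (((4, 5), (0, 995)), 4999, []),
        ],
    )
    def test_breakpoint_geometry(self, cigar, pos, expected):
        rec = make_record(cigar=cigar, pos=pos)
        sigs = extract_softclip_signatures([rec], min_clip=20)
        assert [(s.side, s.breakpoint, s.clip_length) for s in sigs] == expected

    def test_deletions_consume_reference_in_end_breakpoint(self):
        rec = make_record(cigar=((0, 400), (2, 100), (0, 400), (4, 200)), pos=1000)
        (s,) = extract_softclip_signatures([rec], min_clip=20)
        assert s.breakpoint == 1000 + 400 + 100 + 400


class TestClustering:
    def test_chain_within_window_forms_one_cluster(self):
        got = cluster_breakpoints([sig(1000), sig(1005), sig(1008)], window=50)
        assert got == [cluster(1005, "END", support=3)]

    def test_gap_beyond_window_splits(self):
        got = cluster_breakpoints([sig(1000), sig(2000)], window=50)
        assert [c.representative for c in got] == [1000, 2000]

    def test_sides_and_chromosomes_never_mix(self):
        sigs = [sig(1000, "END"), sig(1010, "START"), sig(1000, chrom="chr2")]
        assert len(cluster_breakpoints(sigs, window=100)) == 3

    def test_even_count_takes_lower_middle(self):
        got = cluster_breakpoints([sig(10), sig(20), sig(30), sig(40)], window=50)
        assert got[0].representative == 20

    def test_empty_input(self):
        assert cluster_breakpoints([], window=50) == []


class TestPairing:
    def test_single_admissible_pair(self):
        got = pair_breakpoint_clusters(
            [cluster(1000, "END")], [cluster(1500, "START")]
        )
        assert got == [EstimatedSV("chr1", 1000, 1500)]
        assert got[0].size == 500

    def test_distance_below_sv_floor_rejected(self):
        got = pair_breakpoint_clusters(
            [cluster(1000, "END")], [cluster(1030, "START")], min_sv=50
        )
        assert got == []

    def test_nearest_pair_wins_conflicts(self):
        got = pair_breakpoint_clusters(
            [cluster(1000, "END"), cluster(1100, "END")],
            [cluster(1600, "START")],
            max_sv=100_000,
        )
        assert got == [EstimatedSV("chr1", 1100, 1600)]

    def test_start_must_lie_strictly_downstream(self):
        got = pair_breakpoint_clusters(
            [cluster(2000, "END")], [cluster(1000, "START")]
        )
        assert got == []


class TestFeatures:
    def test_constant_read_length_mean(self):
        recs = [make_record(read_id=f"r{i}", cigar=((0, 1000),), pos=i * 500)
                for i in range(10)]
        avg_len, _, _ = compute_file_level_features(recs)
        assert avg_len == 1000

    def test_depth_is_aligned_bases_over_covered_span(self):
        # 50 reads of 1 kb tiling [0, 10000) -> 50000 / 10000 = 5x
        recs = [
            make_record(read_id=f"r{i}", cigar=((0, 1000),), pos=(i * 200) % 9000)
            for i in range(50)
        ]
        _, depth, span = compute_file_level_features(recs)
        covered = sum(iv.length for iv in span)
        assert depth == pytest.approx(50000 / covered)

    def test_no_mapped_reads_errors(self):
        with pytest.raises(EmptyInputError):
            compute_file_level_features([])

    @pytest.mark.parametrize(
        "sizes, expected",
        [
            ([100, 500, 1500, 60], (0.5, 0.25, 0.25)),
            ([200], (0.0, 1.0, 0.0)),  # 200 bp belongs to the middle class
            ([1000], (0.0, 1.0, 0.0)),  # 1000 bp still middle; large is >1000
            ([], (0.0, 0.0, 0.0)),
        ],
    )
    def test_size_class_proportions(self, sizes, expected):
        svs = [EstimatedSV("chr1", 10_000 * i, 10_000 * i + s)
               for i, s in enumerate(sizes)]
        assert compute_size_proportions(svs) == expected

    def test_tandem_repeat_overlap_fraction(self):
        svs = [EstimatedSV("chr1", 0, 100), EstimatedSV("chr1", 500, 600)]
        tr = [GenomicInterval("chr1", 50, 60)]
        assert compute_tandem_repeat_proportion(svs, tr) == 0.5
        assert compute_tandem_repeat_proportion(svs, []) == 0.0
        one = [EstimatedSV("chr1", 100, 200)]
        assert compute_tandem_repeat_proportion(
            one, [GenomicInterval("chr1", 150, 300)]
        ) == 1.0

    def test_rvb_window_enumeration(self):
        span = [GenomicInterval("chr1", 0, 20000)]
        svs = [EstimatedSV("chr1", 1000, 1100), EstimatedSV("chr1", 2000, 2100)]
        rvb, prop_high = compute_rvb_features(svs, 10000, span, high_threshold=2)
        # windows at 0, 5000, 10000 -> burdens (2, 0, 0)
        assert rvb == pytest.approx(2 / 3)
        assert prop_high == pytest.approx(1 / 3)

    def test_rvb_empty_cases(self):
        span = [GenomicInterval("chr1", 0, 20000)]
        assert compute_rvb_features([], 10000, span) == (0.0, 0.0)

    def test_raising_threshold_never_raises_prop_high(self):
        span = [GenomicInterval("chr1", 0, 50000)]
        svs = [EstimatedSV("chr1", i * 700, i * 700 + 90) for i in range(20)]
        props = [
            compute_rvb_features(svs, 8000, span, high_threshold=t)[1]
            for t in (1, 2, 4, 8)
        ]
        assert props == sorted(props, reverse=True)


def random_records(rng, n):
    recs = []
    for i in range(n):
        pos = rng.randrange(0, 50_000)
        lead = rng.choice([0, 0, rng.randrange(5, 300)])
        tail = rng.choice([0, 0, rng.randrange(5, 300)])
        mid = rng.randrange(100, 3000)
        cigar = []
        if lead:
            cigar.append((4, lead))
        cigar.append((0, mid))
        if rng.random() < 0.3:
            cigar.extend([(2, rng.randrange(1, 200)), (0, rng.randrange(50, 500))])
        if tail:
            cigar.append((4, tail))
        recs.append(make_record(read_id=f"r{i}", pos=pos, cigar=tuple(cigar)))
    return recs


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_streaming_equals_naive_loops(self, seed):
        rng = random.Random(seed)
        recs = random_records(rng, rng.randrange(5, 120))
        tr = [
            GenomicInterval("chr1", s, s + rng.randrange(50, 2000))
            for s in sorted(rng.sample(range(0, 50_000, 100), 5))
        ]
        from svrec.formats import merge_intervals

        tr = merge_intervals(tr)
        got = compute_metafeatures(recs, tr).as_dict()
        want = naive_metafeatures(recs, tr)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key

    @pytest.mark.parametrize("seed", range(4))
    def test_record_order_never_matters(self, seed):
        rng = random.Random(100 + seed)
        recs = random_records(rng, 60)
        base = compute_metafeatures(recs).as_tuple()
        rng.shuffle(recs)
        assert compute_metafeatures(recs).as_tuple() == base

    @pytest.mark.parametrize("seed", range(6))
    def test_size_proportions_sum_to_zero_or_one(self, seed):
        rng = random.Random(200 + seed)
        recs = random_records(rng, rng.randrange(5, 100))
        mf = compute_metafeatures(recs)
        total = mf.prop_short + mf.prop_middle + mf.prop_large
        assert math.isclose(total, 0.0, abs_tol=1e-12) or math.isclose(
            total, 1.0, rel_tol=1e-12
        )
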