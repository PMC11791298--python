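"""Interval algebra, coverage extraction, and format round-trips."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selandscape.core import (
    GenomicInterval,
    ParseError,
    Peak,
    SignalTrack,
    filter_excluded,
    merge_intervals,
    overlap_bp,
    read_narrowpeak,
    read_rose_gff,
    write_narrowpeak,
    write_rose_gff,
)
from conftest import merge_bruteforce, overlap_bruteforce, random_intervals


def _iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestIntervalBasics:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 1000), ("chr1", 900, 1200), 100),
            (("chr1", 0, 100), ("chr1", 100, 200), 0),  # half-open touch
            (("chr1", 0, 100), ("chr1", 0, 100), 100),  # identity
            (("chr1", 0, 100), ("chr2", 0, 100), 0),    # different chrom
        ],
    )
    def test_overlap_bp(self, a, b, expected):
        assert overlap_bp(_iv(*a), _iv(*b)) == expected

    def test_summit_must_lie_inside_peak(self):
        with pytest.raises(ValueError):
            Peak(_iv("chr1", 100, 600), summit_offset=500)
        assert Peak(_iv("chr1", 100, 600), summit_offset=250).summit == 350


class TestMerge:
    def test_touching_intervals_merge_at_gap_zero(self):
        merged = merge_intervals([_iv("chr1", 0, 100), _iv("chr1", 100, 200)])
        assert [(m.chrom, m.start, m.end) for m in merged] == [("chr1", 0, 200)]
        assert merged[0].score == 2  # count of merged inputs

    def test_separated_intervals_stay_apart(self):
        merged = merge_intervals([_iv("chr1", 0, 100), _iv("chr1", 150, 200)])
        assert len(merged) == 2

    def test_max_gap_bridges_separation(self):
        merged = merge_intervals(
            [_iv("chr1", 0, 100), _iv("chr1", 150, 200)], max_gap=50
        )
        assert len(merged) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        triples = random_intervals(rng, int(rng.integers(2, 200)))
        max_gap = int(rng.integers(0, 2000))
        got = merge_intervals([_iv(*t) for t in triples], max_gap=max_gap)
        assert [(m.chrom, m.start, m.end) for m in got] == merge_bruteforce(
            triples, max_gap
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        once = merge_intervals([_iv(*t) for t in random_intervals(rng, 100)])
        twice = merge_intervals(once)
        assert [(m.chrom, m.start, m.end) for m in twice] == [
            (m.chrom, m.start, m.end) for m in once
        ]

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 300)),
            min_size=1, max_size=40,
        ),
        st.integers(0, 500),
    )
    def test_union_of_bases_preserved_and_idempotent(self, spans, max_gap):
        ivs = [_iv("chr1", s, s + l) for s, l in spans]
        merged = merge_intervals(ivs, max_gap=max_gap)
        covered_in = set()
        for iv in ivs:
            covered_in.update(range(iv.start, iv.end))
        covered_out = set()
        for m in merged:
            covered_out.update(range(m.start, m.end))
        assert covered_in <= covered_out  # gap-bridging may only add bases
        for a, b in zip(merged, merged[1:]):
            assert b.start - a.end > max_gap
        again = merge_intervals(merged, max_gap=max_gap)
        assert [(m.start, m.end) for m in again] == [
            (m.start, m.end) for m in merged
        ]

    def test_natural_chromosome_order(self):
        merged = merge_intervals(
            [_iv("chr10", 0, 10), _iv("chr2", 0, 10), _iv("chr1", 0, 10)]
        )
        assert [m.chrom for m in merged] == ["chr1", "chr2", "chr10"]


class TestExclusionFilter:
    def test_one_bp_overlap_removes(self):
        peaks = [Peak(_iv("chr1", 100, 200))]
        assert filter_excluded(peaks, [_iv("chr1", 150, 160)]) == []
        assert filter_excluded(peaks, [_iv("chr1", 199, 300)]) == []

    def test_half_open_touch_keeps(self):
        peaks = [Peak(_iv("chr1", 100, 200))]
        assert filter_excluded(peaks, [_iv("chr1", 200, 300)]) == peaks
        assert filter_excluded(peaks, []) == peaks

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_allpairs_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        peaks = [Peak(_iv(*t)) for t in random_intervals(rng, 100)]
        excl = [_iv(*t) for t in random_intervals(rng, 20)]
        got = filter_excluded(peaks, excl)
        expected = [
            p
            for p in peaks
            if not any(
                overlap_bruteforce(
                    (p.interval.chrom, p.interval.start, p.interval.end),
                    (e.chrom, e.start, e.end),
                )
                > 0
                for e in excl
            )
        ]
        assert got == expected


class TestSignalTrack:
    def test_uniform_track_region_sum(self):
        track = SignalTrack({"chr1": np.full(100, 2.0)}, 10, 1e6)
        assert track.interval_signal(_iv("chr1", 0, 100)) == pytest.approx(20.0)

    def test_zero_track(self):
        track = SignalTrack({"chr1": np.zeros(100)}, 10, 1e6)
        assert track.interval_signal(_iv("chr1", 5, 95)) == 0.0

    def test_partial_bins_prorated(self):
        track = SignalTrack({"chr1": np.array([10.0, 20.0])}, 10, 1e6)
        # [5, 15) covers half of each bin
        assert track.interval_signal(_iv("chr1", 5, 15)) == pytest.approx(15.0)

    def test_region_outside_extent_raises(self):
        track = SignalTrack({"chr1": np.zeros(10)}, 10, 1e6)
        with pytest.raises(ValueError, match="chr1:50-200"):
            track.interval_signal(_iv("chr1", 50, 200))
        with pytest.raises(ValueError, match="chr9"):
            track.interval_signal(_iv("chr9", 0, 10))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_summation(self, seed):
        rng = np.random.default_rng(200 + seed)
        values = rng.random(200) * 5
        bin_size = 10
        track = SignalTrack({"chr1": values}, bin_size, 1e6)
        per_base = np.repeat(values / bin_size, bin_size)
        for _ in range(5):
            start = int(rng.integers(0, 1900))
            end = int(rng.integers(start + 1, 2000))
            assert track.interval_signal(_iv("chr1", start, end)) == pytest.approx(
                per_base[start:end].sum()
            )

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        track = SignalTrack({"chr1": rng.random(50), "chr2": rng.random(30)}, 25, 2e6)
        path = tmp_path / "t.bedGraph"
        track.to_bedgraph(path)
        back = SignalTrack.from_bedgraph(path, 2e6)
        assert back.bin_size == 25
        for chrom in track.values:
            np.testing.assert_allclose(
                back.values[chrom], track.values[chrom], rtol=1e-5
            )

    def test_nonpositive_library_size_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack({"chr1": np.zeros(5)}, 10, 0.0)


class TestNarrowPeakIO:
    def test_single_line_field_mapping(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t600\tp1\t0\t.\t5.0\t3.0\t2.0\t250\n")
        peaks = read_narrowpeak(path)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.interval.chrom, p.interval.start, p.interval.end) == ("chr1", 100, 600)
        assert p.summit == 350
        assert p.signal_value == 5.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert read_narrowpeak(path) == []

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t100\t600\tp1\t0\t.\t5.0\t3.0\t2.0",          # 9 columns
            "chr1\t600\t100\tp1\t0\t.\t5.0\t3.0\t2.0\t250",      # end < start
            "chr1\t100\t600\tp1\t0\t.\t5.0\t3.0\t2.0\tXYZ",      # bad summit
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t0\t50\tok\t0\t.\t1\t1\t1\t25\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_narrowpeak(path)

    def test_round_trip_random_peaks(self, tmp_path):
        rng = np.random.default_rng(42)
        peaks = []
        for i, t in enumerate(random_intervals(rng, 50)):
            iv = _iv(*t, name=f"p{i}", score=float(rng.integers(0, 1000)), strand=".")
            peaks.append(
                Peak(
                    iv,
                    int(rng.integers(0, iv.length)),
                    float(np.round(rng.random() * 10, 3)),
                    float(np.round(rng.random() * 10, 3)),
                    float(np.round(rng.random() * 10, 3)),
                )
            )
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, path)
        assert read_narrowpeak(path) == peaks


class TestRoseGff:
    def test_coordinates_become_one_based_inclusive(self, tmp_path):
        path = tmp_path / "a.gff"
        write_rose_gff([Peak(_iv("chr1", 100, 600, name="p1"))], path)
        fields = path.read_text().strip().split("\t")
        assert (fields[3], fields[4]) == ("101", "600")

    def test_empty_input_writes_empty_file(self, tmp_path):
        path = tmp_path / "e.gff"
        write_rose_gff([], path)
        assert path.read_text() == ""

    def test_duplicate_names_disambiguated(self, tmp_path):
        path = tmp_path / "d.gff"
        write_rose_gff(
            [Peak(_iv("chr1", 0, 10, name="p")), Peak(_iv("chr1", 20, 30, name="p"))],
            path,
        )
        ids = [l.split("\t")[1] for l in path.read_text().splitlines()]
        assert len(set(ids)) == 2

    def test_round_trip_recovers_half_open_intervals(self, tmp_path):
        rng = np.random.default_rng(7)
        peaks = [
            Peak(_iv(*t, name=f"p{i}"))
            for i, t in enumerate(random_intervals(rng, 50))
        ]
        path = tmp_path / "rt.gff"
        write_rose_gff(peaks, path)
        back = read_rose_gff(path)
        assert [(g.chrom, g.start, g.end) for g in back] == [
            (p.interval.chrom, p.interval.start, p.interval.end) for p in peaks
        ]
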