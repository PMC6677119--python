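"""Segment calling: extraction, merging, positions, IDR/foldon/APR summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topoland.io_annotation import Segment
from topoland.track_segmentation import (
    apr_gatekeepers,
    classify_segment_position,
    extract_segments,
    foldon_summary,
    idr_summary,
    merge_segments,
)


def _brute_force_segments(values, threshold, min_len):
    """Position-by-position oracle for maximal above-threshold runs."""
    above = [v >= threshold for v in values]
    out = []
    for start in range(1, len(values) + 1):
        for end in range(start, len(values) + 1):
            if not all(above[start - 1 : end]):
                continue
            left_ok = start == 1 or not above[start - 2]
            right_ok = end == len(values) or not above[end]
            if left_ok and right_ok and end - start + 1 >= min_len:
                out.append((start, end))
    return out


class TestExtractSegments:
    def test_plateau_followed_by_low_tail(self):
        values = [0.6] * 7 + [0.4] * 3
        segs = extract_segments(values, threshold=0.5, min_len=5)
        assert [(s.start, s.end) for s in segs] == [(1, 7)]
        assert segs[0].mean_score == pytest.approx(0.6)

    def test_all_below_threshold_gives_empty(self):
        assert extract_segments([0.1, 0.2, 0.3], threshold=0.5, min_len=1) == []

    def test_run_of_exactly_min_len_included(self):
        values = [0.0, 0.9, 0.9, 0.9, 0.0]
        assert len(extract_segments(values, threshold=0.5, min_len=3)) == 1
        assert extract_segments(values, threshold=0.5, min_len=4) == []

    def test_threshold_is_inclusive(self):
        assert len(extract_segments([0.5, 0.5], threshold=0.5, min_len=2)) == 1

    def test_invalid_min_len_rejected(self):
        with pytest.raises(ValueError):
            extract_segments([0.5], threshold=0.5, min_len=0)

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            values = rng.random(int(rng.integers(1, 60)))
            threshold = float(rng.random())
            min_len = int(rng.integers(1, 6))
            got = [(s.start, s.end) for s in extract_segments(values, threshold, min_len)]
            assert got == _brute_force_segments(values, threshold, min_len)

    def test_reversal_mirrors_coordinates(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            values = rng.random(40)
            L = len(values)
            fwd = {(s.start, s.end) for s in extract_segments(values, 0.5, 3)}
            rev = {
                (L - s.end + 1, L - s.start + 1)
                for s in extract_segments(values[::-1], 0.5, 3)
            }
            assert fwd == rev


segment_lists = st.lists(
    st.tuples(st.integers(1, 50), st.integers(0, 10)).map(
        lambda t: Segment(start=t[0], end=t[0] + t[1], mean_score=1.0)
    ),
    min_size=0,
    max_size=8,
)


class TestMergeSegments:
    def test_directly_adjacent_segments_fuse(self):
        merged = merge_segments([Segment(start=1, end=5), Segment(start=6, end=10)])
        assert [(s.start, s.end) for s in merged] == [(1, 10)]

    def test_gapped_segments_unchanged(self):
        segs = [Segment(start=1, end=5), Segment(start=7, end=12)]
        assert [(s.start, s.end) for s in merge_segments(segs)] == [(1, 5), (7, 12)]

    @settings(derandomize=True, max_examples=100)
    @given(segment_lists)
    def test_idempotent_and_non_overlapping(self, segs):
        once = merge_segments(segs)
        twice = merge_segments(once)
        assert [(s.start, s.end) for s in once] == [(s.start, s.end) for s in twice]
        for a, b in zip(once, once[1:]):
            assert b.start > a.end + 1


class TestSegmentPosition:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(10, 40, "N"), (280, 300, "C"), (100, 150, "M"), (30, 100, "N"), (100, 271, "C")],
    )
    def test_terminal_windows(self, start, end, expected):
        assert classify_segment_position(Segment(start=start, end=end), L=300) == expected

    def test_short_protein_ties_resolve_to_n(self):
        assert classify_segment_position(Segment(start=1, end=40), L=40) == "N"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            classify_segment_position(Segment(start=10, end=60), L=50)


class TestIdrSummary:
    def _track(self, L, idrs):
        values = np.zeros(L)
        for start, end in idrs:
            values[start - 1 : end] = 0.9
        return values

    def test_coverage_at_exact_idp_threshold(self):
        summary = idr_summary(self._track(100, [(1, 30)]))
        assert summary.coverage == pytest.approx(0.30)
        assert summary.is_idp

    def test_coverage_just_below_idp_threshold(self):
        summary = idr_summary(self._track(100, [(1, 29)]))
        assert summary.coverage == pytest.approx(0.29)
        assert not summary.is_idp

    def test_counts_and_frequency(self):
        summary = idr_summary(self._track(200, [(1, 10), (50, 60)]))
        assert summary.n_short == 2
        assert summary.n_long == 0
        assert summary.idrs_per_100 == pytest.approx(1.0)
        assert summary.coverage == pytest.approx(21 / 200)

    def test_short_long_length_boundary(self):
        summary = idr_summary(self._track(300, [(1, 19), (100, 119)]))
        assert summary.n_short == 1  # length 19
        assert summary.n_long == 1  # length 20
        assert summary.longest == 20

    def test_position_classes_attached(self):
        summary = idr_summary(self._track(300, [(1, 10), (150, 160), (290, 300)]))
        assert [s.position_class for s in summary.idr_segments] == ["N", "M", "C"]


class TestFoldonSummary:
    def test_single_plateau(self):
        values = np.zeros(100)
        values[10:16] = 0.5
        summary = foldon_summary(values, threshold=0.163)
        assert summary.foldons_per_100 == pytest.approx(1.0)
        assert summary.mean_length == pytest.approx(6.0)

    def test_no_plateau_reports_absent_means(self):
        summary = foldon_summary(np.zeros(50), threshold=0.163)
        assert summary.foldons_per_100 == 0.0
        assert np.isnan(summary.mean_length)
        assert np.isnan(summary.mean_score)

    def test_two_plateaus_mean_length(self):
        values = np.zeros(200)
        values[0:5] = 0.3
        values[100:109] = 0.3
        summary = foldon_summary(values, threshold=0.163)
        assert summary.foldons_per_100 == pytest.approx(1.0)
        assert summary.mean_length == pytest.approx(7.0)


def _brute_force_gatekeepers(aprs, L, flank):
    in_apr = {p for s, e in aprs for p in range(s, e + 1)}
    positions = set()
    for s, e in aprs:
        positions |= {p for p in range(s - flank, s) if p >= 1}
        positions |= {p for p in range(e + 1, e + flank + 1) if p <= L}
    return positions - in_apr


class TestAprGatekeepers:
    def _track(self, L, aprs, level=10.0):
        values = np.zeros(L)
        for start, end in aprs:
            values[start - 1 : end] = level
        return values

    def test_flank_positions_of_interior_apr(self):
        seq = "A" * 30
        summary = apr_gatekeepers(self._track(30, [(10, 15)]), seq)
        assert summary.gatekeeper_positions == frozenset({7, 8, 9, 16, 17, 18})

    def test_apr_at_n_terminus_has_right_flank_only(self):
        seq = "A" * 20
        summary = apr_gatekeepers(self._track(20, [(1, 6)]), seq)
        assert summary.gatekeeper_positions == frozenset({7, 8, 9})

    def test_gatekeepers_never_inside_another_apr(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            L = int(rng.integers(20, 80))
            n = int(rng.integers(1, 4))
            aprs = []
            cursor = 1
            for _k in range(n):
                if cursor + 6 > L:
                    break
                start = cursor + int(rng.integers(0, 5))
                end = min(L, start + int(rng.integers(5, 10)))
                if end - start + 1 < 5:  # truncated below min_len: not callable
                    break
                aprs.append((start, end))
                cursor = end + 2  # may leave gaps smaller than the flank
            if not aprs:
                continue
            seq = "A" * L
            summary = apr_gatekeepers(self._track(L, aprs), seq)
            assert summary.gatekeeper_positions == frozenset(_brute_force_gatekeepers(aprs, L, 3))

    def test_composition_reflects_planted_flanks(self):
        # P left of the APR, R right of it: composition concentrates on P and R.
        seq = "AAAAAA" + "PPP" + "ILVFM" + "RRR" + "AAAAAA"
        values = np.zeros(len(seq))
        values[9:14] = 10.0  # the ILVFM run
        summary = apr_gatekeepers(values, seq)
        assert summary.gatekeeper_composition == {"P": 0.5, "R": 0.5}
        assert sum(summary.gatekeeper_composition.values()) == pytest.approx(1.0)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            apr_gatekeepers(np.zeros(10), "A" * 10, flank=-1)
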