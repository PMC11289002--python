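"""Flank extraction geometry, overlap/truncation rules and side assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lwikit.io import LabeledAlignment, ReferenceTopology, SeqMeta
from lwikit.segments import (
    SelectorError,
    assign_sides,
    extract_segments,
    pooled_columns,
    segment_table,
)


def gapless_alignment(length, ref_id="ref"):
    seq = ("ACDEFGHIKLMNPQRSTVWY" * (length // 20 + 1))[:length]
    return LabeledAlignment(
        records=[(ref_id, seq)], metadata={ref_id: SeqMeta("x", "mammal")}
    )


def topology(intervals, length=None, side="inner", w=5):
    return ReferenceTopology(
        reference_id="ref",
        tm_intervals=tuple(intervals),
        n_terminus_side=side,
        flank_width=w,
    )


def brute_force_flanks(intervals, length, w):
    """Independent oracle: label every reference position by linear scan.

    For each TM (s, e) the N-window is s-w..s-1 and the C-window e+1..e+w,
    clipped to [1, length]; positions inside any TM are excluded.  Returns
    per-flank position lists and overlap sets.
    """
    in_tm = set()
    for s, e in intervals:
        in_tm.update(range(s, e + 1))
    windows = {}
    for i, (s, e) in enumerate(intervals, start=1):
        windows[(i, "N")] = [
            p for p in range(max(1, s - w), s) if 1 <= p <= length and p not in in_tm
        ]
        windows[(i, "C")] = [
            p
            for p in range(e + 1, min(length, e + w) + 1)
            if p not in in_tm
        ]
    overlaps = {}
    for key, positions in windows.items():
        i, side = key
        other = (i + 1, "N") if side == "C" else (i - 1, "C")
        shared = set(positions) & set(windows.get(other, []))
        overlaps[key] = shared
    return windows, overlaps


class TestExtractSegments:
    def test_roomy_loop_no_overlap(self):
        aln = gapless_alignment(40)
        topo = topology([(11, 15), (26, 30)], 40)
        segmap = extract_segments(aln, topo)
        assert segmap.flank(1, "C").ref_positions == tuple(range(16, 21))
        assert segmap.flank(2, "N").ref_positions == tuple(range(21, 26))
        assert segmap.flank(1, "C").overlap_positions == frozenset()
        assert segmap.flank(2, "N").overlap_positions == frozenset()

    def test_short_loop_positions_counted_for_both_flanks(self):
        # loop 16..21 (length 6): C-TM1 = 16-20, N-TM2 = 17-21, overlap 17-20
        aln = gapless_alignment(40)
        topo = topology([(11, 15), (22, 30)], 40)
        segmap = extract_segments(aln, topo)
        c1 = segmap.flank(1, "C")
        n2 = segmap.flank(2, "N")
        assert c1.ref_positions == tuple(range(16, 21))
        assert n2.ref_positions == tuple(range(17, 22))
        assert c1.overlap_positions == frozenset({17, 18, 19, 20})
        assert n2.overlap_positions == frozenset({17, 18, 19, 20})

    def test_terminus_clipping_sets_truncation_flag(self):
        aln = gapless_alignment(40)
        topo = topology([(3, 10), (26, 30)], 40)
        segmap = extract_segments(aln, topo)
        n1 = segmap.flank(1, "N")
        assert n1.ref_positions == (1, 2)
        assert n1.truncated

    def test_zero_length_loop_yields_empty_truncated_flanks(self):
        aln = gapless_alignment(40)
        topo = topology([(11, 15), (16, 20)], 40)
        segmap = extract_segments(aln, topo)
        assert segmap.flank(1, "C").ref_positions == ()
        assert segmap.flank(1, "C").truncated
        assert segmap.flank(2, "N").ref_positions == ()

    def test_flanks_never_enter_tm_columns(self):
        aln = gapless_alignment(60)
        topo = topology([(8, 20), (24, 40), (44, 52)], 60)
        segmap = extract_segments(aln, topo)
        tm_cols = {c for cols in segmap.tm_columns.values() for c in cols}
        for f in segmap.flanks.values():
            assert not set(f.columns) & tm_cols

    def test_matches_brute_force_oracle_on_random_topologies(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_tm = int(rng.integers(2, 7))
            cursor = int(rng.integers(1, 30))
            intervals = []
            for _ in range(n_tm):
                start = cursor + int(rng.integers(0, 12))
                end = start + int(rng.integers(5, 25))
                intervals.append((start, end))
                cursor = end + 1 + int(rng.integers(0, 15))
            length = intervals[-1][1] + int(rng.integers(0, 12))
            aln = gapless_alignment(length)
            topo = topology(intervals, length)
            segmap = extract_segments(aln, topo)
            windows, overlaps = brute_force_flanks(intervals, length, 5)
            for key in windows:
                assert list(segmap.flanks[key].ref_positions) == windows[key]
                assert set(segmap.flanks[key].overlap_positions) == overlaps[key]

    def test_gapped_reference_maps_to_columns(self):
        # gap inside the N-flank of TM1 shifts alignment columns right
        row = "MKTAY--IAKQRFFLLGGAAVVSSDDEEKKRR"
        aln = LabeledAlignment(
            records=[("ref", row)], metadata={"ref": SeqMeta("x", "mammal")}
        )
        topo = topology([(11, 15)], 30, w=3)
        segmap = extract_segments(aln, topo)
        # reference position p maps to column p + 2 for p > 5
        assert segmap.flank(1, "N").ref_positions == (8, 9, 10)
        assert segmap.flank(1, "N").columns == (10, 11, 12)


class TestAssignSides:
    def test_six_tm_inner_start(self):
        aln = gapless_alignment(200)
        intervals = [(i * 30 + 11, i * 30 + 25) for i in range(6)]
        topo = topology(intervals, 200, side="inner")
        segmap = assign_sides(extract_segments(aln, topo), topo)
        inner = {f.name for f in segmap.flanks.values() if f.side_class == "inner"}
        assert inner == {"N-TM1", "C-TM2", "N-TM3", "C-TM4", "N-TM5", "C-TM6"}
        assert segmap.flank(5, "N").side_class == "inner"
        assert segmap.flank(5, "C").side_class == "outer"

    def test_six_tm_outer_start_swaps_assignment(self):
        aln = gapless_alignment(200)
        intervals = [(i * 30 + 11, i * 30 + 25) for i in range(6)]
        topo = topology(intervals, 200, side="outer")
        segmap = assign_sides(extract_segments(aln, topo), topo)
        assert segmap.flank(1, "N").side_class == "outer"

    def test_two_tm_toy_enumeration(self):
        aln = gapless_alignment(40)
        topo = topology([(11, 15), (26, 30)], 40, side="inner")
        segmap = assign_sides(extract_segments(aln, topo), topo)
        inner = {f.name for f in segmap.flanks.values() if f.side_class == "inner"}
        outer = {f.name for f in segmap.flanks.values() if f.side_class == "outer"}
        assert inner == {"N-TM1", "C-TM2"}
        assert outer == {"C-TM1", "N-TM2"}

    @given(st.integers(2, 6), st.sampled_from(["inner", "outer"]))
    def test_involution_under_side_flip(self, n_tm, side):
        aln = gapless_alignment(40 * n_tm)
        intervals = [(i * 35 + 11, i * 35 + 25) for i in range(n_tm)]
        topo = topology(intervals, side=side)
        flipped = ReferenceTopology(
            reference_id="ref",
            tm_intervals=topo.tm_intervals,
            n_terminus_side="outer" if side == "inner" else "inner",
            flank_width=5,
        )
        base = extract_segments(aln, topo)
        swap = {"inner": "outer", "outer": "inner"}
        once = assign_sides(base, topo)
        twice = assign_sides(base, flipped)
        for key in once.flanks:
            assert swap[once.flanks[key].side_class] == twice.flanks[key].side_class


class TestPooledColumns:
    def _segmap(self, intervals=((11, 15), (26, 30)), length=40):
        aln = gapless_alignment(length)
        topo = topology(list(intervals), length)
        return assign_sides(extract_segments(aln, topo), topo), aln

    def test_no_overlap_total_is_sum_of_flanks(self):
        segmap, _ = self._segmap()
        total = pooled_columns(segmap, "LWI_total")
        flank_sizes = sum(len(f.columns) for f in segmap.flanks.values())
        assert len(total) == flank_sizes

    def test_overlap_deduplicated_in_pool_but_kept_per_flank(self):
        segmap, _ = self._segmap(intervals=((11, 15), (22, 30)))
        flank_sizes = sum(len(f.columns) for f in segmap.flanks.values())
        total = pooled_columns(segmap, "LWI_total")
        assert len(total) == flank_sizes - 4
        assert len(pooled_columns(segmap, ("flank", 1, "C"))) == 5
        assert len(pooled_columns(segmap, ("flank", 2, "N"))) == 5

    def test_full_length_is_all_columns(self):
        segmap, aln = self._segmap()
        assert pooled_columns(segmap, "full_length") == tuple(
            range(1, aln.width + 1)
        )

    def test_inner_outer_partition_lwi_total(self):
        segmap, _ = self._segmap()
        inner = set(pooled_columns(segmap, "LWI_inner"))
        outer = set(pooled_columns(segmap, "LWI_outer"))
        total = set(pooled_columns(segmap, "LWI_total"))
        assert inner | outer == total

    def test_unknown_selector_rejected(self):
        segmap, _ = self._segmap()
        with pytest.raises(SelectorError):
            pooled_columns(segmap, "LWI_sideways")
        with pytest.raises(SelectorError):
            pooled_columns(segmap, ("tm", 9))


def test_segment_table_lists_all_regions():
    aln = gapless_alignment(40)
    topo = topology([(11, 15), (26, 30)], 40)
    segmap = assign_sides(extract_segments(aln, topo), topo)
    table = segment_table(segmap)
    assert set(table["name"]) == {"TM1", "TM2", "N-TM1", "C-TM1", "N-TM2", "C-TM2"}
    assert (table.loc[table["name"] == "TM1", "side_class"] == "membrane").all()
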