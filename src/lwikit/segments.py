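"""Derivation of lipid-water-interface (LWI) flank regions from a TM topology.

Each transmembrane helix contributes two LWI flanks: the ``flank_width``
(default 5) residues immediately N-terminal of the helix and the same number
immediately C-terminal.  A 6-TM topology therefore yields twelve flanks.
When the loop between two helices is shorter than twice the flank width, the
two facing flanks overlap and the shared residues are counted for BOTH flanks
in per-flank statistics; pooled LWI aggregates deduplicate them.  Flanks are
defined on the reference sequence and transferred to every species through
alignment columns, so insertions relative to the reference are invisible to
region statistics.

Membrane sidedness alternates at each TM crossing starting from the side of
the N-terminus, which partitions the flanks into an inner (cytoplasmic) and
an outer (extracellular) set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .io import (
    LabeledAlignment,
    LwiError,
    ReferenceTopology,
    map_reference_to_columns,
)

__all__ = [
    "Flank",
    "LwiSegmentMap",
    "SelectorError",
    "extract_segments",
    "assign_sides",
    "pooled_columns",
    "segment_table",
]


class SelectorError(LwiError):
    """An unknown region selector was passed to :func:`pooled_columns`."""


@dataclass(frozen=True)
class Flank:
    """One LWI flank: ``(tm_index, side)`` with its positions and flags.

    ``ref_positions`` are ungapped reference coordinates (1-based), already
    clipped to the sequence and with positions falling inside any TM removed.
    ``overlap_positions`` is the subset shared with the facing flank of the
    adjacent TM.  ``truncated`` is set when clipping at a terminus or at a TM
    boundary shortened the flank below ``flank_width``.
    """

    tm_index: int
    side: str  # "N" or "C"
    ref_positions: tuple[int, ...]
    columns: tuple[int, ...]
    overlap_positions: frozenset[int]
    truncated: bool
    side_class: str | None = None  # "inner" / "outer" once assigned

    @property
    def name(self) -> str:
        return f"{self.side}-TM{self.tm_index}"


@dataclass(frozen=True)
class LwiSegmentMap:
    """TM and flank regions as reference positions and alignment columns."""

    reference_id: str
    flank_width: int
    n_terminus_side: str
    tm_ref: dict[int, tuple[int, ...]]
    tm_columns: dict[int, tuple[int, ...]]
    flanks: dict[tuple[int, str], Flank]
    alignment_width: int

    @property
    def n_tm(self) -> int:
        return len(self.tm_ref)

    def flank(self, tm_index: int, side: str) -> Flank:
        return self.flanks[(tm_index, side)]

    def sides_assigned(self) -> bool:
        return all(f.side_class is not None for f in self.flanks.values())


def extract_segments(aln: LabeledAlignment, topo: ReferenceTopology) -> LwiSegmentMap:
    """Build the flank/TM segment map for a topology on its reference.

    For a TM spanning reference positions ``(s, e)`` the N-side flank window
    is ``s - w .. s - 1`` and the C-side window ``e + 1 .. e + w``.  Windows
    are clipped to ``[1, reference length]`` and positions falling inside any
    TM interval are excluded (both set the truncation flag).  Residues shared
    between the C-flank of one TM and the N-flank of the next (loop shorter
    than ``2 w``) are recorded as overlap positions on both flanks.
    """
    topo.validate_against(aln)
    ref_to_col = map_reference_to_columns(aln, topo)
    ref_len = len(ref_to_col)
    w = topo.flank_width

    in_tm: set[int] = set()
    for start, end in topo.tm_intervals:
        in_tm.update(range(start, end + 1))

    def window(lo: int, hi: int) -> tuple[tuple[int, ...], bool]:
        truncated = lo < 1 or hi > ref_len
        positions = [
            p for p in range(max(lo, 1), min(hi, ref_len) + 1) if p not in in_tm
        ]
        if len(positions) < hi - lo + 1:
            truncated = True
        return tuple(positions), truncated

    raw: dict[tuple[int, str], tuple[tuple[int, ...], bool]] = {}
    tm_ref: dict[int, tuple[int, ...]] = {}
    tm_columns: dict[int, tuple[int, ...]] = {}
    for i, (start, end) in enumerate(topo.tm_intervals, start=1):
        tm_ref[i] = tuple(range(start, end + 1))
        tm_columns[i] = tuple(ref_to_col[p] for p in tm_ref[i])
        raw[(i, "N")] = window(start - w, start - 1)
        raw[(i, "C")] = window(end + 1, end + w)

    flanks: dict[tuple[int, str], Flank] = {}
    for (i, side), (positions, truncated) in raw.items():
        neighbour: tuple[int, ...] = ()
        if side == "C" and (i + 1, "N") in raw:
            neighbour = raw[(i + 1, "N")][0]
        elif side == "N" and (i - 1, "C") in raw:
            neighbour = raw[(i - 1, "C")][0]
        overlap = frozenset(positions) & frozenset(neighbour)
        flanks[(i, side)] = Flank(
            tm_index=i,
            side=side,
            ref_positions=positions,
            columns=tuple(ref_to_col[p] for p in positions),
            overlap_positions=overlap,
            truncated=truncated,
        )

    return LwiSegmentMap(
        reference_id=topo.reference_id,
        flank_width=w,
        n_terminus_side=topo.n_terminus_side,
        tm_ref=tm_ref,
        tm_columns=tm_columns,
        flanks=flanks,
        alignment_width=aln.width,
    )


def assign_sides(segmap: LwiSegmentMap, topo: ReferenceTopology) -> LwiSegmentMap:
    """Label every flank inner or outer by parity of TM crossings.

    The stretch before TM1 lies on ``n_terminus_side``; the side flips at
    every TM crossing.  The N-flank of TM ``i`` lies before crossing ``i``
    (``i - 1`` flips from the N-terminus), the C-flank after it (``i`` flips).
    """
    start_inner = topo.n_terminus_side == "inner"

    def side_class(i: int, side: str) -> str:
        flips = i - 1 if side == "N" else i
        inner = start_inner if flips % 2 == 0 else not start_inner
        return "inner" if inner else "outer"

    flanks = {
        key: dataclasses.replace(f, side_class=side_class(*key))
        for key, f in segmap.flanks.items()
    }
    return dataclasses.replace(
        segmap, flanks=flanks, n_terminus_side=topo.n_terminus_side
    )


def pooled_columns(segmap: LwiSegmentMap, selector) -> tuple[int, ...]:
    """Resolve a region selector to an ordered list of alignment columns.

    String selectors: ``LWI_total``, ``LWI_inner``, ``LWI_outer``,
    ``TM_total``, ``full_length``.  Tuple selectors address single regions:
    ``("flank", tm_index, "N"|"C")`` and ``("tm", tm_index)``.  Pooled LWI
    selectors deduplicate columns double-assigned by flank overlap; the
    single-flank selector keeps every column of that flank, so overlapping
    residues contribute to both adjacent flanks.
    """
    if isinstance(selector, tuple):
        kind = selector[0]
        if kind == "flank":
            _, i, side = selector
            try:
                return segmap.flanks[(i, side)].columns
            except KeyError:
                raise SelectorError(f"no flank {side}-TM{i} in segment map") from None
        if kind == "tm":
            _, i = selector
            try:
                return segmap.tm_columns[i]
            except KeyError:
                raise SelectorError(f"no TM{i} in segment map") from None
        raise SelectorError(f"unknown selector {selector!r}")

    if selector == "full_length":
        return tuple(range(1, segmap.alignment_width + 1))
    if selector == "TM_total":
        cols: set[int] = set()
        for c in segmap.tm_columns.values():
            cols.update(c)
        return tuple(sorted(cols))
    if selector in ("LWI_total", "LWI_inner", "LWI_outer"):
        wanted = {"LWI_total": None, "LWI_inner": "inner", "LWI_outer": "outer"}[
            selector
        ]
        cols = set()
        for f in segmap.flanks.values():
            if wanted is not None and f.side_class != wanted:
                if f.side_class is None:
                    raise SelectorError(
                        f"selector {selector!r} requires assign_sides() first"
                    )
                continue
            cols.update(f.columns)
        return tuple(sorted(cols))
    raise SelectorError(f"unknown selector {selector!r}")


def segment_table(segmap: LwiSegmentMap) -> pd.DataFrame:
    """BED-like table of all regions in reference coordinates, for inspection."""
    rows = []
    for i in sorted(segmap.tm_ref):
        pos = segmap.tm_ref[i]
        rows.append(
            {
                "name": f"TM{i}",
                "start": pos[0],
                "end": pos[-1],
                "side_class": "membrane",
                "n_positions": len(pos),
                "overlap_length": 0,
                "truncated": False,
            }
        )
        for side in ("N", "C"):
            f = segmap.flanks[(i, side)]
            rows.append(
                {
                    "name": f.name,
                    "start": f.ref_positions[0] if f.ref_positions else -1,
                    "end": f.ref_positions[-1] if f.ref_positions else -1,
                    "side_class": f.side_class or "unassigned",
                    "n_positions": len(f.ref_positions),
                    "overlap_length": len(f.overlap_positions),
                    "truncated": f.truncated,
                }
            )
    return pd.DataFrame(rows)
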