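"""Kullback–Leibler enrichment/depletion logos.

For each alignment column the observed amino-acid distribution ``p`` (with a
background-weighted pseudocount) is compared against a background ``q``; the
letter height is the signed per-letter KL contribution

    height_a = p_a * log2(p_a / q_a)   [bits]

so the positive stack shows letters enriched over background, the negative
stack letters depleted, and the signed heights at a position sum to the
position's KL divergence D(p || q) >= 0.  This is the standard construction
of background-referenced sequence logos.

The machine-readable height table is the primary output; a vector graphic
rendered with matplotlib is provided on a best-effort basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import (
    AMINO_ACIDS,
    GAP,
    UNKNOWN,
    BackgroundComposition,
    LabeledAlignment,
    LwiError,
)

__all__ = [
    "EnrichmentLogo",
    "column_distribution",
    "kl_logo",
    "logo_table",
    "render_logo",
]


@dataclass
class EnrichmentLogo:
    """Signed letter heights (bits) per position of a region."""

    region_name: str
    stratum: str
    positions: list[int]  # alignment columns (1-based)
    heights: list[dict[str, float]]  # per position: letter -> signed bits
    kl_divergence: list[float]  # per position, bits
    pseudocount_weight: float
    degenerate: list[bool]  # per position: no counts and no pseudocount


def column_distribution(
    aln: LabeledAlignment,
    column: int,
    stratum: str = "all",
    pseudocount_weight: float = 1.0,
    bg: BackgroundComposition | None = None,
) -> dict[str, float]:
    """Pseudocounted amino-acid distribution at one alignment column.

    ``p_a = (count_a + w * q_a) / (n + w)`` with ``w`` the pseudocount weight
    and ``q`` the background; gaps and X are excluded from counts and ``n``.
    ``w = 0`` returns the raw empirical distribution (empty columns then have
    no distribution and raise).
    """
    if not 1 <= column <= aln.width:
        raise LwiError(f"column {column} outside alignment width {aln.width}")
    if pseudocount_weight < 0:
        raise LwiError("pseudocount_weight must be non-negative")
    if bg is None and pseudocount_weight > 0:
        raise LwiError("a background is required when pseudocount_weight > 0")
    counts = {a: 0 for a in AMINO_ACIDS}
    for seq_id in aln.ids_for_stratum(stratum):
        ch = aln.sequence(seq_id)[column - 1]
        if ch not in (GAP, UNKNOWN):
            counts[ch] += 1
    n = sum(counts.values())
    if n == 0 and pseudocount_weight == 0:
        raise LwiError(f"column {column} is empty and pseudocount_weight is 0")
    denom = n + pseudocount_weight
    return {
        a: (counts[a] + pseudocount_weight * (bg[a] if bg else 0.0)) / denom
        for a in AMINO_ACIDS
    }


def kl_logo(
    aln: LabeledAlignment,
    columns,
    stratum: str = "all",
    bg: BackgroundComposition | None = None,
    pseudocount_weight: float = 1.0,
    region_name: str = "region",
) -> EnrichmentLogo:
    """Build the KL enrichment/depletion logo over a set of columns.

    The background must be strictly positive for every letter (guaranteed by
    :class:`BackgroundComposition`); unobserved letters contribute height 0 at
    pseudocount weight 0 by the ``p log p`` limit.  Fully-gapped columns with
    no pseudocount are flagged degenerate and carry all-zero heights.
    """
    if bg is None:
        raise LwiError("kl_logo requires a background composition")
    positions: list[int] = []
    heights: list[dict[str, float]] = []
    kls: list[float] = []
    degenerate: list[bool] = []
    for column in columns:
        column = int(column)
        try:
            p = column_distribution(aln, column, stratum, pseudocount_weight, bg)
        except LwiError as exc:
            if "empty" not in str(exc):
                raise
            positions.append(column)
            heights.append({a: 0.0 for a in AMINO_ACIDS})
            kls.append(0.0)
            degenerate.append(True)
            continue
        h = {}
        for a in AMINO_ACIDS:
            pa, qa = p[a], bg[a]
            h[a] = 0.0 if pa == 0.0 else pa * math.log2(pa / qa)
        positions.append(column)
        heights.append(h)
        kls.append(sum(h.values()))
        degenerate.append(False)
    return EnrichmentLogo(
        region_name=region_name,
        stratum=stratum,
        positions=positions,
        heights=heights,
        kl_divergence=kls,
        pseudocount_weight=pseudocount_weight,
        degenerate=degenerate,
    )


def logo_table(logos) -> pd.DataFrame:
    """Tidy table: one row per (region, stratum, position, letter)."""
    rows = []
    for logo in logos:
        for pos, h, kl in zip(logo.positions, logo.heights, logo.kl_divergence):
            for a in AMINO_ACIDS:
                rows.append(
                    {
                        "region": logo.region_name,
                        "stratum": logo.stratum,
                        "position": pos,
                        "letter": a,
                        "height_bits": h[a],
                        "kl_bits": kl,
                    }
                )
    return pd.DataFrame(rows)


_LETTER_COLOURS = {
    **{a: "#2c7fb8" for a in "AGILMPV"},  # small / aliphatic
    **{a: "#111111" for a in "FWY"},  # aromatic
    **{a: "#d7301f" for a in "KRH"},  # basic
    **{a: "#2ca25f" for a in "DE"},  # acidic
    **{a: "#8856a7" for a in "STNQC"},  # polar
}


def render_logo(logo: EnrichmentLogo, path, title: str | None = None) -> None:
    """Render a logo to a vector graphic (best effort; the TSV is canonical).

    Letters stack by |height| with the largest contribution nearest the axis,
    positive stack above zero (enrichment), negative below (depletion).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    matplotlib.rcParams["svg.hashsalt"] = "lwikit"
    font = FontProperties(family="DejaVu Sans", weight="bold")

    fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(logo.positions)), 3.2))
    top = bottom = 0.1
    for x, h in enumerate(logo.heights):
        pos_letters = sorted(
            (a for a in AMINO_ACIDS if h[a] > 0), key=lambda a: -h[a]
        )
        neg_letters = sorted(
            (a for a in AMINO_ACIDS if h[a] < 0), key=lambda a: h[a]
        )
        y = 0.0
        for a in pos_letters:
            _draw_letter(ax, a, x, y, h[a], font, PathPatch, TextPath, Affine2D)
            y += h[a]
        top = max(top, y)
        y = 0.0
        for a in neg_letters:
            y += h[a]  # negative
            _draw_letter(ax, a, x, y, -h[a], font, PathPatch, TextPath, Affine2D)
        bottom = max(bottom, -y)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xlim(-0.5, len(logo.positions) - 0.2)
    ax.set_ylim(-bottom * 1.05, top * 1.05)
    ax.set_xticks(range(len(logo.positions)))
    ax.set_xticklabels([str(p) for p in logo.positions], rotation=90, fontsize=7)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("enrichment / depletion (bits)")
    ax.set_title(title or f"{logo.region_name} [{logo.stratum}]")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def _draw_letter(ax, letter, x, y, height, font, PathPatch, TextPath, Affine2D):
    if height <= 0:
        return
    tp = TextPath((0, 0), letter, size=1.0, prop=font)
    bbox = tp.get_extents()
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(0.8 / bbox.width, height / bbox.height)
        .translate(x - 0.4, y)
    )
    ax.add_patch(
        PathPatch(
            transform.transform_path(tp),
            facecolor=_LETTER_COLOURS.get(letter, "#555555"),
            edgecolor="none",
        )
    )
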