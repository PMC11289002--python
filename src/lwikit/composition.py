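"""Amino-acid composition statistics over alignment regions.

Frequencies are pooled over every non-gap, non-X residue at the selected
columns across all sequences of a stratum (each residue one observation); a
per-sequence-then-average mode is available since either convention is
defensible for alignment-derived frequency plots.  Group totals combine the
hydrophobic/hydrophilic and charged sets, and each profile can be compared
against a "natural abundance" background to call per-letter enrichment,
depletion or outright absence.

The group memberships are deliberately the unconventional published lists
this analysis tradition uses (Val grouped hydrophilic, Cys hydrophobic, His
in both the hydrophilic and the positive set); pass
``AminoAcidScales.conventional()`` to substitute textbook sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

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
    "StratumError",
    "AminoAcidScales",
    "CompositionProfile",
    "BackgroundComparison",
    "region_frequencies",
    "grouped_profile",
    "compare_to_background",
    "mean_hydropathy",
    "region_residue_content",
    "profile_table",
    "KYTE_DOOLITTLE",
    "WIMLEY_WHITE_INTERFACE",
]


class StratumError(LwiError):
    """A requested stratum has no sequences."""


#: Kyte–Doolittle hydropathy index (positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Wimley–White interface-scale side-chain transfer free energies
#: (kcal/mol, water -> POPC interface; more negative = more favourable).
#: Used only to order letters along plot axes, never in a statistic.
WIMLEY_WHITE_INTERFACE: dict[str, float] = {
    "W": -1.85, "F": -1.13, "Y": -0.94, "L": -0.56, "I": -0.31, "C": -0.24,
    "M": -0.23, "G": 0.01, "V": 0.07, "S": 0.13, "T": 0.14, "A": 0.17,
    "N": 0.42, "P": 0.45, "Q": 0.58, "R": 0.81, "H": 0.96, "K": 0.99,
    "D": 1.23, "E": 2.02,
}


@dataclass(frozen=True)
class AminoAcidScales:
    """Group memberships and per-residue scales used by composition statistics."""

    hydrophobic_set: frozenset[str] = frozenset("YILMFCW")
    hydrophilic_set: frozenset[str] = frozenset("AGHPSTVKREDQN")
    positive_set: frozenset[str] = frozenset("RHK")
    negative_set: frozenset[str] = frozenset("DE")
    kd_scale: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    #: Letters ordered by side-chain interface transfer free energy
    #: (presentation order for plots only).
    dg_order: tuple[str, ...] = tuple(
        sorted(WIMLEY_WHITE_INTERFACE, key=WIMLEY_WHITE_INTERFACE.get)
    )
    #: Residues treated as snorkeling-capable; an annotation layer in reports,
    #: not an input to any statistic.
    snorkeling_set: frozenset[str] = frozenset("KRWY")

    def __post_init__(self) -> None:
        union = self.hydrophobic_set | self.hydrophilic_set
        if union != frozenset(AMINO_ACIDS) or (
            self.hydrophobic_set & self.hydrophilic_set
        ):
            raise LwiError(
                "hydrophobic and hydrophilic sets must partition the 20 amino acids"
            )

    @classmethod
    def conventional(cls) -> "AminoAcidScales":
        """Textbook grouping (Val hydrophobic, Cys special-cased hydrophilic)."""
        return cls(
            hydrophobic_set=frozenset("AVILMFWY"),
            hydrophilic_set=frozenset("GSTCNQDEKRHP"),
        )


@dataclass
class CompositionProfile:
    """Amino-acid counts/frequencies for one region and stratum.

    ``n_residues`` excludes gaps and X.  ``group_totals`` and ``ratios`` are
    empty until :func:`grouped_profile` fills them.  ``degenerate`` marks an
    empty residue pool (frequencies undefined).
    """

    region_name: str
    stratum: str
    counts: dict[str, int]
    n_residues: int
    frequency: dict[str, float]
    group_totals: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    mean_hydropathy: float | None = None
    degenerate: bool = False
    pooling: str = "residues"

    def freq(self, letter: str) -> float:
        return self.frequency.get(letter, 0.0)


class BackgroundComparison(NamedTuple):
    observed: float
    expected: float
    log2_ratio: float  # -inf when observed == 0
    direction: str  # "enriched" / "depleted" / "absent" / "equal"


def region_frequencies(
    aln: LabeledAlignment,
    columns,
    stratum: str = "all",
    region_name: str = "region",
    pooling: str = "residues",
) -> CompositionProfile:
    """Pool amino-acid counts at the given alignment columns over a stratum.

    ``pooling="residues"`` counts every residue as one observation;
    ``pooling="per_sequence"`` averages per-sequence frequency vectors so each
    species contributes equally regardless of gap content.
    """
    ids = aln.ids_for_stratum(stratum)
    if not ids:
        raise StratumError(f"stratum {stratum!r} has no sequences")
    width = aln.width
    cols = [int(c) for c in columns]
    for c in cols:
        if not 1 <= c <= width:
            raise LwiError(f"column {c} outside alignment width {width}")

    counts = {a: 0 for a in AMINO_ACIDS}
    per_seq_freqs = []
    for seq_id in ids:
        seq = aln.sequence(seq_id)
        local = {a: 0 for a in AMINO_ACIDS}
        for c in cols:
            ch = seq[c - 1]
            if ch not in (GAP, UNKNOWN):
                local[ch] += 1
        n_local = sum(local.values())
        if n_local:
            per_seq_freqs.append({a: local[a] / n_local for a in AMINO_ACIDS})
        for a in AMINO_ACIDS:
            counts[a] += local[a]

    n = sum(counts.values())
    if pooling == "residues":
        frequency = {a: counts[a] / n for a in AMINO_ACIDS} if n else {}
    elif pooling == "per_sequence":
        m = len(per_seq_freqs)
        frequency = (
            {a: sum(f[a] for f in per_seq_freqs) / m for a in AMINO_ACIDS} if m else {}
        )
    else:
        raise LwiError(f"unknown pooling mode {pooling!r}")

    return CompositionProfile(
        region_name=region_name,
        stratum=stratum,
        counts=counts,
        n_residues=n,
        frequency=frequency,
        degenerate=(n == 0),
        pooling=pooling,
    )


def grouped_profile(
    profile: CompositionProfile, scales: AminoAcidScales | None = None
) -> CompositionProfile:
    """Fill hydrophobic/hydrophilic and charge group totals plus their ratios.

    The hydrophilic total is the exact complement of the hydrophobic total, so
    the two always sum to 1 for a non-degenerate profile.  A zero denominator
    yields ``inf``; 0/0 yields ``nan`` (the "undefined" flag).
    """
    scales = scales or AminoAcidScales()
    out = CompositionProfile(**{**profile.__dict__})
    if profile.degenerate:
        return out
    hydrophobic = sum(profile.freq(a) for a in scales.hydrophobic_set)
    positive = sum(profile.freq(a) for a in scales.positive_set)
    negative = sum(profile.freq(a) for a in scales.negative_set)
    out.group_totals = {
        "hydrophobic": hydrophobic,
        "hydrophilic": 1.0 - hydrophobic,
        "positive": positive,
        "negative": negative,
    }
    out.ratios = {
        "positive_to_negative": _ratio(positive, negative),
        "hydrophobic_to_hydrophilic": _ratio(hydrophobic, 1.0 - hydrophobic),
    }
    out.mean_hydropathy = mean_hydropathy(profile, scales)
    return out


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


def compare_to_background(
    profile: CompositionProfile, bg: BackgroundComposition
) -> dict[str, BackgroundComparison]:
    """Per-letter observed vs expected frequency with an enrichment call.

    Direction is ``absent`` when the letter is never observed, ``enriched`` /
    ``depleted`` by the sign of observed − expected, and ``equal`` on exact
    ties.  The log2 ratio is ``-inf`` for absent letters.
    """
    if profile.degenerate:
        raise LwiError(
            f"profile {profile.region_name}/{profile.stratum} is degenerate"
        )
    out: dict[str, BackgroundComparison] = {}
    for a in AMINO_ACIDS:
        observed = profile.freq(a)
        expected = bg[a]
        if observed == 0.0:
            direction, log2_ratio = "absent", -math.inf
        elif observed > expected:
            direction, log2_ratio = "enriched", math.log2(observed / expected)
        elif observed < expected:
            direction, log2_ratio = "depleted", math.log2(observed / expected)
        else:
            direction, log2_ratio = "equal", 0.0
        out[a] = BackgroundComparison(observed, expected, log2_ratio, direction)
    return out


def mean_hydropathy(
    profile: CompositionProfile, scales: AminoAcidScales | None = None
) -> float:
    """Frequency-weighted mean Kyte–Doolittle hydropathy of a profile."""
    scales = scales or AminoAcidScales()
    if profile.degenerate:
        return math.nan
    return sum(profile.freq(a) * scales.kd_scale[a] for a in AMINO_ACIDS)


def region_residue_content(
    aln: LabeledAlignment, columns, letter: str, stratum: str = "all"
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-sequence proportion of one residue in a region, with a summary.

    Returns ``(per_sequence, summary)`` where ``per_sequence`` maps sequence
    id to the proportion of ``letter`` among its non-gap, non-X characters at
    the given columns, and ``summary`` holds the stratum mean/min/max and the
    number of fully-gapped sequences excluded.
    """
    letter = letter.upper()
    if letter not in AMINO_ACIDS:
        raise LwiError(f"{letter!r} is not an amino-acid letter")
    cols = [int(c) for c in columns]
    if not cols:
        raise LwiError("region has no columns")
    ids = aln.ids_for_stratum(stratum)
    if not ids:
        raise StratumError(f"stratum {stratum!r} has no sequences")
    per_sequence: dict[str, float] = {}
    excluded = 0
    for seq_id in ids:
        seq = aln.sequence(seq_id)
        chars = [seq[c - 1] for c in cols]
        informative = [ch for ch in chars if ch not in (GAP, UNKNOWN)]
        if not informative:
            excluded += 1
            continue
        per_sequence[seq_id] = informative.count(letter) / len(informative)
    values = list(per_sequence.values())
    summary = {
        "mean": sum(values) / len(values) if values else math.nan,
        "min": min(values) if values else math.nan,
        "max": max(values) if values else math.nan,
        "n_sequences": float(len(values)),
        "n_excluded": float(excluded),
    }
    return per_sequence, summary


def profile_table(
    profiles, bg: BackgroundComposition | None = None
) -> pd.DataFrame:
    """Tidy TSV-ready table: one row per (region, stratum, letter)."""
    rows = []
    for profile in profiles:
        comparison = (
            compare_to_background(profile, bg)
            if bg is not None and not profile.degenerate
            else None
        )
        for a in AMINO_ACIDS:
            row = {
                "region": profile.region_name,
                "stratum": profile.stratum,
                "letter": a,
                "count": profile.counts.get(a, 0),
                "frequency": profile.freq(a) if not profile.degenerate else math.nan,
                "n_residues": profile.n_residues,
            }
            if comparison is not None:
                cmp_row = comparison[a]
                row["background"] = cmp_row.expected
                row["log2_ratio"] = cmp_row.log2_ratio
                row["direction"] = cmp_row.direction
            rows.append(row)
    return pd.DataFrame(rows)
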