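"""Chi-square testing, length summaries, and the end-to-end pipeline.

``run_pipeline`` glues the stages together: read inputs, derive the LWI
segment map, compute stratified composition profiles and group ratios,
p-distance conservation summaries with bootstrap variances, KL logos,
chi-square independence reports and per-phylum length summaries, and write
everything as TSV (plus a JSON run manifest) into an output directory.
Given identical inputs and seed the machine-readable outputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import composition as comp
from . import conservation as cons
from . import logo as logo_mod
from . import segments as seg
from .io import (
    LabeledAlignment,
    LwiError,
    ReferenceTopology,
    load_background,
    read_labeled_alignment,
    read_topology,
)

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "DegenerateTableError",
    "ConfigError",
    "LengthSummary",
    "chi_square_independence",
    "build_group_contingency",
    "summarize_lengths",
    "run_pipeline",
]

logger = logging.getLogger("lwikit")

_FLOAT_FORMAT = "%.10g"


class DegenerateTableError(LwiError):
    """A contingency table has an all-zero row or column."""


class ConfigError(LwiError):
    """The pipeline configuration is missing a key or names a bad file."""


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.column_labels)):
            raise LwiError("counts shape does not match labels")
        if (counts < 0).any():
            raise LwiError("contingency counts must be non-negative")
        object.__setattr__(self, "counts", counts)


class ChiSquareResult(NamedTuple):
    statistic: float
    dof: int
    p_value: float


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts come from the table margins; dof = (r-1)(c-1).  A table
    with an all-zero row or column (or fewer than 2 rows/columns) is
    degenerate and raises rather than returning a meaningless statistic.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise DegenerateTableError(
            f"need at least a 2x2 table, got shape {counts.shape}"
        )
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    statistic, p_value, dof, _ = scipy.stats.chi2_contingency(
        counts, correction=False
    )
    return ChiSquareResult(float(statistic), int(dof), float(p_value))


def build_group_contingency(profiles, mode: str = "letters_x_regions") -> ContingencyTable:
    """Assemble a letters-by-category count table from composition profiles.

    ``letters_x_regions`` requires all profiles to share a stratum and uses
    region names as columns; ``letters_x_strata`` requires a shared region
    and uses strata as columns.  All-zero letter rows are dropped (they carry
    no information and would degenerate the test).
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise DegenerateTableError("need at least two profiles to build a table")
    if mode == "letters_x_regions":
        strata = {p.stratum for p in profiles}
        if len(strata) != 1:
            raise LwiError(f"profiles span several strata {sorted(strata)}")
        columns = [p.region_name for p in profiles]
    elif mode == "letters_x_strata":
        regions = {p.region_name for p in profiles}
        if len(regions) != 1:
            raise LwiError(f"profiles span several regions {sorted(regions)}")
        columns = [p.stratum for p in profiles]
    else:
        raise LwiError(f"unknown contingency mode {mode!r}")
    if len(set(columns)) != len(columns):
        raise LwiError(f"duplicate column labels {columns}")

    from .io import AMINO_ACIDS

    counts = np.array(
        [[p.counts.get(a, 0) for p in profiles] for a in AMINO_ACIDS], dtype=int
    )
    keep = counts.sum(axis=1) > 0
    return ContingencyTable(
        row_labels=tuple(a for a, k in zip(AMINO_ACIDS, keep) if k),
        column_labels=tuple(columns),
        counts=counts[keep],
    )


@dataclass
class LengthSummary:
    """Per-sequence lengths plus a per-stratum summary table."""

    per_sequence: pd.DataFrame  # sequence_id, species, phylum, lengths
    per_stratum: pd.DataFrame  # stratum, n, median/min/max of each length


def summarize_lengths(aln: LabeledAlignment, topo: ReferenceTopology) -> LengthSummary:
    """Ungapped sequence lengths and the N-terminal tail proxy per stratum.

    The tail proxy for each sequence is its number of non-gap characters in
    the alignment columns preceding the first TM1 column of the reference —
    reference-anchored, so insertions within the reference's N-tail region
    count toward every species' tail.
    """
    segmap = seg.extract_segments(aln, topo)
    tm1_first_col = segmap.tm_columns[1][0]
    rows = []
    for seq_id, seq in aln.records:
        meta = aln.metadata[seq_id]
        ungapped = sum(1 for ch in seq if ch != "-")
        n_tail = sum(1 for ch in seq[: tm1_first_col - 1] if ch != "-")
        rows.append(
            {
                "sequence_id": seq_id,
                "species": meta.species,
                "phylum": meta.phylum,
                "ungapped_length": ungapped,
                "n_tail_length": n_tail,
            }
        )
    per_sequence = pd.DataFrame(rows)
    summaries = []
    for stratum in aln.strata():
        sub = per_sequence[per_sequence["phylum"] == stratum]
        if sub.empty:
            logger.warning("stratum %s empty; omitted from length summary", stratum)
            continue
        summaries.append(
            {
                "stratum": stratum,
                "n_sequences": len(sub),
                "median_length": float(sub["ungapped_length"].median()),
                "min_length": int(sub["ungapped_length"].min()),
                "max_length": int(sub["ungapped_length"].max()),
                "median_n_tail": float(sub["n_tail_length"].median()),
                "min_n_tail": int(sub["n_tail_length"].min()),
                "max_n_tail": int(sub["n_tail_length"].max()),
            }
        )
    return LengthSummary(per_sequence, pd.DataFrame(summaries))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("alignment", "metadata", "topology", "seed", "out_dir")

_POOLED_REGIONS = ("full_length", "TM_total", "LWI_total", "LWI_inner", "LWI_outer")


def run_pipeline(config) -> Path:
    """Run every stage on one input bundle and write the output tree.

    ``config`` is a dict or a YAML file path with keys ``alignment``,
    ``metadata``, ``topology``, ``seed``, ``out_dir`` and the optional knobs
    ``background`` (default packaged table), ``flank_width``,
    ``bootstrap_reps`` (default 1000), ``deletion_mode``, ``pseudocount``,
    ``pooling``, ``contingency_mode``, ``max_gap_fraction``, ``render``.
    Outputs are deterministic given identical inputs and seed.
    """
    if not isinstance(config, dict):
        with open(config) as handle:
            config = yaml.safe_load(handle)
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise ConfigError(f"pipeline config missing key {key!r}")
    for key in ("alignment", "metadata", "topology"):
        if not Path(config[key]).exists():
            raise ConfigError(f"config key {key!r} names missing file {config[key]}")

    seed = int(config["seed"])
    bootstrap_reps = int(config.get("bootstrap_reps", 1000))
    deletion = config.get("deletion_mode", "complete")
    pseudocount = float(config.get("pseudocount", 1.0))
    pooling = config.get("pooling", "residues")
    contingency_mode = config.get("contingency_mode", "letters_x_regions")
    max_gap_fraction = float(config.get("max_gap_fraction", 0.5))
    render = bool(config.get("render", False))

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        t0 = time.perf_counter()

        def done():
            logger.info("stage %-12s %6.2f s", name, time.perf_counter() - t0)

        return done

    done = stage("load")
    aln = read_labeled_alignment(config["alignment"], config["metadata"])
    topo = read_topology(config["topology"])
    if "flank_width" in config:
        topo = ReferenceTopology(
            reference_id=topo.reference_id,
            tm_intervals=topo.tm_intervals,
            n_terminus_side=topo.n_terminus_side,
            flank_width=int(config["flank_width"]),
        )
    bg = load_background(config.get("background", "swissprot"))
    done()

    done = stage("extract")
    segmap = seg.assign_sides(seg.extract_segments(aln, topo), topo)
    _write(seg.segment_table(segmap), out_dir / "segments.tsv")
    done()

    strata = ["all"] + aln.strata()
    selectors: list[tuple[str, object]] = [(name, name) for name in _POOLED_REGIONS]
    selectors += [
        (f"{side}-TM{i}", ("flank", i, side))
        for i in sorted(segmap.tm_ref)
        for side in ("N", "C")
    ]
    selectors += [(f"TM{i}", ("tm", i)) for i in sorted(segmap.tm_ref)]

    done = stage("compose")
    scales = comp.AminoAcidScales()
    profiles = []
    grouped_rows = []
    for stratum in strata:
        for name, selector in selectors:
            cols = seg.pooled_columns(segmap, selector)
            profile = comp.region_frequencies(
                aln, cols, stratum=stratum, region_name=name, pooling=pooling
            )
            profiles.append(profile)
            if profile.degenerate:
                continue
            g = comp.grouped_profile(profile, scales)
            grouped_rows.append(
                {
                    "region": name,
                    "stratum": stratum,
                    "n_residues": g.n_residues,
                    "hydrophobic": g.group_totals["hydrophobic"],
                    "hydrophilic": g.group_totals["hydrophilic"],
                    "positive": g.group_totals["positive"],
                    "negative": g.group_totals["negative"],
                    "positive_to_negative": g.ratios["positive_to_negative"],
                    "hydrophobic_to_hydrophilic": g.ratios[
                        "hydrophobic_to_hydrophilic"
                    ],
                    "mean_hydropathy": g.mean_hydropathy,
                }
            )
    _write(comp.profile_table(profiles, bg), out_dir / "composition.tsv")
    _write(pd.DataFrame(grouped_rows), out_dir / "group_ratios.tsv")
    done()

    done = stage("conserve")
    summaries = []
    skipped = []
    for stratum in strata:
        for name, selector in selectors:
            cols = seg.pooled_columns(segmap, selector)
            try:
                summaries.append(
                    cons.region_distance_summary(
                        aln,
                        cols,
                        stratum=stratum,
                        region_name=name,
                        deletion=deletion,
                        bootstrap_reps=bootstrap_reps,
                        seed=seed,
                        max_gap_fraction=max_gap_fraction,
                    )
                )
            except cons.InsufficientDataError as exc:
                skipped.append({"region": name, "stratum": stratum, "reason": str(exc)})
    _write(cons.compare_regions(summaries), out_dir / "distance_summary.tsv")
    dropped_rows = [
        {"region": s.region_name, "stratum": s.stratum, "sequence_id": sid,
         "reason": reason}
        for s in summaries
        for sid, reason in s.dropped_sequences
    ] + [dict(r, sequence_id="") for r in skipped]
    _write(
        pd.DataFrame(dropped_rows, columns=["region", "stratum", "sequence_id", "reason"]),
        out_dir / "dropped_sequences.tsv",
    )
    done()

    done = stage("logo")
    logos = []
    for stratum in strata:
        for i in sorted(segmap.tm_ref):
            for side in ("N", "C"):
                cols = segmap.flanks[(i, side)].columns
                if not cols:
                    continue
                logos.append(
                    logo_mod.kl_logo(
                        aln, cols, stratum=stratum, bg=bg,
                        pseudocount_weight=pseudocount,
                        region_name=f"{side}-TM{i}",
                    )
                )
    _write(logo_mod.logo_table(logos), out_dir / "logo_heights.tsv")
    if render:
        lwi_logo = logo_mod.kl_logo(
            aln,
            seg.pooled_columns(segmap, "LWI_total"),
            stratum="all",
            bg=bg,
            pseudocount_weight=pseudocount,
            region_name="LWI_total",
        )
        logo_mod.render_logo(lwi_logo, out_dir / "logo_lwi_total.svg")
    done()

    done = stage("chi_square")
    chi_rows = []
    by_key = {(p.stratum, p.region_name): p for p in profiles}
    flank_names = [
        f"{side}-TM{i}" for i in sorted(segmap.tm_ref) for side in ("N", "C")
    ]
    for stratum in strata:
        chosen = [
            by_key[(stratum, n)]
            for n in flank_names
            if not by_key[(stratum, n)].degenerate
        ]
        try:
            table = build_group_contingency(chosen, mode="letters_x_regions")
            result = chi_square_independence(table)
            chi_rows.append(
                {
                    "comparison": "letters_x_flanks",
                    "stratum": stratum,
                    "statistic": result.statistic,
                    "dof": result.dof,
                    "p_value": result.p_value,
                    "n_observations": int(table.counts.sum()),
                }
            )
        except (DegenerateTableError, LwiError) as exc:
            logger.warning("chi-square skipped for %s: %s", stratum, exc)
    phylum_profiles = [
        by_key[(s, "LWI_total")]
        for s in aln.strata()
        if not by_key[(s, "LWI_total")].degenerate
    ]
    if len(phylum_profiles) >= 2:
        table = build_group_contingency(phylum_profiles, mode="letters_x_strata")
        result = chi_square_independence(table)
        chi_rows.append(
            {
                "comparison": "letters_x_strata_LWI_total",
                "stratum": "all",
                "statistic": result.statistic,
                "dof": result.dof,
                "p_value": result.p_value,
                "n_observations": int(table.counts.sum()),
            }
        )
    _write(pd.DataFrame(chi_rows), out_dir / "chi_square.tsv")
    done()

    done = stage("lengths")
    lengths = summarize_lengths(aln, topo)
    _write(lengths.per_sequence, out_dir / "lengths_per_sequence.tsv")
    _write(lengths.per_stratum, out_dir / "lengths_summary.tsv")
    done()

    manifest = {
        "inputs": {
            "alignment": str(config["alignment"]),
            "metadata": str(config["metadata"]),
            "topology": str(config["topology"]),
            "background": str(config.get("background", "swissprot")),
        },
        "parameters": {
            "seed": seed,
            "bootstrap_reps": bootstrap_reps,
            "deletion_mode": deletion,
            "pseudocount": pseudocount,
            "pooling": pooling,
            "contingency_mode": contingency_mode,
            "max_gap_fraction": max_gap_fraction,
            "flank_width": topo.flank_width,
        },
        "alignment": {
            "n_sequences": len(aln.records),
            "width": aln.width,
            "strata": aln.strata(),
            "reference_id": topo.reference_id,
        },
        "versions": _versions(),
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return out_dir


def _versions() -> dict[str, str]:
    import Bio
    import matplotlib
    import scipy

    from . import __version__

    return {
        "lwikit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "biopython": Bio.__version__,
        "matplotlib": matplotlib.__version__,
        "python": sys.version.split()[0],
    }


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
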