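"""Pairwise p-distance conservation scoring with bootstrap variance.

The conservation score of a region is the distribution of pairwise
p-distances (proportion of differing residues over compared sites) among the
sequences of a stratum, restricted to the region's alignment columns.
Scores lie in [0, 1]: 0 means identical, 1 fully diverged.  Site-to-site
rates are treated as uniform and no substitution-model correction is applied.

Gap handling follows the distance-matrix conventions of standard phylogenetic
software: a sequence mostly gapped within the analysed region is dropped
("improper" sequence, threshold configurable), after which *complete
deletion* removes every column still containing a gap or X in any retained
sequence.  Variances are estimated by bootstrap over columns (default 1000
replicates), seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GAP, UNKNOWN, LabeledAlignment, LwiError

__all__ = [
    "InsufficientDataError",
    "DistanceSummary",
    "p_distance",
    "region_distance_summary",
    "compare_regions",
    "distance_matrix",
]


class InsufficientDataError(LwiError):
    """Fewer than two sequences (or no shared columns) remain for a region."""


@dataclass
class DistanceSummary:
    """Pairwise p-distance distribution for one region and stratum."""

    region_name: str
    stratum: str
    sequence_ids: list[str]
    pair_ids: list[tuple[str, str]]
    distances: np.ndarray  # shape (n_pairs,), values in [0, 1] (nan if undefined)
    bootstrap_variances: np.ndarray  # shape (n_pairs,)
    dropped_sequences: list[tuple[str, str]] = field(default_factory=list)
    deletion_mode: str = "complete"
    n_columns_used: int = 0
    bootstrap_reps: int = 0
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def p_distance(seq_a: str, seq_b: str, columns=None) -> float:
    """Proportion of mismatches between two aligned sequences.

    Only *pairwise complete* positions are compared: columns where both
    sequences carry a non-gap, non-X character.  Returns ``nan`` when no
    position is comparable (degenerate pair — flagged, not raised).
    """
    if len(seq_a) != len(seq_b):
        raise LwiError("sequences must have equal aligned length")
    if columns is None:
        idx = range(len(seq_a))
    else:
        idx = [int(c) - 1 for c in columns]
        for i in idx:
            if not 0 <= i < len(seq_a):
                raise LwiError(f"column {i + 1} outside alignment width {len(seq_a)}")
    compared = 0
    mismatches = 0
    for i in idx:
        a, b = seq_a[i], seq_b[i]
        if a in (GAP, UNKNOWN) or b in (GAP, UNKNOWN):
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        return float("nan")
    return mismatches / compared


def region_distance_summary(
    aln: LabeledAlignment,
    columns,
    stratum: str = "all",
    region_name: str = "region",
    deletion: str = "complete",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    max_gap_fraction: float = 0.5,
) -> DistanceSummary:
    """All pairwise p-distances over a region, with bootstrap variances.

    Sequences whose region is more than ``max_gap_fraction`` gaps/X are
    dropped and listed (entirely-gapped sequences always are).  With
    ``deletion="complete"`` every column containing a gap or X in any
    retained sequence is removed before distances are computed; with
    ``"pairwise"`` each pair uses its own complete positions.  The bootstrap
    resamples the retained columns with replacement; the recorded statistic
    is the per-pair variance of the replicate distances.
    """
    if deletion not in ("complete", "pairwise"):
        raise LwiError(f"unknown deletion mode {deletion!r}")
    ids = aln.ids_for_stratum(stratum)
    cols = np.asarray([int(c) for c in columns], dtype=int)
    if cols.size == 0:
        raise InsufficientDataError("region has no columns")
    matrix = aln.to_matrix(ids)[:, cols - 1]
    missing = (matrix == GAP) | (matrix == UNKNOWN)

    dropped: list[tuple[str, str]] = []
    keep: list[int] = []
    for row, seq_id in enumerate(ids):
        frac = missing[row].mean()
        if frac == 1.0:
            dropped.append((seq_id, "region entirely gapped"))
        elif frac > max_gap_fraction:
            dropped.append(
                (seq_id, f"gap fraction {frac:.2f} exceeds {max_gap_fraction}")
            )
        else:
            keep.append(row)
    if len(keep) < 2:
        raise InsufficientDataError(
            f"fewer than 2 sequences retained for {region_name!r}/{stratum!r}"
        )
    retained_ids = [ids[r] for r in keep]
    matrix = matrix[keep]
    missing = missing[keep]

    if deletion == "complete":
        col_ok = ~missing.any(axis=0)
        if not col_ok.any():
            raise InsufficientDataError(
                f"complete deletion removed every column of {region_name!r}/{stratum!r}"
            )
        matrix = matrix[:, col_ok]
        missing = missing[:, col_ok]

    n, m = matrix.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pair_ids = [(retained_ids[i], retained_ids[j]) for i, j in pairs]

    # mismatch / validity indicators per pair and column
    mism = np.empty((len(pairs), m), dtype=bool)
    valid = np.empty((len(pairs), m), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        ok = ~(missing[i] | missing[j])
        valid[k] = ok
        mism[k] = ok & (matrix[i] != matrix[j])
    compared = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        distances = np.where(
            compared > 0, mism.sum(axis=1) / compared, np.nan
        ).astype(np.float64)

    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        sample_counts = np.empty((m, bootstrap_reps), dtype=np.float32)
        for b in range(bootstrap_reps):
            draw = rng.integers(0, m, size=m)
            sample_counts[:, b] = np.bincount(draw, minlength=m)
        rep_mism = mism.astype(np.float32) @ sample_counts
        rep_valid = valid.astype(np.float32) @ sample_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            rep_dist = np.where(rep_valid > 0, rep_mism / rep_valid, np.nan)
        variances = np.nanvar(rep_dist.astype(np.float64), axis=1)
    else:
        variances = np.full(len(pairs), np.nan)

    return DistanceSummary(
        region_name=region_name,
        stratum=stratum,
        sequence_ids=retained_ids,
        pair_ids=pair_ids,
        distances=distances,
        bootstrap_variances=variances,
        dropped_sequences=dropped,
        deletion_mode=deletion,
        n_columns_used=m,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )


def compare_regions(summaries) -> pd.DataFrame:
    """Boxplot statistics per region and stratum (median, quartiles, extremes).

    Regions sharing a stratum are ranked by median distance; exact ties get
    the same rank and are reported as ties.
    """
    rows = []
    for s in summaries:
        vals = s.distances[~np.isnan(s.distances)]
        if vals.size == 0:
            continue
        rows.append(
            {
                "region": s.region_name,
                "stratum": s.stratum,
                "n_pairs": int(vals.size),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "mean_bootstrap_variance": float(np.nanmean(s.bootstrap_variances))
                if s.bootstrap_reps
                else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["median_rank"] = (
        table.groupby("stratum")["median"].rank(method="min").astype(int)
    )
    return table.sort_values(["stratum", "median_rank", "region"]).reset_index(
        drop=True
    )


def distance_matrix(summary: DistanceSummary, lower_triangle: bool = False):
    """Square (or lower-triangle) p-distance matrix as a DataFrame."""
    ids = summary.sequence_ids
    n = len(ids)
    mat = np.zeros((n, n))
    index = {sid: k for k, sid in enumerate(ids)}
    for (a, b), d in zip(summary.pair_ids, summary.distances):
        i, j = index[a], index[b]
        mat[i, j] = mat[j, i] = d
    frame = pd.DataFrame(mat, index=ids, columns=ids)
    if lower_triangle:
        mask = np.triu(np.ones_like(mat, dtype=bool), k=0)
        frame = frame.mask(mask)
    return frame
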