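"""Readers, writers and coordinate mapping for labeled membrane-protein alignments.

The pipeline consumes three kinds of input: an aligned FASTA of homologous
sequences, a TSV metadata table assigning each sequence a species and a
vertebrate phylum group, and a small YAML topology file that places the
transmembrane (TM) segments on one named reference sequence in ungapped,
1-based residue coordinates.  Everything downstream works in alignment-column
space, so the key operation here is :func:`map_reference_to_columns`.

All user-facing coordinates are 1-based and inclusive, matching residue
numbering conventions (e.g. "Ser579").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "UNKNOWN",
    "PHYLA",
    "LwiError",
    "AlignmentShapeError",
    "MetadataError",
    "SequenceParseError",
    "CompositionError",
    "TopologyError",
    "SeqMeta",
    "LabeledAlignment",
    "ReferenceTopology",
    "BackgroundComposition",
    "read_labeled_alignment",
    "write_labeled_alignment",
    "map_reference_to_columns",
    "read_topology",
    "write_topology",
    "load_background",
]

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: Vertebrate phylum groups used for stratified outputs.
PHYLA = ("mammal", "bird", "reptile", "amphibian", "fish")

_ALLOWED_CHARS = frozenset(AMINO_ACIDS + GAP + UNKNOWN)


class LwiError(ValueError):
    """Base class for all input-validation errors raised by this package."""


class AlignmentShapeError(LwiError):
    """Sequences in an alignment do not all have the same length."""


class MetadataError(LwiError):
    """Metadata table is missing entries or contains unknown phylum labels."""


class SequenceParseError(LwiError):
    """A sequence contains a character outside the amino-acid alphabet."""


class CompositionError(LwiError):
    """A background composition table is incomplete or badly normalised."""


class TopologyError(LwiError):
    """A reference topology is inconsistent with itself or the alignment."""


@dataclass(frozen=True)
class SeqMeta:
    species: str
    phylum: str


@dataclass
class LabeledAlignment:
    """A multiple sequence alignment with per-sequence species/phylum labels.

    Parameters
    ----------
    records
        Ordered ``(sequence_id, aligned_sequence)`` pairs.  Aligned sequences
        use uppercase one-letter amino-acid codes, ``X`` for unknown residues
        and ``-`` for gaps; all must have identical length.
    metadata
        Mapping from sequence id to :class:`SeqMeta`.  Every record must have
        an entry and the phylum must be one of :data:`PHYLA`.
    """

    records: list[tuple[str, str]]
    metadata: dict[str, SeqMeta]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment has no records")
        width = len(self.records[0][1])
        seen: set[str] = set()
        for seq_id, seq in self.records:
            if seq_id in seen:
                raise MetadataError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            if len(seq) != width:
                raise AlignmentShapeError(
                    f"sequence {seq_id!r} has length {len(seq)}, expected {width}"
                )
            for col, ch in enumerate(seq, start=1):
                if ch not in _ALLOWED_CHARS:
                    raise SequenceParseError(
                        f"illegal character {ch!r} in record {seq_id!r} at column {col}"
                    )
            if seq_id not in self.metadata:
                raise MetadataError(f"metadata missing entry for sequence {seq_id!r}")
        for seq_id, meta in self.metadata.items():
            if meta.phylum not in PHYLA:
                raise MetadataError(
                    f"unknown phylum {meta.phylum!r} for sequence {seq_id!r}; "
                    f"expected one of {PHYLA}"
                )
        self._by_id = dict(self.records)

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [seq_id for seq_id, _ in self.records]

    def sequence(self, seq_id: str) -> str:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def strata(self) -> list[str]:
        """Phylum groups present, in :data:`PHYLA` order."""
        present = {m.phylum for m in self.metadata.values()}
        return [p for p in PHYLA if p in present]

    def ids_for_stratum(self, stratum: str) -> list[str]:
        """Sequence ids in a phylum group, or all ids for stratum ``"all"``."""
        if stratum == "all":
            return self.ids
        if stratum not in PHYLA:
            raise MetadataError(f"unknown stratum {stratum!r}")
        return [i for i in self.ids if self.metadata[i].phylum == stratum]

    def to_matrix(self, ids: Iterable[str] | None = None):
        """Character matrix (rows = sequences, columns = alignment columns)."""
        import numpy as np

        chosen = list(ids) if ids is not None else self.ids
        return np.array([list(self.sequence(i)) for i in chosen], dtype="<U1")


@dataclass(frozen=True)
class ReferenceTopology:
    """TM segment placement on an ungapped reference sequence.

    ``tm_intervals`` are 1-based inclusive ``(start, end)`` pairs in ungapped
    reference coordinates, sorted and non-overlapping.  ``n_terminus_side``
    records on which membrane side the N-terminus sits and drives the
    inner/outer classification of the flanking lipid-water-interface regions.
    """

    reference_id: str
    tm_intervals: tuple[tuple[int, int], ...]
    n_terminus_side: str = "inner"
    flank_width: int = 5

    def __post_init__(self) -> None:
        if self.n_terminus_side not in ("inner", "outer"):
            raise TopologyError(
                f"n_terminus_side must be 'inner' or 'outer', got {self.n_terminus_side!r}"
            )
        if self.flank_width < 1:
            raise TopologyError("flank_width must be a positive integer")
        object.__setattr__(self, "tm_intervals", tuple(map(tuple, self.tm_intervals)))
        prev_end = 0
        for start, end in self.tm_intervals:
            if start > end:
                raise TopologyError(f"TM interval ({start}, {end}) has start > end")
            if start <= prev_end:
                raise TopologyError("TM intervals must be sorted and non-overlapping")
            if start < 1:
                raise TopologyError("TM coordinates must be >= 1")
            prev_end = end

    @property
    def n_tm(self) -> int:
        return len(self.tm_intervals)

    def validate_against(self, aln: LabeledAlignment) -> None:
        """Check the reference exists and all TM coordinates fit inside it."""
        if self.reference_id not in aln.ids:
            raise TopologyError(f"reference {self.reference_id!r} not in alignment")
        ungapped = len(aln.sequence(self.reference_id).replace(GAP, ""))
        for start, end in self.tm_intervals:
            if end > ungapped:
                raise TopologyError(
                    f"TM interval ({start}, {end}) exceeds reference length {ungapped}"
                )


@dataclass(frozen=True)
class BackgroundComposition:
    """A "natural abundance" amino-acid frequency baseline.

    Exactly 20 entries, each in (0, 1), summing to 1 within 1e-9.
    """

    frequency: Mapping[str, float]

    def __post_init__(self) -> None:
        freq = dict(self.frequency)
        missing = sorted(set(AMINO_ACIDS) - set(freq))
        extra = sorted(set(freq) - set(AMINO_ACIDS))
        if missing or extra:
            raise CompositionError(
                f"background must cover exactly the 20 amino acids; "
                f"missing {missing}, unexpected {extra}"
            )
        for letter, value in freq.items():
            if not 0.0 < value < 1.0:
                raise CompositionError(
                    f"background frequency for {letter} is {value}; must be in (0, 1)"
                )
        total = sum(freq.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"background frequencies sum to {total}, not 1")
        object.__setattr__(self, "frequency", freq)

    def __getitem__(self, letter: str) -> float:
        return self.frequency[letter]

    def as_array(self, order: str = AMINO_ACIDS):
        import numpy as np

        return np.array([self.frequency[a] for a in order])


def read_labeled_alignment(fasta_path, metadata_path) -> LabeledAlignment:
    """Read an aligned FASTA plus its TSV metadata into a :class:`LabeledAlignment`.

    The metadata table must have a header with columns ``sequence_id``,
    ``species`` and ``phylum``; extra metadata rows not present in the FASTA
    are ignored, but every FASTA record must be covered.  Record order is
    preserved from the FASTA file.
    """
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    metadata = _read_metadata(metadata_path)
    relevant = {rid: metadata[rid] for rid, _ in records if rid in metadata}
    return LabeledAlignment(records=records, metadata=relevant)


def _read_metadata(path) -> dict[str, SeqMeta]:
    text = Path(path).read_text().splitlines()
    if not text:
        raise MetadataError(f"metadata file {path} is empty")
    header = text[0].rstrip("\n").split("\t")
    required = ("sequence_id", "species", "phylum")
    try:
        idx = {name: header.index(name) for name in required}
    except ValueError as exc:
        raise MetadataError(
            f"metadata header must contain columns {required}, got {header}"
        ) from exc
    out: dict[str, SeqMeta] = {}
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(header):
            raise MetadataError(f"metadata line {lineno} has too few columns")
        seq_id = parts[idx["sequence_id"]]
        out[seq_id] = SeqMeta(
            species=parts[idx["species"]], phylum=parts[idx["phylum"]]
        )
    return out


def write_labeled_alignment(aln: LabeledAlignment, fasta_path, metadata_path) -> None:
    """Write the alignment back to aligned FASTA + TSV (round-trip safe)."""
    seq_records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in aln.records
    ]
    with open(fasta_path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")
    with open(metadata_path, "w") as handle:
        handle.write("sequence_id\tspecies\tphylum\n")
        for seq_id, _ in aln.records:
            meta = aln.metadata[seq_id]
            handle.write(f"{seq_id}\t{meta.species}\t{meta.phylum}\n")


def map_reference_to_columns(
    aln: LabeledAlignment, topo: ReferenceTopology
) -> dict[int, int]:
    """Map ungapped reference positions (1-based) to alignment columns (1-based).

    Position ``p`` maps to column ``k`` iff the reference row's ``k``-th column
    holds its ``p``-th non-gap character; the mapping is strictly increasing
    and its size equals the reference's ungapped length.
    """
    if topo.reference_id not in aln.ids:
        raise TopologyError(f"reference {topo.reference_id!r} not in alignment")
    row = aln.sequence(topo.reference_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    return mapping


def read_topology(path) -> ReferenceTopology:
    """Read a topology config (YAML key-value; ``tm`` is a list of [start, end])."""
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise TopologyError(f"topology file {path} is not a key-value mapping")
    try:
        intervals = tuple((int(s), int(e)) for s, e in cfg["tm"])
        return ReferenceTopology(
            reference_id=str(cfg["reference_id"]),
            tm_intervals=intervals,
            n_terminus_side=str(cfg.get("n_terminus_side", "inner")),
            flank_width=int(cfg.get("flank_width", 5)),
        )
    except KeyError as exc:
        raise TopologyError(f"topology file missing key {exc.args[0]!r}") from exc


def write_topology(topo: ReferenceTopology, path) -> None:
    cfg = {
        "reference_id": topo.reference_id,
        "tm": [list(iv) for iv in topo.tm_intervals],
        "n_terminus_side": topo.n_terminus_side,
        "flank_width": topo.flank_width,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(cfg, handle, sort_keys=False)


def load_background(source: str | Path = "swissprot") -> BackgroundComposition:
    """Load a background composition from a packaged name or a two-column TSV.

    ``"swissprot"`` loads the packaged proteome-average table.  A file path
    loads a TSV with columns ``amino_acid`` and ``frequency``.  Totals within
    1e-3 of 1 are renormalised; anything further off is an error.
    """
    if isinstance(source, str) and source == "swissprot":
        text = (
            resources.files("lwikit.data")
            .joinpath("background_swissprot.tsv")
            .read_text()
        )
    else:
        text = Path(source).read_text()
    freq: dict[str, float] = {}
    lines = text.splitlines()
    start = 1 if lines and lines[0].split("\t")[0] == "amino_acid" else 0
    for line in lines[start:]:
        if not line.strip():
            continue
        letter, value = line.split("\t")[:2]
        freq[letter.strip().upper()] = float(value)
    missing = sorted(set(AMINO_ACIDS) - set(freq))
    if missing:
        raise CompositionError(f"background table missing amino acids {missing}")
    total = sum(freq[a] for a in AMINO_ACIDS)
    if abs(total - 1.0) > 1e-3:
        raise CompositionError(
            f"background frequencies sum to {total}; more than 1e-3 from 1"
        )
    return BackgroundComposition({a: freq[a] / total for a in AMINO_ACIDS})
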