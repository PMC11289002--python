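"""Synthetic membrane-protein families with planted, recoverable structure.

The generator emulates the statistical shape of a multi-species alignment of
a 6-TM channel subunit: a star phylogeny over vertebrate phylum groups,
region-specific substitution rates (TM sites more constrained than the
lipid-water-interface flanks, flanks more constrained than loops), region-
specific stationary amino-acid compositions (aromatic enrichment at the
inner LWI, Cys excluded from all LWI flanks), and length-variable terminal
tails per phylum.  Every downstream module is tested against the ground
truth this module records.

Model: one ancestor sequence is drawn per region class from its stationary
distribution; each species descends independently (star tree) and at every
site, with the per-class substitution probability, replaces the residue by a
fresh draw from that site's stationary distribution.  This "substitute to
stationarity" move keeps the planted composition an exact stationary target
while pairwise distance grows with the rate, and makes the expected pairwise
distance analytically checkable:  (2 r − r²) · (1 − Σ_a p_a²)  for two
species with branch probability ``r`` over sites with composition ``p``.
Ancestor residues are laid down by a largest-remainder quota over the
stationary distribution (then shuffled), so planted compositions are hit
exactly up to integer rounding rather than fluctuating with a single
multinomial draw — on a star tree the shared ancestor would otherwise
dominate the sampling error of every pooled frequency.

Terminal tails are phylum-specific (their own ancestor, composition and
length), jittered in length per species and gap-padded into the alignment;
the TM/flank/loop core is gapless, so alignment is trivial by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AMINO_ACIDS,
    PHYLA,
    GAP,
    LabeledAlignment,
    LwiError,
    ReferenceTopology,
    SeqMeta,
    write_labeled_alignment,
    write_topology,
)

__all__ = [
    "PhylumSpec",
    "GeneratorConfig",
    "generate_family",
    "make_fixture",
    "write_bundle",
    "REGION_CLASSES",
    "CATSPER_LIKE_RATES",
    "CATSPER_LIKE_COMPOSITIONS",
]

#: Region classes in canonical order (fixed order keeps the RNG stream stable).
REGION_CLASSES = ("TM", "LWI_inner", "LWI_outer", "loop", "tail")


@dataclass(frozen=True)
class PhylumSpec:
    """One phylum group on the star tree.

    ``rate_scale`` multiplies every region-class substitution probability for
    this phylum's branches.  ``tail_composition`` overrides the ``tail``
    stationary distribution (e.g. His-rich mammalian N-tails); tails of
    different phyla are treated as non-homologous and get their own ancestor.
    """

    name: str
    n_species: int
    rate_scale: float = 1.0
    n_tail_length: int = 150
    c_tail_length: int = 80
    tail_jitter: int = 10
    tail_composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.name not in PHYLA:
            raise LwiError(f"phylum {self.name!r} not one of {PHYLA}")
        if self.n_species < 1:
            raise LwiError("n_species must be >= 1")
        if self.tail_composition is not None:
            _check_distribution(self.tail_composition, f"{self.name} tail")


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of a synthetic family: phyla, architecture, rates."""

    seed: int
    phyla: tuple[PhylumSpec, ...]
    region_rates: dict[str, float]
    region_compositions: dict[str, dict[str, float]]
    tm_count: int = 6
    tm_length: int = 21
    loop_lengths: tuple[int, ...] = (14, 12, 16, 12, 18)
    flank_width: int = 5
    n_terminus_side: str = "inner"

    def __post_init__(self) -> None:
        object.__setattr__(self, "phyla", tuple(self.phyla))
        object.__setattr__(self, "loop_lengths", tuple(self.loop_lengths))
        if len(self.loop_lengths) != self.tm_count - 1:
            raise LwiError(
                f"need {self.tm_count - 1} loop lengths, got {len(self.loop_lengths)}"
            )
        for cls in REGION_CLASSES:
            if cls not in self.region_rates:
                raise LwiError(f"region_rates missing class {cls!r}")
            if cls not in self.region_compositions:
                raise LwiError(f"region_compositions missing class {cls!r}")
            _check_distribution(self.region_compositions[cls], cls)
        for spec in self.phyla:
            for cls, rate in self.region_rates.items():
                eff = rate * spec.rate_scale
                if not 0.0 <= eff < 1.0:
                    raise LwiError(
                        f"effective rate {eff} for {cls}/{spec.name} outside [0, 1)"
                    )


def _check_distribution(dist: dict[str, float], label: str) -> None:
    bad = sorted(set(dist) - set(AMINO_ACIDS))
    if bad:
        raise LwiError(f"{label} distribution has non-amino-acid keys {bad}")
    if any(v < 0 for v in dist.values()):
        raise LwiError(f"{label} distribution has negative weights")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise LwiError(f"{label} distribution sums to {total}, not 1")


def _quota_sequence(dist: dict[str, float], length: int, rng) -> np.ndarray:
    """Length-``length`` letter array hitting ``dist`` by largest remainder."""
    letters = [a for a in AMINO_ACIDS if dist.get(a, 0.0) > 0.0]
    if not letters:
        raise LwiError("distribution has empty support")
    exact = {a: dist[a] * length for a in letters}
    counts = {a: int(np.floor(exact[a])) for a in letters}
    shortfall = length - sum(counts.values())
    by_remainder = sorted(letters, key=lambda a: (-(exact[a] - counts[a]), a))
    for a in by_remainder[:shortfall]:
        counts[a] += 1
    seq = np.array(
        [a for letter in letters for a in [letter] * counts[letter]], dtype="<U1"
    )
    rng.shuffle(seq)
    return seq


def _evolve(anc: np.ndarray, n_species: int, rates: np.ndarray, draws_by_class, rng):
    """Star-tree descent: per species and site, substitute to stationarity.

    ``rates`` is a per-site substitution probability vector; ``draws_by_class``
    maps a class label to (site index array, letter array, probability array).
    """
    block = np.tile(anc, (n_species, 1))
    mask = rng.random((n_species, anc.size)) < rates[None, :]
    for _cls, (idx, letters, probs) in draws_by_class:
        sub = mask[:, idx]
        count = int(sub.sum())
        if count:
            fresh = rng.choice(letters, size=count, p=probs)
            sub_block = block[:, idx]
            sub_block[sub] = fresh
            block[:, idx] = sub_block
    return block


def _core_layout(cfg: GeneratorConfig):
    """Label every core position TM / LWI_inner / LWI_outer / loop.

    The core spans one flank width before TM1 through one flank width after
    the last TM; loops shorter than twice the flank width make the facing
    flanks share positions (same membrane side by parity), which simply means
    those positions are LWI.
    """
    w = cfg.flank_width
    side0 = cfg.n_terminus_side
    flip = {"inner": "outer", "outer": "inner"}

    labels: list[str] = []
    tm_intervals_core: list[tuple[int, int]] = []
    labels.extend([f"LWI_{side0}"] * w)  # N-flank of TM1
    side = side0
    for i in range(cfg.tm_count):
        start = len(labels) + 1
        labels.extend(["TM"] * cfg.tm_length)
        tm_intervals_core.append((start, len(labels)))
        side = flip[side]
        if i < cfg.tm_count - 1:
            length = cfg.loop_lengths[i]
            loop = ["loop"] * length
            for k in range(min(w, length)):  # C-flank of TM i+1
                loop[k] = f"LWI_{side}"
            for k in range(min(w, length)):  # N-flank of TM i+2
                loop[length - 1 - k] = f"LWI_{side}"
            labels.extend(loop)
    labels.extend([f"LWI_{side}"] * w)  # C-flank of the last TM
    return labels, tm_intervals_core


def generate_family(cfg: GeneratorConfig):
    """Generate ``(LabeledAlignment, ReferenceTopology, ground_truth)``.

    The first species of the first phylum is the reference.  The ground-truth
    record carries the true rates, compositions, per-class alignment columns
    and tail lengths so tests can score recovery.
    """
    rng = np.random.default_rng(cfg.seed)
    labels, tm_core = _core_layout(cfg)
    core_len = len(labels)
    label_arr = np.array(labels)

    core_classes = [c for c in REGION_CLASSES if c != "tail"]
    class_idx = {c: np.flatnonzero(label_arr == c) for c in core_classes}

    # ancestor core: quota draw per class, positions interleaved by layout
    anc_core = np.empty(core_len, dtype="<U1")
    for cls in core_classes:
        idx = class_idx[cls]
        if idx.size:
            anc_core[idx] = _quota_sequence(cfg.region_compositions[cls], idx.size, rng)

    core_rate = np.array([cfg.region_rates[c] for c in labels])
    draw_specs = []
    for cls in core_classes:
        idx = class_idx[cls]
        if idx.size == 0:
            continue
        dist = cfg.region_compositions[cls]
        letters = np.array([a for a in AMINO_ACIDS if dist.get(a, 0.0) > 0], dtype="<U1")
        probs = np.array([dist[a] for a in letters.tolist()])
        probs = probs / probs.sum()
        draw_specs.append((cls, (idx, letters, probs)))

    tail_rate = cfg.region_rates["tail"]
    per_phylum = []
    for spec in cfg.phyla:
        tail_dist = spec.tail_composition or cfg.region_compositions["tail"]
        core_block = _evolve(
            anc_core, spec.n_species, core_rate * spec.rate_scale, draw_specs, rng
        )
        tails = {}
        for side_len, key in ((spec.n_tail_length, "N"), (spec.c_tail_length, "C")):
            max_len = side_len + spec.tail_jitter
            anc_tail = (
                _quota_sequence(tail_dist, max_len, rng)
                if max_len
                else np.empty(0, dtype="<U1")
            )
            lengths = (
                side_len
                + rng.integers(
                    -spec.tail_jitter, spec.tail_jitter + 1, size=spec.n_species
                )
                if side_len
                else np.zeros(spec.n_species, dtype=int)
            )
            letters = np.array(
                [a for a in AMINO_ACIDS if tail_dist.get(a, 0.0) > 0], dtype="<U1"
            )
            probs = np.array([tail_dist[a] for a in letters.tolist()])
            probs = probs / probs.sum()
            evolved = (
                _evolve(
                    anc_tail,
                    spec.n_species,
                    np.full(max_len, tail_rate * spec.rate_scale),
                    [("tail", (np.arange(max_len), letters, probs))],
                    rng,
                )
                if max_len
                else np.empty((spec.n_species, 0), dtype="<U1")
            )
            tails[key] = (evolved, lengths)
        per_phylum.append((spec, core_block, tails))

    all_n_lengths = [
        int(l) for _, _, tails in per_phylum for l in tails["N"][1]
    ]
    all_c_lengths = [
        int(l) for _, _, tails in per_phylum for l in tails["C"][1]
    ]
    n_width = max(all_n_lengths) if all_n_lengths else 0
    c_width = max(all_c_lengths) if all_c_lengths else 0

    records: list[tuple[str, str]] = []
    metadata: dict[str, SeqMeta] = {}
    tail_lengths: dict[str, tuple[int, int]] = {}
    for spec, core_block, tails in per_phylum:
        n_block, n_lens = tails["N"]
        c_block, c_lens = tails["C"]
        for k in range(spec.n_species):
            seq_id = f"{spec.name}{k + 1:02d}"
            ln, lc = int(n_lens[k]), int(c_lens[k])
            # N-tail keeps its TM-proximal end: take the trailing ln residues
            n_part = "".join(n_block[k, n_block.shape[1] - ln :]) if ln else ""
            c_part = "".join(c_block[k, :lc]) if lc else ""
            row = (
                GAP * (n_width - ln)
                + n_part
                + "".join(core_block[k])
                + c_part
                + GAP * (c_width - lc)
            )
            records.append((seq_id, row))
            metadata[seq_id] = SeqMeta(
                species=f"{spec.name.capitalize()} species {k + 1}", phylum=spec.name
            )
            tail_lengths[seq_id] = (ln, lc)

    aln = LabeledAlignment(records=records, metadata=metadata)

    reference_id = records[0][0]
    ref_n_len = tail_lengths[reference_id][0]
    topo = ReferenceTopology(
        reference_id=reference_id,
        tm_intervals=tuple(
            (ref_n_len + a, ref_n_len + b) for a, b in tm_core
        ),
        n_terminus_side=cfg.n_terminus_side,
        flank_width=cfg.flank_width,
    )

    class_columns = {
        cls: [int(n_width + i + 1) for i in class_idx[cls]] for cls in core_classes
    }
    truth = {
        "seed": cfg.seed,
        "reference_id": reference_id,
        "core_offset_columns": n_width,
        "core_length": core_len,
        "core_labels": labels,
        "class_columns": class_columns,
        "tm_intervals_core": [list(iv) for iv in tm_core],
        "region_rates": dict(cfg.region_rates),
        "region_compositions": {
            c: dict(d) for c, d in cfg.region_compositions.items()
        },
        "phyla": [
            {
                "name": s.name,
                "n_species": s.n_species,
                "rate_scale": s.rate_scale,
                "n_tail_length": s.n_tail_length,
                "c_tail_length": s.c_tail_length,
                "tail_jitter": s.tail_jitter,
                "tail_composition": s.tail_composition,
            }
            for s in cfg.phyla
        ],
        "tail_lengths": {k: list(v) for k, v in tail_lengths.items()},
    }
    return aln, topo, truth


# ---------------------------------------------------------------------------
# Bundled fixture configurations
# ---------------------------------------------------------------------------

#: Region substitution probabilities of the channel-like fixture: TM sites
#: most constrained, LWI flanks intermediate, loops free; tails at 0.15 so
#: that full-length conservation sits between TM and LWI, as observed for
#: the protein family this fixture emulates.
CATSPER_LIKE_RATES = {
    "TM": 0.05,
    "LWI_inner": 0.20,
    "LWI_outer": 0.20,
    "loop": 0.30,
    "tail": 0.15,
}

_LOOP_COMP = {
    "S": 0.06, "T": 0.07, "G": 0.08, "A": 0.07, "P": 0.06, "N": 0.06,
    "Q": 0.06, "E": 0.07, "D": 0.06, "K": 0.07, "R": 0.06, "H": 0.03,
    "L": 0.06, "I": 0.04, "V": 0.05, "F": 0.03, "Y": 0.02, "W": 0.01,
    "M": 0.02, "C": 0.02,
}

#: Stationary compositions of the channel-like fixture.  Inner LWI plants
#: Phe at exactly 0.20 (against a natural abundance near 0.039) with strong
#: Trp/Tyr enrichment; Cys has weight zero at both LWI classes.
CATSPER_LIKE_COMPOSITIONS = {
    "TM": {
        "L": 0.18, "I": 0.12, "V": 0.12, "F": 0.10, "A": 0.10, "M": 0.06,
        "G": 0.06, "T": 0.05, "S": 0.05, "W": 0.04, "Y": 0.04, "C": 0.03,
        "P": 0.02, "N": 0.01, "Q": 0.01, "H": 0.004, "K": 0.002, "R": 0.002,
        "E": 0.001, "D": 0.001,
    },
    "LWI_inner": {
        "F": 0.20, "W": 0.12, "Y": 0.10, "L": 0.10, "I": 0.06, "R": 0.06,
        "K": 0.06, "S": 0.05, "A": 0.05, "G": 0.04, "T": 0.04, "V": 0.04,
        "M": 0.03, "N": 0.02, "Q": 0.02, "H": 0.005, "P": 0.002,
        "E": 0.0015, "D": 0.0015, "C": 0.0,
    },
    "LWI_outer": {
        "Y": 0.08, "W": 0.06, "F": 0.06, "S": 0.10, "T": 0.08, "G": 0.08,
        "A": 0.08, "P": 0.06, "N": 0.06, "Q": 0.06, "R": 0.06, "K": 0.06,
        "E": 0.04, "D": 0.04, "H": 0.04, "L": 0.02, "I": 0.01, "V": 0.005,
        "M": 0.005, "C": 0.0,
    },
    "loop": dict(_LOOP_COMP),
    "tail": dict(_LOOP_COMP),
}

#: His-rich stationary composition of the long mammalian N-tail (H = 0.17).
MAMMAL_TAIL_COMPOSITION = {
    "H": 0.17, "S": 0.10, "P": 0.08, "G": 0.08, "A": 0.08, "T": 0.07,
    "E": 0.07, "D": 0.06, "Q": 0.06, "N": 0.05, "K": 0.05, "R": 0.04,
    "L": 0.03, "V": 0.02, "I": 0.01, "F": 0.01, "Y": 0.01, "M": 0.005,
    "W": 0.0025, "C": 0.0025,
}

_UNIFORM = {a: 0.05 for a in AMINO_ACIDS}

_FIXTURE_SEEDS = {"catsper_like": 101, "null_uniform": 202, "high_divergence": 303}


def fixture_config(name: str, seed: int | None = None) -> GeneratorConfig:
    """The GeneratorConfig behind a named fixture (seed overridable)."""
    if name not in _FIXTURE_SEEDS:
        raise LwiError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_SEEDS)}"
        )
    seed = _FIXTURE_SEEDS[name] if seed is None else seed
    if name == "catsper_like":
        phyla = (
            PhylumSpec("mammal", 10, n_tail_length=350, c_tail_length=100,
                       tail_jitter=12, tail_composition=dict(MAMMAL_TAIL_COMPOSITION)),
            PhylumSpec("bird", 10, n_tail_length=200, c_tail_length=100),
            PhylumSpec("reptile", 10, n_tail_length=180, c_tail_length=100),
            PhylumSpec("amphibian", 10, n_tail_length=160, c_tail_length=100),
            PhylumSpec("fish", 10, n_tail_length=120, c_tail_length=100),
        )
        return GeneratorConfig(
            seed=seed,
            phyla=phyla,
            region_rates=dict(CATSPER_LIKE_RATES),
            region_compositions={
                c: dict(d) for c, d in CATSPER_LIKE_COMPOSITIONS.items()
            },
        )
    if name == "null_uniform":
        phyla = tuple(
            PhylumSpec(p, 10, n_tail_length=40, c_tail_length=40, tail_jitter=3)
            for p in PHYLA
        )
        return GeneratorConfig(
            seed=seed,
            phyla=phyla,
            region_rates={c: 0.95 for c in REGION_CLASSES},
            region_compositions={c: dict(_UNIFORM) for c in REGION_CLASSES},
        )
    # high_divergence: channel-like compositions at near-saturation rates
    phyla = tuple(
        PhylumSpec(p, 10, n_tail_length=80, c_tail_length=60) for p in PHYLA
    )
    return GeneratorConfig(
        seed=seed,
        phyla=phyla,
        region_rates={c: 0.95 for c in REGION_CLASSES},
        region_compositions={c: dict(d) for c, d in CATSPER_LIKE_COMPOSITIONS.items()},
    )


def make_fixture(name: str, seed: int | None = None):
    """Generate a named fixture family deterministically.

    ``catsper_like``: 5 phyla x 10 species, TM rate < LWI rate < loop rate,
    aromatic-enriched Cys-free inner LWI, long His-rich mammalian N-tails.
    ``null_uniform``: uniform composition everywhere, equal near-saturation
    rates — no signal for any statistic to find.
    ``high_divergence``: channel-like compositions at rates near saturation.
    """
    return generate_family(fixture_config(name, seed))


def write_bundle(aln, topo, truth, out_dir) -> dict[str, str]:
    """Write the standard input bundle: FASTA + metadata + topology + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "metadata": out / "metadata.tsv",
        "topology": out / "topology.yaml",
        "truth": out / "ground_truth.json",
    }
    write_labeled_alignment(aln, paths["alignment"], paths["metadata"])
    write_topology(topo, paths["topology"])
    with open(paths["truth"], "w") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
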