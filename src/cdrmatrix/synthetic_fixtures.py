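"""Deterministic two-class synthetic repertoires with known ground truth.

The generator emulates the structure of a paired heavy/light-chain CDR table:
two labeled classes of six-loop records with configurable loop-length
distributions and background residue frequencies.  Known signals can be
implanted on top of the background —

* property shifts: at chosen loop positions, residues of one class are
  replaced with draws from a chosen residue set (e.g. {R, K} to shift the
  charge profile) with a given enrichment probability;
* position couplings: with a given probability, the residue at one site is
  copied to another site of the same record, creating mutual-information
  "crosstalk" in one class only.

Everything is reproducible from (spec, seed).  Reactivity counts are
synthesized consistently with class (polyreactive records bind 4-7 panel
ligands, non-polyreactive records bind 0), so the records round-trip through
the normal labeling scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import (
    LABEL_NONPOLY,
    LABEL_POLY,
    LOOP_NAMES,
    RESIDUE_ORDER,
    EncodingLayout,
    SequenceRecord,
)

#: Loop-length candidate sets reflecting typical antibody CDR ranges: short
#: fixed germline-encoded loops, a long and variable CDR3H.
DEFAULT_LOOP_LENGTHS: dict[str, tuple[int, ...]] = {
    "cdr1l": (5, 6, 7),
    "cdr2l": (3,),
    "cdr3l": (8, 9, 10),
    "cdr1h": (8,),
    "cdr2h": (7, 8),
    "cdr3h": tuple(range(10, 23)),
}

#: Approximate average amino-acid composition of antibody CDR loops
#: (serine/glycine/tyrosine-rich), for a more realistic background than
#: the uniform default.
NATURAL_CDR_FREQUENCIES: dict[str, float] = {
    "S": 0.13, "G": 0.10, "Y": 0.09, "T": 0.07, "A": 0.07, "D": 0.06,
    "R": 0.05, "N": 0.05, "L": 0.05, "V": 0.05, "F": 0.04, "I": 0.04,
    "K": 0.04, "P": 0.04, "E": 0.03, "Q": 0.03, "W": 0.02, "H": 0.02,
    "M": 0.01, "C": 0.01,
}


@dataclass(frozen=True)
class PropertyShift:
    """Residue-set enrichment at chosen loop positions of one class."""

    loop: str
    positions: tuple[int, ...]
    residues: tuple[str, ...]
    delta: float  # per-position enrichment probability
    class_label: str = LABEL_POLY

    def __post_init__(self) -> None:
        if self.loop not in LOOP_NAMES:
            raise ValueError(f"unknown loop {self.loop!r}")
        if not self.residues:
            raise ValueError("residue set must be non-empty")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")


@dataclass(frozen=True)
class Coupling:
    """Copy-coupling between two loop positions, optionally class-restricted."""

    site_a: tuple[str, int]  # (loop, 0-based position within loop)
    site_b: tuple[str, int]
    strength: float
    class_label: str | None = LABEL_POLY  # None couples both classes

    def __post_init__(self) -> None:
        for loop, _ in (self.site_a, self.site_b):
            if loop not in LOOP_NAMES:
                raise ValueError(f"unknown loop {loop!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic two-class repertoire."""

    n_polyreactive: int = 200
    n_nonpolyreactive: int = 200
    loop_lengths: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_LENGTHS)
    )
    background: str | Mapping[str, float] = "uniform"
    shifts: tuple[PropertyShift, ...] = ()
    couplings: tuple[Coupling, ...] = ()
    label_noise: float = 0.0
    source: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_polyreactive < 1 or self.n_nonpolyreactive < 1:
            raise ValueError("class sizes must be positive")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        for loop in self.loop_lengths:
            if loop not in LOOP_NAMES:
                raise ValueError(f"unknown loop {loop!r} in loop_lengths")
        for sig in self.shifts:
            widths = self.loop_lengths.get(sig.loop, DEFAULT_LOOP_LENGTHS[sig.loop])
            if max(sig.positions, default=0) >= min(widths):
                raise ValueError(
                    f"shift positions {sig.positions} exceed the shortest "
                    f"{sig.loop} length {min(widths)}"
                )


@dataclass
class FixtureTruth:
    """Registry of what was implanted where, for recovery tests."""

    true_class: dict[str, str]
    shifts: tuple[PropertyShift, ...]
    couplings: tuple[Coupling, ...]
    seed: int


def _background_frequencies(spec_bg: str | Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    if isinstance(spec_bg, str):
        if spec_bg == "uniform":
            residues = list(RESIDUE_ORDER)
            return residues, np.full(len(residues), 1.0 / len(residues))
        if spec_bg == "natural":
            residues = list(NATURAL_CDR_FREQUENCIES)
            freqs = np.array([NATURAL_CDR_FREQUENCIES[r] for r in residues])
            return residues, freqs / freqs.sum()
        raise ValueError(f"unknown background preset {spec_bg!r}")
    residues = list(spec_bg)
    bad = [r for r in residues if r not in RESIDUE_ORDER]
    if bad:
        raise ValueError(f"background contains non-standard residues {bad}")
    freqs = np.array([float(spec_bg[r]) for r in residues])
    if np.any(freqs < 0) or freqs.sum() <= 0:
        raise ValueError("background frequencies must be non-negative and sum > 0")
    return residues, freqs / freqs.sum()


def generate_repertoire(spec: FixtureSpec) -> tuple[list[SequenceRecord], FixtureTruth]:
    """Draw a labeled two-class repertoire from the spec, fully seeded."""
    rng = np.random.default_rng(spec.seed)
    residues, freqs = _background_frequencies(spec.background)
    lengths = {**DEFAULT_LOOP_LENGTHS, **{k: tuple(v) for k, v in spec.loop_lengths.items()}}

    records: list[SequenceRecord] = []
    true_class: dict[str, str] = {}
    plan = [(LABEL_POLY, spec.n_polyreactive), (LABEL_NONPOLY, spec.n_nonpolyreactive)]
    counter = 0
    for label, n in plan:
        for _ in range(n):
            loops = {}
            for name in LOOP_NAMES:
                ln = int(rng.choice(lengths[name]))
                loops[name] = "".join(rng.choice(residues, size=ln, p=freqs))
            rec_id = f"syn{counter:05d}"
            counter += 1
            loops = _apply_shifts(loops, label, spec.shifts, rng)
            loops = _apply_couplings(loops, label, spec.couplings, rng)
            count = int(rng.integers(4, 8)) if label == LABEL_POLY else 0
            records.append(
                SequenceRecord(
                    id=rec_id, loops=loops, reactivity_count=count,
                    label=label, source=spec.source,
                )
            )
            true_class[rec_id] = label

    if spec.label_noise > 0:
        flip = rng.random(len(records)) < spec.label_noise
        for i, rec in enumerate(records):
            if flip[i]:
                new = LABEL_NONPOLY if rec.label == LABEL_POLY else LABEL_POLY
                rec.label = new
                rec.reactivity_count = int(rng.integers(4, 8)) if new == LABEL_POLY else 0

    truth = FixtureTruth(
        true_class=true_class, shifts=spec.shifts,
        couplings=spec.couplings, seed=spec.seed,
    )
    return records, truth


def _apply_shifts(
    loops: dict[str, str], label: str,
    shifts: Sequence[PropertyShift], rng: np.random.Generator,
) -> dict[str, str]:
    for sig in shifts:
        if sig.class_label != label or sig.delta == 0.0:
            continue
        seq = list(loops[sig.loop])
        for pos in sig.positions:
            if pos < len(seq) and rng.random() < sig.delta:
                seq[pos] = str(rng.choice(sig.residues))
        loops[sig.loop] = "".join(seq)
    return loops


def _apply_couplings(
    loops: dict[str, str], label: str,
    couplings: Sequence[Coupling], rng: np.random.Generator,
) -> dict[str, str]:
    for sig in couplings:
        if sig.strength == 0.0:
            continue
        if sig.class_label is not None and sig.class_label != label:
            continue
        loop_a, pos_a = sig.site_a
        loop_b, pos_b = sig.site_b
        if pos_a >= len(loops[loop_a]) or pos_b >= len(loops[loop_b]):
            continue
        if rng.random() < sig.strength:
            seq_b = list(loops[loop_b])
            seq_b[pos_b] = loops[loop_a][pos_a]
            loops[loop_b] = "".join(seq_b)
    return loops


def implant_property_shift(
    records: Sequence[SequenceRecord],
    loop: str,
    positions: Sequence[int],
    residues: Sequence[str],
    delta: float,
    class_label: str = LABEL_POLY,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Apply a residue-set enrichment to existing records (out of place)."""
    sig = PropertyShift(
        loop=loop, positions=tuple(positions), residues=tuple(residues),
        delta=delta, class_label=class_label,
    )
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        loops = _apply_shifts(dict(rec.loops), rec.label, (sig,), rng)
        out.append(SequenceRecord(
            id=rec.id, loops=loops, reactivity_count=rec.reactivity_count,
            label=rec.label, source=rec.source,
            v_gene_h=rec.v_gene_h, v_gene_l=rec.v_gene_l,
            j_gene_h=rec.j_gene_h, j_gene_l=rec.j_gene_l,
        ))
    return out


def implant_coupling(
    records: Sequence[SequenceRecord],
    site_a: tuple[str, int],
    site_b: tuple[str, int],
    strength: float,
    class_label: str | None = LABEL_POLY,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Copy-couple two loop positions in existing records (out of place)."""
    sig = Coupling(site_a=site_a, site_b=site_b, strength=strength,
                   class_label=class_label)
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        loops = _apply_couplings(dict(rec.loops), rec.label, (sig,), rng)
        out.append(SequenceRecord(
            id=rec.id, loops=loops, reactivity_count=rec.reactivity_count,
            label=rec.label, source=rec.source,
            v_gene_h=rec.v_gene_h, v_gene_l=rec.v_gene_l,
            j_gene_h=rec.j_gene_h, j_gene_l=rec.j_gene_l,
        ))
    return out


def generate_platform_classes(
    n_per_class: int = 12,
    n_test_per_class: int = 5,
    shift_probability: float = 0.5,
    seed: int = 0,
):
    """Synthetic aligned platform-domain classes with a hydrophobicity split.

    Emulates two molecular classes whose antigen-binding platforms differ in
    mean hydrophobicity — a "lipid-binding-like" class enriched in hydrophobic
    residues and a "peptide-binding-like" class enriched in hydrophilic ones —
    plus held-out test members drawn from the same generators.  Returns
    (train_classes, test_classes, boundaries); all sequences share one
    aligned length and the boundaries mark two strands and two helices.

    These are synthetic stand-ins for real MHC-I/CD1 platform alignments.
    """
    from .mhc_platform import FeatureBoundaries, PlatformClass

    rng = np.random.default_rng(seed)
    boundaries = FeatureBoundaries((
        ("strand_1", 0, 25),
        ("strand_2", 30, 55),
        ("helix_1", 60, 100),
        ("helix_2", 110, 150),
    ))
    length = 150
    hydrophobic = list("IVLFMA")
    hydrophilic = list("STNQDE")
    residues = list(RESIDUE_ORDER)

    def draw(enriched: list[str]) -> str:
        seq = rng.choice(residues, size=length)
        swap = rng.random(length) < shift_probability
        seq[swap] = rng.choice(enriched, size=int(swap.sum()))
        return "".join(seq)

    def build(name: str, enriched: list[str], n: int, role: str) -> "PlatformClass":
        return PlatformClass(
            name=name,
            ids=[f"{name}-{role}-{i}" for i in range(n)],
            sequences=[draw(enriched) for _ in range(n)],
            role=role,
        )

    train = [
        build("lipid_binding", hydrophobic, n_per_class, "train"),
        build("peptide_binding", hydrophilic, n_per_class, "train"),
    ]
    test = [
        build("lipid_binding", hydrophobic, n_test_per_class, "test"),
        build("peptide_binding", hydrophilic, n_test_per_class, "test"),
    ]
    return train, test, boundaries


def loop_position_column(
    layout: EncodingLayout, loop: str, loop_length: int, position: int
) -> int:
    """Matrix column where loop-local ``position`` lands for a loop of
    ``loop_length`` under centre alignment (odd slack to the right)."""
    start, end = layout.loop_spans[loop]
    width = end - start
    if loop_length > width or position >= loop_length:
        raise ValueError("position outside the centred loop block")
    return start + (width - loop_length) // 2 + position
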