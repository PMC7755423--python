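"""Platform-domain encoding for MHC and MHC-like molecules.

The membrane-distal platform domain of MHC-fold proteins (the beta-sheet
floor plus two alpha-helices) binds the presented antigen.  Given an aligned
FASTA per molecular class and user-declared structural feature boundaries
(strand/helix intervals in alignment coordinates, e.g. from a structure
prediction run upstream), each feature segment is cut out, stripped of
alignment gaps, and centre-aligned into its own column block — producing the
same integer position matrix used for antibody CDR loops, so every downstream
stage (property masks, statistics, information theory, PCA/LDA) applies
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from .sequence_io import (
    EncodedMatrix,
    EncodingLayout,
    center_align_segment,
    encode_residue,
)

GAP_CHARS = "-."


@dataclass
class PlatformClass:
    """One molecular class: aligned member sequences sharing a single length."""

    name: str
    ids: list[str]
    sequences: list[str]
    role: str = "train"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"class {self.name!r} has no members")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"class {self.name!r} members have unequal aligned lengths "
                f"{sorted(lengths)}; align the sequences first"
            )
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class FeatureBoundaries:
    """Ordered structural features as (name, start, end) half-open intervals."""

    features: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.features:
            kind = name.split("_")[0].lower()
            if kind not in ("strand", "helix"):
                raise ValueError(f"feature {name!r}: kind must be strand or helix")
            if not (0 <= start < end):
                raise ValueError(f"feature {name!r}: bad interval [{start}, {end})")
            if start < prev_end:
                raise ValueError(f"feature {name!r} overlaps or is out of order")
            prev_end = end

    def validate_against(self, alignment_length: int) -> None:
        for name, _, end in self.features:
            if end > alignment_length:
                raise ValueError(
                    f"feature {name!r} ends at {end}, beyond alignment "
                    f"length {alignment_length}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureBoundaries":
        """Load from YAML or JSON: a list of {name, start, end} mappings."""
        raw = yaml.safe_load(Path(path).read_text())
        items = raw["features"] if isinstance(raw, Mapping) else raw
        return cls(tuple((d["name"], int(d["start"]), int(d["end"])) for d in items))


def load_platform_classes(
    fasta_by_class: Mapping[str, str | Path],
    roles: Mapping[str, str] | None = None,
) -> list[PlatformClass]:
    """Read one aligned FASTA per class (gap characters '-' or '.')."""
    roles = roles or {}
    classes = []
    for name, path in fasta_by_class.items():
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"empty FASTA for class {name!r}: {path}")
        classes.append(
            PlatformClass(
                name=name,
                ids=[r.id for r in records],
                sequences=[str(r.seq).upper() for r in records],
                role=roles.get(name, "train"),
            )
        )
    return classes


def _strip_gaps(segment: str) -> str:
    return "".join(c for c in segment if c not in GAP_CHARS)


def encode_platform(
    classes: Sequence[PlatformClass],
    boundaries: FeatureBoundaries,
    buffer_width: int = 3,
    strip_gaps: bool = True,
) -> EncodedMatrix:
    """Encode platform-domain sequences feature-segment by feature-segment.

    Each declared feature is extracted from the alignment, optionally stripped
    of in-segment gaps, and centre-aligned into a block wide enough for the
    longest observed (ungapped) segment.  Rows carry the class name as label,
    so two-class downstream comparisons work directly.
    """
    if not classes:
        raise ValueError("no classes")
    for cls in classes:
        boundaries.validate_against(cls.alignment_length)

    n_features = len(boundaries.features)
    segments: list[list[str]] = []  # per row: list of segment strings
    ids, labels = [], []
    for cls in classes:
        for rid, seq in zip(cls.ids, cls.sequences):
            segs = []
            for name, start, end in boundaries.features:
                seg = seq[start:end]
                if strip_gaps:
                    segs.append(_strip_gaps(seg))
                else:
                    segs.append(seg)  # gap columns preserved, encoded as 0
            segments.append(segs)
            ids.append(f"{cls.name}:{rid}")
            labels.append(cls.name)

    widths = tuple(
        max(len(row[f]) for row in segments) for f in range(n_features)
    )
    layout = EncodingLayout(
        loop_widths=widths,
        buffer_width=buffer_width,
        slot_names=tuple(name for name, _, _ in boundaries.features),
    )
    values = np.zeros((len(segments), layout.total_length), dtype=np.int64)
    spans = layout.loop_spans
    for i, row in enumerate(segments):
        for f, (name, _, _) in enumerate(boundaries.features):
            start, end = spans[name]
            seg = row[f]
            if strip_gaps:
                values[i, start:end] = center_align_segment(seg, end - start, record_id=ids[i])
            else:
                codes = [0 if c in GAP_CHARS else encode_residue(c) for c in seg]
                values[i, start:start + len(codes)] = codes
    return EncodedMatrix(values=values, layout=layout, row_ids=ids, row_labels=labels)
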