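"""Reading CDR-loop repertoires and building the position-sensitive matrix encoding.

An antibody is represented by its six complementarity-determining-region (CDR)
loops — three per chain: CDR1/2/3 of the light chain and CDR1/2/3 of the heavy
chain.  Because CDR loops vary in length, conventional multiple alignment is
awkward; instead every loop is centre-aligned into a fixed-width column block
and residues are encoded as small integers, yielding an ``N x L`` matrix in
which column position is directly comparable across sequences.  A zero value
acts as a buffer both between loops and as padding inside a block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Canonical slot order: light-chain CDR1/2/3, then heavy-chain CDR1/2/3.
LOOP_NAMES: tuple[str, ...] = ("cdr1l", "cdr2l", "cdr3l", "cdr1h", "cdr2h", "cdr3h")

# Residue codes 1..20, grouped hydrophobic -> polar -> charged.  The grouping
# pins leucine to 3, histidine to 16 and arginine to 17, the three published
# anchor assignments of the encoding.  Code 21 is reserved for X/non-standard.
RESIDUE_ORDER = "AVLIMFWPGSTCYNQHRKDE"
NONSTANDARD_CODE = 21
ALPHABET = RESIDUE_ORDER + "X"

_CODE_OF = {aa: i + 1 for i, aa in enumerate(RESIDUE_ORDER)}
_CODE_OF["X"] = NONSTANDARD_CODE
_RESIDUE_OF = {v: k for k, v in _CODE_OF.items()}

LABEL_POLY = "polyreactive"
LABEL_NONPOLY = "non_polyreactive"
LABEL_EXCLUDED = "excluded"
LABEL_UNKNOWN = "unknown"

#: Size of the ELISA ligand panel; reactivity counts live in 0..PANEL_SIZE.
PANEL_SIZE = 7


def ordered_class_labels(labels: Iterable[str]) -> tuple[str, str]:
    """The two class labels of a comparison, polyreactive first when present.

    Differences downstream (means, frequencies, mutual information) are
    signed first-minus-second.
    """
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, found {uniq}")
    if LABEL_POLY in uniq:
        return LABEL_POLY, next(l for l in uniq if l != LABEL_POLY)
    return uniq[0], uniq[1]


class SchemaError(ValueError):
    """Input table is missing a required column."""


class EncodingError(ValueError):
    """A character cannot be mapped to a residue code."""


class LayoutError(ValueError):
    """A sequence does not fit the requested encoding layout."""


@dataclass
class SequenceRecord:
    """One antibody: six CDR loop strings plus reactivity metadata."""

    id: str
    loops: dict[str, str]
    reactivity_count: int | None = None
    label: str = LABEL_UNKNOWN
    v_gene_h: str | None = None
    v_gene_l: str | None = None
    j_gene_h: str | None = None
    j_gene_l: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        loops = {name: str(self.loops.get(name, "") or "").upper() for name in LOOP_NAMES}
        for name, seq in loops.items():
            bad = [c for c in seq if c not in _CODE_OF]
            if bad:
                logger.warning(
                    "record %s loop %s: non-standard letters %s mapped to X",
                    self.id, name, sorted(set(bad)),
                )
                seq = "".join(c if c in _CODE_OF else "X" for c in seq)
                loops[name] = seq
        self.loops = loops

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.loops.values())


@dataclass(frozen=True)
class EncodingLayout:
    """Fixed column layout shared by every encoded row.

    ``loop_widths`` gives the block width per slot (the six CDR loops by
    default; platform-domain features reuse the same machinery with their own
    ``slot_names``); ``buffer_width`` zero columns separate consecutive
    blocks.  Spans are 0-based half-open column intervals.
    """

    loop_widths: tuple[int, ...]
    buffer_width: int = 3
    slot_names: tuple[str, ...] = LOOP_NAMES

    def __post_init__(self) -> None:
        if len(self.loop_widths) != len(self.slot_names) or not self.loop_widths:
            raise LayoutError(
                f"need one width per slot ({len(self.slot_names)}), got {self.loop_widths}"
            )
        if any(w < 0 for w in self.loop_widths):
            raise LayoutError(f"loop widths must be non-negative, got {self.loop_widths}")
        if self.buffer_width < 0:
            raise LayoutError("buffer_width must be non-negative")

    @property
    def total_length(self) -> int:
        return sum(self.loop_widths) + (len(self.loop_widths) - 1) * self.buffer_width

    @property
    def loop_spans(self) -> dict[str, tuple[int, int]]:
        spans = {}
        start = 0
        for name, width in zip(self.slot_names, self.loop_widths):
            spans[name] = (start, start + width)
            start += width + self.buffer_width
        return spans

    def to_dict(self) -> dict:
        return {
            "slot_names": list(self.slot_names),
            "loop_widths": list(self.loop_widths),
            "buffer_width": self.buffer_width,
            "total_length": self.total_length,
            "loop_spans": {k: list(v) for k, v in self.loop_spans.items()},
        }


@dataclass
class EncodedMatrix:
    """Integer position matrix: rows are sequences, entries are residue codes 0..21."""

    values: np.ndarray
    layout: EncodingLayout
    row_ids: list[str]
    row_labels: list[str]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def rows_for_label(self, label: str) -> np.ndarray:
        mask = np.array([lbl == label for lbl in self.row_labels])
        return self.values[mask]

    def column_loop(self, column: int) -> str | None:
        """Name of the CDR slot covering ``column``, or None for a buffer column."""
        for name, (start, end) in self.layout.loop_spans.items():
            if start <= column < end:
                return name
        return None

    def save(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        pd.DataFrame(self.values, index=self.row_ids).to_csv(csv_path, header=False)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
        payload = {"layout": self.layout.to_dict(), "row_labels": self.row_labels}
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def encode_residue(residue: str) -> int:
    """Map a one-letter residue to its integer code (1..21; X and rarities -> 21)."""
    if len(residue) != 1 or not residue.isalpha():
        raise EncodingError(f"not a residue letter: {residue!r}")
    r = residue.upper()
    if r in _CODE_OF:
        return _CODE_OF[r]
    # B/J/Z/U/O ambiguity codes collapse onto the non-standard bucket
    return NONSTANDARD_CODE


def decode_code(code: int) -> str:
    if code == 0:
        return ""
    try:
        return _RESIDUE_OF[int(code)]
    except KeyError:
        raise EncodingError(f"no residue for code {code}") from None


def center_align_segment(sequence: str, width: int, record_id: str = "") -> np.ndarray:
    """Centre a residue string inside ``width`` columns of zeros.

    Odd slack goes to the right: pad_left = (width - len) // 2.
    """
    n = len(sequence)
    if n > width:
        who = f" (record {record_id})" if record_id else ""
        raise LayoutError(f"sequence of length {n} exceeds block width {width}{who}")
    out = np.zeros(width, dtype=np.int64)
    left = (width - n) // 2
    for i, ch in enumerate(sequence):
        out[left + i] = encode_residue(ch)
    return out


def read_repertoire(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[SequenceRecord]:
    """Read a CSV table of six-loop CDR records.

    Expected columns (renameable through ``schema``, a map from our canonical
    name to the column name in the file): ``id``, the six loop columns
    ``cdr1l..cdr3h``, and optionally ``reactivity_count``, ``source`` and gene
    call columns ``v_gene_h``/``v_gene_l``/``j_gene_h``/``j_gene_l``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty repertoire table: {path}")
    rename = {v: k for k, v in (schema or {}).items()}
    df = df.rename(columns=rename)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in LOOP_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required loop columns: {missing}")
    if "id" not in df.columns:
        df["id"] = [f"seq{i}" for i in range(len(df))]
    records = []
    for _, row in df.iterrows():
        count = row.get("reactivity_count", "")
        records.append(
            SequenceRecord(
                id=str(row["id"]),
                loops={name: row[name] for name in LOOP_NAMES},
                reactivity_count=int(count) if str(count).strip() != "" else None,
                v_gene_h=row.get("v_gene_h") or None,
                v_gene_l=row.get("v_gene_l") or None,
                j_gene_h=row.get("j_gene_h") or None,
                j_gene_l=row.get("j_gene_l") or None,
                source=row.get("source", ""),
            )
        )
    return records


def write_repertoire(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Emit records in the same CSV schema ``read_repertoire`` consumes."""
    rows = []
    for rec in records:
        row = {"id": rec.id, **{name: rec.loops[name] for name in LOOP_NAMES}}
        row["reactivity_count"] = "" if rec.reactivity_count is None else rec.reactivity_count
        row["source"] = rec.source
        for attr in ("v_gene_h", "v_gene_l", "j_gene_h", "j_gene_l"):
            row[attr] = getattr(rec, attr) or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def assign_polyreactivity_labels(
    records: Iterable[SequenceRecord], scheme: str = "full"
) -> list[SequenceRecord]:
    """Label records from their ELISA reactivity counts.

    ``full``: binding two or more panel ligands is polyreactive, otherwise
    non-polyreactive.  ``parsed``: only strong phenotypes are kept — 4-7
    ligands bound is polyreactive, 0 is non-polyreactive, 1-3 is excluded.
    """
    if scheme not in ("full", "parsed"):
        raise ValueError(f"unknown labeling scheme {scheme!r}")
    out = []
    for rec in records:
        count = rec.reactivity_count
        if count is None or not (0 <= count <= PANEL_SIZE):
            raise ValueError(
                f"record {rec.id}: reactivity_count {count!r} outside 0..{PANEL_SIZE}"
            )
        if scheme == "full":
            label = LABEL_POLY if count >= 2 else LABEL_NONPOLY
        else:
            if count >= 4:
                label = LABEL_POLY
            elif count == 0:
                label = LABEL_NONPOLY
            else:
                label = LABEL_EXCLUDED
        out.append(replace(rec, label=label))
    return out


def auto_layout(records: Sequence[SequenceRecord], buffer_width: int = 3) -> EncodingLayout:
    """Layout whose block widths are the maximum observed loop lengths.

    Widths are computed over all records regardless of class so that both
    populations share one coordinate system.
    """
    if not records:
        raise ValueError("no records")
    widths = tuple(
        max(len(rec.loops[name]) for rec in records) for name in LOOP_NAMES
    )
    return EncodingLayout(loop_widths=widths, buffer_width=buffer_width)


def encode_repertoire(
    records: Sequence[SequenceRecord],
    layout: EncodingLayout | None = None,
    buffer_width: int = 3,
    drop_excluded: bool = True,
) -> EncodedMatrix:
    """Build the position-sensitive integer matrix for a repertoire.

    Rows are grouped by class label (polyreactive block first) so the matrix
    visualises as two stacked populations.
    """
    recs = [r for r in records if not (drop_excluded and r.label == LABEL_EXCLUDED)]
    if not recs:
        raise ValueError("no records to encode")
    if layout is None:
        layout = auto_layout(recs, buffer_width=buffer_width)
    order = {LABEL_POLY: 0, LABEL_NONPOLY: 1, LABEL_EXCLUDED: 2, LABEL_UNKNOWN: 3}
    recs = sorted(recs, key=lambda r: order.get(r.label, 4))
    values = np.zeros((len(recs), layout.total_length), dtype=np.int64)
    spans = layout.loop_spans
    for i, rec in enumerate(recs):
        for name in LOOP_NAMES:
            start, end = spans[name]
            values[i, start:end] = center_align_segment(
                rec.loops[name], end - start, record_id=rec.id
            )
    return EncodedMatrix(
        values=values,
        layout=layout,
        row_ids=[r.id for r in recs],
        row_labels=[r.label for r in recs],
    )


def decode_row(row: np.ndarray, layout: EncodingLayout) -> dict[str, str]:
    """Recover the six loop strings from one encoded row (inverse of encoding)."""
    loops = {}
    for name, (start, end) in layout.loop_spans.items():
        codes = row[start:end]
        loops[name] = "".join(decode_code(int(c)) for c in codes if c != 0)
    return loops


@dataclass
class GeneUsageTable:
    """Per-class gene usage counts/frequencies and the between-class differences."""

    counts: dict[str, dict[str, int]]
    frequencies: dict[str, dict[str, float]]
    difference: dict[str, float]
    below_threshold_flags: dict[str, str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        classes = list(self.counts)
        genes = sorted(self.difference)
        data = {}
        for cls in classes:
            data[f"count_{cls}"] = [self.counts[cls].get(g, 0) for g in genes]
            data[f"freq_{cls}"] = [self.frequencies[cls].get(g, 0.0) for g in genes]
        data["difference"] = [self.difference[g] for g in genes]
        data["flag"] = [self.below_threshold_flags.get(g, "") for g in genes]
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"))


def gene_usage_table(
    records: Sequence[SequenceRecord],
    gene_field: str = "v_gene_h",
    threshold: float = 0.02,
) -> GeneUsageTable:
    """Tabulate gene usage per class with the between-class frequency difference.

    Genes used in one class but present below ``threshold`` (default 2%) in the
    other are flagged, mirroring the display convention of gene-usage wheels.
    """
    by_class: dict[str, list[str]] = {}
    for rec in records:
        gene = getattr(rec, gene_field, None)
        if gene:
            by_class.setdefault(rec.label, []).append(gene)
    if not by_class:
        raise ValueError(
            f"no {gene_field} gene calls on any record; attach calls from an "
            "AIRR rearrangement TSV first (see attach_gene_calls)"
        )
    counts = {
        cls: dict(pd.Series(genes).value_counts()) for cls, genes in by_class.items()
    }
    frequencies = {
        cls: {g: c / len(by_class[cls]) for g, c in cnts.items()}
        for cls, cnts in counts.items()
    }
    classes = sorted(by_class)
    genes = sorted({g for cnts in counts.values() for g in cnts})
    difference, flags = {}, {}
    if len(classes) >= 2:
        a, b = classes[0], classes[1]
        for g in genes:
            fa = frequencies[a].get(g, 0.0)
            fb = frequencies[b].get(g, 0.0)
            difference[g] = fa - fb
            if fa > 0 and fb <= threshold:
                flags[g] = f"below threshold in {b}"
            elif fb > 0 and fa <= threshold:
                flags[g] = f"below threshold in {a}"
    else:
        difference = {g: 0.0 for g in genes}
    return GeneUsageTable(
        counts={k: {g: int(c) for g, c in v.items()} for k, v in counts.items()},
        frequencies=frequencies,
        difference=difference,
        below_threshold_flags=flags,
        threshold=threshold,
    )


def attach_gene_calls(
    records: Sequence[SequenceRecord],
    airr_path: str | Path,
    chain: str = "heavy",
) -> list[SequenceRecord]:
    """Attach v_call/j_call gene annotations from an AIRR-C rearrangement TSV.

    Rows are matched to records by ``sequence_id``.  The TSV is the standard
    tab-separated output of annotation tools (IgBLAST and friends); running
    the annotator itself is out of scope here.
    """
    df = pd.read_csv(airr_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sequence_id", "v_call", "j_call"):
        if col not in df.columns:
            raise SchemaError(f"AIRR TSV missing required column {col!r}")
    calls = {row["sequence_id"]: (row["v_call"], row["j_call"]) for _, row in df.iterrows()}
    out = []
    for rec in records:
        if rec.id in calls:
            v, j = calls[rec.id]
            if chain == "heavy":
                rec = replace(rec, v_gene_h=v or None, j_gene_h=j or None)
            else:
                rec = replace(rec, v_gene_l=v or None, j_gene_l=j or None)
        out.append(rec)
    return out
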