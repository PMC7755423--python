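"""Biophysical property masks over the integer position matrix.

A mask replaces each residue code 1..21 with a per-residue scalar (charge,
hydrophobicity, a Kidera-style factor, ...), turning the integer matrix into a
real-valued position matrix.  Buffer/pad entries (code 0) always map to 0.0,
as do non-standard residues (code 21) under the default table.

The default table ships as CSV data (``data/properties.csv``) with 62 masks;
see ``scripts/make_default_properties.py`` in the repository for its exact
construction and provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import (
    NONSTANDARD_CODE,
    RESIDUE_ORDER,
    EncodedMatrix,
    EncodingLayout,
    encode_residue,
)

logger = logging.getLogger(__name__)

# side-chain pKa values chosen so that fractional charge at pH 7 reproduces
# the table anchors (H -> 0.091 with pKa 6.0)
DEFAULT_PKA = {
    "D": 3.65, "E": 4.25, "H": 6.0, "C": 8.3, "Y": 10.07, "K": 10.53, "R": 12.48,
}
_BASIC = frozenset("RKH")

BASIC_PROPERTIES = (
    "hydrophobicity1", "charge", "hydrophobicity2",
    "side_chain_flexibility", "side_chain_bulk",
)


class PropertyTableError(ValueError):
    pass


def charge_at_pH(residue: str, pH: float = 7.0, pka_table: dict[str, float] | None = None) -> float:
    """Fractional side-chain charge from a single Henderson-Hasselbalch term.

    Basic side chains contribute +1/(1 + 10^(pH - pKa)), acidic ones
    -1/(1 + 10^(pKa - pH)); residues without an ionizable side chain are 0.
    """
    r = residue.upper()
    encode_residue(r)  # validates the letter
    pka_table = DEFAULT_PKA if pka_table is None else pka_table
    pka = pka_table.get(r)
    if pka is None:
        return 0.0
    if r in _BASIC:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


@dataclass
class PropertyTable:
    """Per-residue values for each named property mask.

    ``values`` is indexed by residue letter (20 standard + 'X'); each column
    is one mask.  ``by_code(name)`` returns a length-22 lookup vector indexed
    by residue code, with code 0 (buffer) fixed at 0.0.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [r for r in RESIDUE_ORDER if r not in self.values.index]
        if missing:
            raise PropertyTableError(f"property table missing residue rows: {missing}")
        if "X" not in self.values.index:
            logger.info("property table has no X row; non-standard residues map to 0")
            self.values = self.values.copy()
            self.values.loc["X"] = 0.0

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return self.values.shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self.values.columns

    def category(self, name: str) -> str | None:
        if self.metadata is None:
            return None
        row = self.metadata[self.metadata["property"] == name]
        return None if row.empty else str(row["category"].iloc[0])

    def by_code(self, name: str) -> np.ndarray:
        if name not in self:
            raise PropertyTableError(
                f"unknown property {name!r}; available: {', '.join(self.names)}"
            )
        lut = np.zeros(NONSTANDARD_CODE + 1, dtype=float)
        for i, aa in enumerate(RESIDUE_ORDER):
            lut[i + 1] = float(self.values.at[aa, name])
        lut[NONSTANDARD_CODE] = float(self.values.at["X", name])
        return lut


def load_property_table(
    path: str | Path | None = None,
    metadata_path: str | Path | None = None,
) -> PropertyTable:
    """Load a property table CSV (first column residue letter, one column per mask).

    With no ``path`` the packaged 62-mask default is returned.
    """
    if path is None:
        data = resources.files("cdrmatrix").joinpath("data")
        values = pd.read_csv(data.joinpath("properties.csv"), index_col=0)
        metadata = pd.read_csv(data.joinpath("property_metadata.csv"))
        return PropertyTable(values=values, metadata=metadata)
    values = pd.read_csv(path, index_col=0)
    metadata = pd.read_csv(metadata_path) if metadata_path else None
    return PropertyTable(values=values, metadata=metadata)


@dataclass
class MaskedMatrix:
    """A real-valued position matrix: one property mask applied to an EncodedMatrix."""

    values: np.ndarray
    property: str
    layout: EncodingLayout
    row_ids: list[str]
    row_labels: list[str]

    def rows_for_label(self, label: str) -> np.ndarray:
        mask = np.array([lbl == label for lbl in self.row_labels])
        return self.values[mask]


def apply_mask(
    matrix: EncodedMatrix,
    property_name: str,
    table: PropertyTable | None = None,
) -> MaskedMatrix:
    """Replace residue codes by the property's per-residue values (code 0 -> 0.0)."""
    table = table if table is not None else load_property_table()
    lut = table.by_code(property_name)
    if np.any(matrix.values == NONSTANDARD_CODE) and lut[NONSTANDARD_CODE] == 0.0:
        logger.info(
            "matrix contains non-standard residues (code %d); masked as 0 under %r",
            NONSTANDARD_CODE, property_name,
        )
    return MaskedMatrix(
        values=lut[matrix.values],
        property=property_name,
        layout=matrix.layout,
        row_ids=list(matrix.row_ids),
        row_labels=list(matrix.row_labels),
    )


@dataclass
class FeatureMatrix:
    """Flattened N x (L*P) feature matrix: positions x properties, column-named 'property@column'."""

    values: np.ndarray
    columns: list[str]
    row_ids: list[str]
    row_labels: list[str]
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)

    @property
    def labels_array(self) -> np.ndarray:
        return np.asarray(self.row_labels)


def standardize_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns; constant columns map to all-zero instead of NaN."""
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=0)
    safe = np.where(sds > 0, sds, 1.0)
    z = (values - means) / safe
    z[:, sds == 0] = 0.0
    return z, means, sds


def build_feature_matrix(
    matrix: EncodedMatrix,
    properties: list[str] | None = None,
    table: PropertyTable | None = None,
    standardize: bool = False,
) -> FeatureMatrix:
    """Concatenate masked position matrices into one feature matrix per sequence."""
    table = table if table is not None else load_property_table()
    properties = list(properties) if properties is not None else table.names
    if not properties:
        raise ValueError("no properties requested")
    blocks, columns = [], []
    for prop in properties:
        lut = table.by_code(prop)
        blocks.append(lut[matrix.values])
        columns.extend(f"{prop}@{c}" for c in range(matrix.n_columns))
    values = np.hstack(blocks)
    means = sds = None
    if standardize:
        values, means, sds = standardize_columns(values)
    return FeatureMatrix(
        values=values,
        columns=columns,
        row_ids=list(matrix.row_ids),
        row_labels=list(matrix.row_labels),
        standardized=standardize,
        column_means=means,
        column_sds=sds,
    )
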