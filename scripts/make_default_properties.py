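"""Regenerate the default biophysical property table shipped with cdrmatrix.

The table holds 62 per-residue masks in three categories:

* ``basic`` (5): hydrophobicity1 (Kyte-Doolittle, rescaled to [-1, 1]),
  charge (Henderson-Hasselbalch fractional side-chain charge at pH 7),
  hydrophobicity2 (Eisenberg consensus, rescaled to [-1, 1]), side-chain
  flexibility (rotatable side-chain dihedral count) and side-chain bulk
  (Zimmerman bulkiness).
* ``kidera`` (10): orthogonal standardized factors obtained here by PCA of a
  panel of classic per-residue scales, in the spirit of the published Kidera
  factors (which were built the same way from a larger panel).  They are a
  reconstruction, not the published values.
* ``hotspot`` (47): numbered structural-propensity descriptors.  Slots 6, 24,
  25 and 41 carry standardized helix, sheet and turn propensities and
  side-chain flexibility; the remaining slots are synthetic standardized
  placeholder descriptors (seeded, reproducible) that keep the table at its
  full width until curated values are substituted.

Run from the repository root:  python scripts/make_default_properties.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

RESIDUES = list("AVLIMFWPGSTCYNQHRKDE")

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}
HELIX_PROPENSITY = {
    "E": 1.51, "M": 1.45, "A": 1.42, "L": 1.21, "K": 1.16, "F": 1.13,
    "Q": 1.11, "W": 1.08, "I": 1.08, "V": 1.06, "D": 1.01, "H": 1.00,
    "R": 0.98, "T": 0.83, "S": 0.77, "C": 0.70, "Y": 0.69, "N": 0.67,
    "P": 0.57, "G": 0.57,
}
SHEET_PROPENSITY = {
    "V": 1.70, "I": 1.60, "Y": 1.47, "F": 1.38, "W": 1.37, "L": 1.30,
    "C": 1.19, "T": 1.19, "Q": 1.10, "M": 1.05, "R": 0.93, "N": 0.89,
    "H": 0.87, "A": 0.83, "S": 0.75, "G": 0.75, "K": 0.74, "P": 0.55,
    "D": 0.54, "E": 0.37,
}
TURN_PROPENSITY = {
    "N": 1.56, "G": 1.56, "P": 1.52, "D": 1.46, "S": 1.43, "C": 1.19,
    "Y": 1.14, "K": 1.01, "Q": 0.98, "T": 0.96, "W": 0.96, "R": 0.95,
    "H": 0.95, "E": 0.74, "A": 0.66, "M": 0.60, "F": 0.60, "L": 0.59,
    "V": 0.50, "I": 0.47,
}
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
    "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
    "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}
BULKINESS = {
    "A": 11.50, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46, "Q": 14.45,
    "E": 13.57, "G": 3.40, "H": 13.69, "I": 21.40, "L": 21.40, "K": 15.71,
    "M": 16.25, "F": 19.80, "P": 17.43, "S": 9.47, "T": 15.77, "W": 21.67,
    "Y": 18.03, "V": 21.57,
}
SIDECHAIN_DIHEDRALS = {
    "G": 0, "A": 0, "P": 0, "S": 1, "C": 1, "T": 1, "V": 1, "L": 2, "I": 2,
    "D": 2, "N": 2, "H": 2, "F": 2, "Y": 2, "W": 2, "M": 3, "E": 3, "Q": 3,
    "K": 4, "R": 4,
}

PKA_SIDECHAIN = {"D": 3.65, "E": 4.25, "H": 6.0, "C": 8.3, "Y": 10.07,
                 "K": 10.53, "R": 12.48}
BASIC_RESIDUES = {"R", "K", "H"}


def fractional_charge(residue: str, pH: float = 7.0) -> float:
    pka = PKA_SIDECHAIN.get(residue)
    if pka is None:
        return 0.0
    if residue in BASIC_RESIDUES:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


def _vec(scale: dict[str, float]) -> np.ndarray:
    return np.array([scale[r] for r in RESIDUES], dtype=float)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def build_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    cols: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str, str]] = []

    kd = _vec(KYTE_DOOLITTLE)
    cols["hydrophobicity1"] = kd / np.abs(kd).max()
    meta.append(("hydrophobicity1", "basic", "Kyte-Doolittle scale rescaled to [-1, 1]"))

    cols["charge"] = np.array([round(fractional_charge(r), 3) for r in RESIDUES])
    meta.append(("charge", "basic",
                 "Henderson-Hasselbalch fractional side-chain charge at pH 7.0"))

    ei = _vec(EISENBERG)
    cols["hydrophobicity2"] = ei / np.abs(ei).max()
    meta.append(("hydrophobicity2", "basic", "Eisenberg consensus scale rescaled to [-1, 1]"))

    cols["side_chain_flexibility"] = _vec({k: float(v) for k, v in SIDECHAIN_DIHEDRALS.items()})
    meta.append(("side_chain_flexibility", "basic", "rotatable side-chain dihedral count"))

    cols["side_chain_bulk"] = _vec(BULKINESS)
    meta.append(("side_chain_bulk", "basic", "Zimmerman bulkiness"))

    # Kidera-style factors: PCA over a z-scored panel of classic scales,
    # each factor standardized over the 20 residues.  Reconstruction, not the
    # published Kidera values.
    panel = np.column_stack([
        _standardize(_vec(s)) for s in (
            KYTE_DOOLITTLE, EISENBERG, HOPP_WOODS, HELIX_PROPENSITY,
            SHEET_PROPENSITY, TURN_PROPENSITY, VOLUME, RESIDUE_MASS,
            POLARITY, ISOELECTRIC_POINT, BULKINESS,
            {k: float(v) for k, v in SIDECHAIN_DIHEDRALS.items()},
        )
    ] + [np.array([fractional_charge(r) for r in RESIDUES])])
    panel = panel - panel.mean(axis=0)
    _, _, vt = np.linalg.svd(panel, full_matrices=False)
    scores = panel @ vt.T
    for i in range(10):
        v = _standardize(scores[:, i])
        # deterministic sign: largest-magnitude entry positive
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        cols[f"kidera_{i + 1}"] = v
        meta.append((f"kidera_{i + 1}", "kidera",
                     "orthogonal standardized factor (PCA of classic scales; reconstruction)"))

    curated = {
        6: (_standardize(_vec(HELIX_PROPENSITY)), "alpha-helix propensity (standardized)"),
        24: (_standardize(_vec(SHEET_PROPENSITY)), "beta-sheet propensity (standardized)"),
        25: (_standardize(_vec(TURN_PROPENSITY)), "reverse-turn propensity (standardized)"),
        41: (_standardize(_vec({k: float(v) for k, v in SIDECHAIN_DIHEDRALS.items()})),
             "side-chain flexibility (standardized)"),
    }
    rng = np.random.default_rng(20200404)
    for i in range(1, 48):
        if i in curated:
            v, desc = curated[i]
        else:
            v = _standardize(rng.standard_normal(len(RESIDUES)))
            desc = "synthetic standardized placeholder descriptor"
        cols[f"hotspot_{i}"] = v
        meta.append((f"hotspot_{i}", "hotspot", desc))

    table = pd.DataFrame(cols, index=pd.Index(RESIDUES, name="residue")).round(6)
    # X / non-standard residues carry a neutral 0 under every mask
    table.loc["X"] = 0.0
    metadata = pd.DataFrame(meta, columns=["property", "category", "description"])
    return table, metadata


def main() -> None:
    out_dir = Path(__file__).resolve().parent.parent / "src" / "cdrmatrix" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    table, metadata = build_table()
    assert table.shape == (21, 62)
    table.to_csv(out_dir / "properties.csv")
    metadata.to_csv(out_dir / "property_metadata.csv", index=False)
    print(f"wrote {out_dir / 'properties.csv'} ({table.shape[1]} properties)")


if __name__ == "__main__":
    main()
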