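"""Shannon entropy and mutual information over matrix columns.

Treating each matrix column as a categorical variable (residue codes, with the
buffer/gap code 0 included as an ordinary symbol by default), positional
diversity is the plug-in Shannon entropy

    H(X) = -sum_x p(x) log2 p(x)

and between-column "crosstalk" is the mutual information

    I(X;Y) = H(X) - H(X|Y),

with the conditional entropy taken from the joint plug-in histogram.  All
quantities are in bits.  Fully conserved columns have H = 0 and hence zero
mutual information with everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .position_stats import PermutationTestResult, permutation_test
from .sequence_io import EncodedMatrix, ordered_class_labels


def _as_codes(column: np.ndarray) -> np.ndarray:
    col = np.asarray(column)
    if col.size == 0:
        raise ValueError("empty column")
    return col


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def column_entropy(column: np.ndarray) -> float:
    """Plug-in Shannon entropy of one column, in bits (0*log0 = 0)."""
    col = _as_codes(column)
    _, counts = np.unique(col, return_counts=True)
    return _entropy_from_counts(counts)


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Dense joint count table over the observed symbols of x and y."""
    xi, x_inv = np.unique(x, return_inverse=True)
    yi, y_inv = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.size, yi.size), dtype=np.int64)
    np.add.at(joint, (x_inv, y_inv), 1)
    return joint


def conditional_entropy(x: np.ndarray, y: np.ndarray) -> float:
    """H(X|Y) in bits from the joint plug-in histogram."""
    x, y = _as_codes(x), _as_codes(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("columns must have equal length")
    joint = _joint_counts(x, y)
    n = joint.sum()
    h = 0.0
    for j in range(joint.shape[1]):
        col = joint[:, j]
        ny = col.sum()
        if ny == 0:
            continue
        h += (ny / n) * _entropy_from_counts(col)
    return float(h)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """I(X;Y) = H(X) - H(X|Y) in bits, clipped at 0 against float dust."""
    return max(0.0, column_entropy(x) - conditional_entropy(x, y))


@dataclass
class EntropyProfile:
    """Per-column entropies (bits) with the symbol sets used."""

    entropies: np.ndarray
    gap_included: bool


@dataclass
class MIMatrix:
    """Symmetric L x L mutual-information matrix in bits; diagonal = H(X)."""

    values: np.ndarray
    label: str | None = None


def _class_rows(matrix: EncodedMatrix, label: str | None) -> np.ndarray:
    if label is None:
        return matrix.values
    rows = matrix.rows_for_label(label)
    if rows.shape[0] == 0:
        raise ValueError(f"no rows with label {label!r}")
    return rows


def _mi_from_rows(rows: np.ndarray, gap_mode: str) -> tuple[np.ndarray, np.ndarray]:
    L = rows.shape[1]
    mi = np.zeros((L, L))
    ent = np.zeros(L)
    cols = [rows[:, i] for i in range(L)]
    if gap_mode == "exclude":
        masks = [c != 0 for c in cols]
    for i in range(L):
        ci = cols[i]
        if gap_mode == "exclude":
            ci = ci[masks[i]]
        ent[i] = column_entropy(ci) if ci.size else 0.0
        mi[i, i] = ent[i]
    for i in range(L):
        for j in range(i + 1, L):
            xi, yj = cols[i], cols[j]
            if gap_mode == "exclude":
                keep = masks[i] & masks[j]
                if keep.sum() < 2:
                    continue
                xi, yj = xi[keep], yj[keep]
            val = mutual_information(xi, yj)
            mi[i, j] = mi[j, i] = val
    return mi, ent


def mi_matrix(
    matrix: EncodedMatrix,
    label: str | None = None,
    gap_mode: str = "include",
) -> tuple[MIMatrix, EntropyProfile]:
    """Mutual information for every column pair of one class (or all rows).

    ``gap_mode='include'`` treats the buffer/gap code 0 as an ordinary symbol
    (so loop-edge columns keep their loop-length information);
    ``'exclude'`` restricts estimation to rows without a gap at the positions
    involved.
    """
    if gap_mode not in ("include", "exclude"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    rows = _class_rows(matrix, label)
    if rows.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    mi, ent = _mi_from_rows(rows, gap_mode)
    return MIMatrix(values=mi, label=label), EntropyProfile(
        entropies=ent, gap_included=(gap_mode == "include")
    )


@dataclass
class MIDifferenceResult:
    """Class difference of mutual information with permutation significance."""

    delta: np.ndarray          # I(class_a) - I(class_b), L x L
    p_values: np.ndarray       # NaN where untested
    significant: np.ndarray    # bool mask at alpha
    label_a: str
    label_b: str
    permutations: int
    alpha: float

    def runs_for_row(self, row: int) -> list[tuple[int, int]]:
        from .position_stats import significant_runs
        return significant_runs(self.significant[row].tolist())


def mi_difference_with_significance(
    matrix: EncodedMatrix,
    iterations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    pairs: Sequence[tuple[int, int]] | None = None,
    gap_mode: str = "include",
) -> MIDifferenceResult:
    """Per-pair MI difference between the two classes, with permutation p-values.

    The statistic for pair (i, j) is the signed difference
    I_a(i,j) - I_b(i,j); its null distribution comes from shuffling class
    labels over rows while preserving class sizes, counting permutations with
    t >= t0 on the absolute difference (two-sided).  With ``pairs`` given,
    only those pairs are tested (the full difference map is still computed);
    testing all L^2 pairs at large R is expensive.
    """
    labels = np.asarray(matrix.row_labels)
    label_a, label_b = ordered_class_labels(matrix.row_labels)
    rows_a = matrix.values[labels == label_a]
    rows_b = matrix.values[labels == label_b]
    mi_a, _ = _mi_from_rows(rows_a, gap_mode)
    mi_b, _ = _mi_from_rows(rows_b, gap_mode)
    delta = mi_a - mi_b
    L = delta.shape[0]

    if pairs is None:
        pairs = [(i, j) for i in range(L) for j in range(i, L)]
    rng = np.random.default_rng(seed)
    n_a = rows_a.shape[0]
    pooled = np.vstack([rows_a, rows_b])
    p = np.full((L, L), np.nan)

    # one shared set of label permutations across pairs keeps cost linear in R
    perm_idx = [rng.permutation(pooled.shape[0]) for _ in range(iterations)]
    for i, j in pairs:
        t0 = abs(delta[i, j])
        xi, yj = pooled[:, i], pooled[:, j]
        exceed = 0
        for idx in perm_idx:
            ia, ib = idx[:n_a], idx[n_a:]
            t = abs(
                mutual_information(xi[ia], yj[ia])
                - mutual_information(xi[ib], yj[ib])
            )
            if t >= t0:
                exceed += 1
        val = (1 + exceed) / (iterations + 1)
        p[i, j] = p[j, i] = val
    significant = np.zeros((L, L), dtype=bool)
    with np.errstate(invalid="ignore"):
        significant[~np.isnan(p)] = p[~np.isnan(p)] <= alpha
    return MIDifferenceResult(
        delta=delta, p_values=p, significant=significant,
        label_a=label_a, label_b=label_b, permutations=iterations, alpha=alpha,
    )


def mi_pair_permutation_test(
    matrix: EncodedMatrix,
    pair: tuple[int, int],
    iterations: int = 1000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test of the MI difference at a single column pair.

    Thin wrapper over :func:`position_stats.permutation_test` with the
    MI-difference statistic over row subsets.
    """
    labels = np.asarray(matrix.row_labels)
    label_a, label_b = ordered_class_labels(matrix.row_labels)
    i, j = pair
    a = matrix.values[labels == label_a][:, [i, j]]
    b = matrix.values[labels == label_b][:, [i, j]]

    def stat(x: np.ndarray, y: np.ndarray) -> float:
        return abs(
            mutual_information(x[:, 0], x[:, 1])
            - mutual_information(y[:, 0], y[:, 1])
        )

    return permutation_test(a, b, statistic=stat, iterations=iterations, seed=seed)
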