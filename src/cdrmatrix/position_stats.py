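"""Position-resolved two-population statistics.

Per matrix column the two classes are compared with nonparametric resampling:

* bootstrap class means with bootstrap standard errors (resampling within
  class, from the empirical distribution);
* a two-sided Studentized bootstrap test whose null replicates are drawn from
  the pooled, label-free sample, p = (1 + #(z^2 >= z0^2)) / (R + 1);
* a label-permutation test with a pluggable statistic (difference of means by
  default), p = (1 + #(t >= t0)) / (R + 1);
* Bonferroni correction and contiguous-run reporting for profile plots.

The Studentized statistic is z = (Ȳ2 − Ȳ1) / sqrt(σ2²/n2 + σ1²/n1) with
n−1 sample standard deviations; the variance terms add under the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .property_masks import MaskedMatrix
from .sequence_io import ordered_class_labels



@dataclass
class PositionProfile:
    """Per-column class means and bootstrap standard errors."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    se_a: np.ndarray
    se_b: np.ndarray
    n_a: int
    n_b: int
    label_a: str
    label_b: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            f"mean_{self.label_a}": self.mean_a,
            f"mean_{self.label_b}": self.mean_b,
            f"se_{self.label_a}": self.se_a,
            f"se_{self.label_b}": self.se_b,
        })


@dataclass
class BootstrapTestResult:
    z0: float
    iterations: int
    exceed_count: int
    p: float


@dataclass
class PermutationTestResult:
    t0: float
    permutations: int
    exceed_count: int
    p: float


def _two_labels(row_labels: Sequence[str]) -> tuple[str, str]:
    return ordered_class_labels(row_labels)


def bootstrap_se_of_mean(
    values: np.ndarray, iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """SD of the column mean over `iterations` with-replacement resamples.

    ``values`` is (n, L); returns a length-L vector.
    """
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 members to bootstrap")
    idx = rng.integers(0, n, size=(iterations, n))
    means = values[idx].mean(axis=1)  # (iterations, L)
    return means.std(axis=0, ddof=0)


def position_mean_profile(
    masked: MaskedMatrix,
    iterations: int = 1000,
    seed: int | None = None,
) -> PositionProfile:
    """Class mean and bootstrap SE per matrix column (empirical resampling)."""
    label_a, label_b = _two_labels(masked.row_labels)
    rng = np.random.default_rng(seed)
    a = masked.rows_for_label(label_a)
    b = masked.rows_for_label(label_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least 2 members")
    return PositionProfile(
        mean_a=a.mean(axis=0),
        mean_b=b.mean(axis=0),
        se_a=bootstrap_se_of_mean(a, iterations, rng),
        se_b=bootstrap_se_of_mean(b, iterations, rng),
        n_a=a.shape[0],
        n_b=b.shape[0],
        label_a=label_a,
        label_b=label_b,
    )


def _studentized_z(
    mean1: np.ndarray, var1: np.ndarray, n1: int,
    mean2: np.ndarray, var2: np.ndarray, n2: int,
) -> np.ndarray:
    denom = np.sqrt(var2 / n2 + var1 / n1)
    num = mean2 - mean1
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / denom
    # 0/0 -> 0 (no difference, no spread); x/0 -> +-inf kept as-is
    z = np.where((denom == 0) & (num == 0), 0.0, z)
    return z


def studentized_bootstrap_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    iterations: int = 1000,
    seed: int | None = None,
    null: str = "pooled_resample",
) -> BootstrapTestResult:
    """Two-sided Studentized bootstrap test of equal means.

    The empirical statistic z0 Studentizes the difference of group means.
    Null replicates pool both groups without labels and draw n1 and n2
    observations from the pool — with replacement by default
    (``null='pooled_resample'``) or as a random partition of the pooled sample
    (``null='partition'``).  Significance counts replicates with z^2 >= z0^2,
    so p is floored at 1/(R+1) and never reaches 0.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if null not in ("pooled_resample", "partition"):
        raise ValueError(f"unknown null mode {null!r}")

    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    z0 = float(_studentized_z(a.mean(), var_a, n1, b.mean(), var_b, n2))

    # degenerate data: both groups constant
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            return BootstrapTestResult(z0=0.0, iterations=iterations,
                                       exceed_count=iterations, p=1.0)
        return BootstrapTestResult(z0=float("inf"), iterations=iterations,
                                   exceed_count=0, p=1.0 / (iterations + 1))

    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    n = pool.size
    if null == "pooled_resample":
        s1 = pool[rng.integers(0, n, size=(iterations, n1))]
        s2 = pool[rng.integers(0, n, size=(iterations, n2))]
    else:
        perm = rng.permuted(np.broadcast_to(pool, (iterations, n)).copy(), axis=1)
        s1, s2 = perm[:, :n1], perm[:, n1:]
    z_null = _studentized_z(
        s1.mean(axis=1), s1.var(axis=1, ddof=1), n1,
        s2.mean(axis=1), s2.var(axis=1, ddof=1), n2,
    )
    # replicates where both resamples are constant but unequal give +-inf;
    # inf^2 >= z0^2 correctly counts them as extreme
    exceed = int(np.count_nonzero(np.square(z_null) >= z0 * z0))
    p = (1 + exceed) / (iterations + 1)
    return BootstrapTestResult(z0=z0, iterations=iterations, exceed_count=exceed, p=p)


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    iterations: int = 1000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Label-permutation test preserving group sizes.

    The default statistic is the absolute difference of means (two-sided);
    any callable ``statistic(a, b) -> float`` may be supplied, e.g. a
    mutual-information difference.  p = (1 + #(t >= t0)) / (R + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] + b.shape[0] < 4:
        raise ValueError("pooled size must be at least 4")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n1 = a.shape[0]

    if statistic is None and a.ndim == 1:
        pool = np.concatenate([a, b])
        t0 = abs(a.mean() - b.mean())
        perm = rng.permuted(
            np.broadcast_to(pool, (iterations, pool.size)).copy(), axis=1
        )
        t = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
        exceed = int(np.count_nonzero(t >= t0))
    else:
        stat = statistic or (lambda x, y: abs(float(np.mean(x)) - float(np.mean(y))))
        pool = np.concatenate([a, b], axis=0)
        t0 = float(stat(a, b))
        exceed = 0
        for _ in range(iterations):
            idx = rng.permutation(pool.shape[0])
            if stat(pool[idx[:n1]], pool[idx[n1:]]) >= t0:
                exceed += 1
    p = (1 + exceed) / (iterations + 1)
    return PermutationTestResult(t0=float(t0), permutations=iterations,
                                 exceed_count=exceed, p=p)


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni-adjusted p: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) else min(1.0, p * m)


def significant_runs(flags: Sequence[bool]) -> list[tuple[int, int]]:
    """Contiguous True stretches as 0-based half-open [start, end) intervals."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def profile_significance(
    masked: MaskedMatrix,
    iterations: int = 1000,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    seed: int | None = None,
    null: str = "pooled_resample",
) -> pd.DataFrame:
    """Column-wise Studentized bootstrap p-values with optional Bonferroni.

    Buffer columns (all-zero in both classes) are reported untestable with
    NaN p.  The result is a tidy frame: column, means, SEs, p_raw, p_adj,
    significant, plus an attached ``.attrs['runs']`` list of contiguous
    significant column intervals.
    """
    label_a, label_b = _two_labels(masked.row_labels)
    a = masked.rows_for_label(label_a)
    b = masked.rows_for_label(label_b)
    rng = np.random.default_rng(seed)
    L = masked.values.shape[1]
    profile = position_mean_profile(masked, iterations=iterations,
                                    seed=None if seed is None else seed + 1)
    p_raw = np.full(L, np.nan)
    testable = np.zeros(L, dtype=bool)
    for col in range(L):
        col_a, col_b = a[:, col], b[:, col]
        if np.all(col_a == 0) and np.all(col_b == 0):
            continue  # buffer column, not testable
        res = studentized_bootstrap_test(
            col_a, col_b, iterations=iterations,
            seed=int(rng.integers(0, 2**31 - 1)), null=null,
        )
        p_raw[col] = res.p
        testable[col] = True
    m = bonferroni_m if bonferroni_m is not None else 1
    p_adj = np.where(np.isnan(p_raw), np.nan, np.minimum(1.0, p_raw * m))
    significant = testable & (p_adj <= alpha)
    df = pd.DataFrame({
        "column": np.arange(L),
        f"mean_{label_a}": profile.mean_a,
        f"mean_{label_b}": profile.mean_b,
        f"se_{label_a}": profile.se_a,
        f"se_{label_b}": profile.se_b,
        "testable": testable,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "significant": significant,
    })
    df.attrs["runs"] = significant_runs(significant.tolist())
    return df
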