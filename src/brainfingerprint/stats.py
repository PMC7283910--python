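"""Quantitative comparisons between STE matrices.

Covers the average-Euclidean-distance summaries (between participants for a
matched condition vs. between conditions within a participant), the
two-sample z-test comparing the two distance groups, and the two-way
fixed-effects ANOVA with replication applied to the stacked spectrum
vectors (conditions × replicates rows, participants as columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .ste import STEMatrix


def matrix_distance(a: STEMatrix | np.ndarray, b: STEMatrix | np.ndarray) -> float:
    """Euclidean (Frobenius) distance between two coupling matrices."""
    av = a.values if isinstance(a, STEMatrix) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, STEMatrix) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {bv.shape}")
    return float(np.sqrt(((av - bv) ** 2).sum()))


def pair_count(n: int) -> int:
    """Number of unordered pairs n·(n−1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 items to form pairs, got {n}")
    return n * (n - 1) // 2


@dataclass
class DistanceSummary:
    """Mean/SD of a group of pairwise matrix distances."""

    label: str
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)

    @property
    def n_pairs(self) -> int:
        return self.distances.size

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        return float(self.distances.std(ddof=1)) if self.n_pairs > 1 else 0.0


def distance_summaries(
    matrices: Iterable[STEMatrix],
) -> tuple[DistanceSummary, DistanceSummary]:
    """Between-participant and within-participant distance groups.

    Between: unordered participant pairs compared on the same (task, event)
    condition.  Within: unordered (task, event) condition pairs of the same
    participant.  Each matrix is labelled by its own context.
    """
    by_key: dict[tuple[int, int, int], STEMatrix] = {}
    for m in matrices:
        by_key[(m.participant_id, m.task, m.event)] = m
    participants = sorted({p for p, _, _ in by_key})
    conditions = sorted({(t, e) for _, t, e in by_key})
    if len(participants) < 2 or len(conditions) < 2:
        raise ValueError("need at least 2 participants and 2 conditions")

    between = []
    for t, e in conditions:
        for pa, pb in combinations(participants, 2):
            ka, kb = (pa, t, e), (pb, t, e)
            if ka in by_key and kb in by_key:
                between.append(matrix_distance(by_key[ka], by_key[kb]))
    within = []
    for p in participants:
        for (ta, ea), (tb, eb) in combinations(conditions, 2):
            ka, kb = (p, ta, ea), (p, tb, eb)
            if ka in by_key and kb in by_key:
                within.append(matrix_distance(by_key[ka], by_key[kb]))
    return (
        DistanceSummary("between_participants", np.array(between)),
        DistanceSummary("within_participant", np.array(within)),
    )


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p_one_tailed: float
    p_two_tailed: float
    critical_one_tailed: float
    critical_two_tailed: float
    alpha: float


def two_sample_ztest(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = 0.01,
) -> ZTestResult:
    """Two-sample z-test from group summaries.

    ``z = (mean1 − mean2) / sqrt(sd1²/n1 + sd2²/n2)`` with normal reference
    distribution; at α = 0.01 the critical values are 2.326 (one-tailed) and
    2.576 (two-tailed).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    se = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
    z = (mean1 - mean2) / se
    return ZTestResult(
        z=float(z),
        p_one_tailed=float(sstats.norm.sf(abs(z))),
        p_two_tailed=float(2 * sstats.norm.sf(abs(z))),
        critical_one_tailed=float(sstats.norm.ppf(1 - alpha)),
        critical_two_tailed=float(sstats.norm.ppf(1 - alpha / 2)),
        alpha=alpha,
    )


def two_way_anova(
    data: np.ndarray,
    n_column_levels: int,
    n_row_levels: int,
    n_replicates: int,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with replication.

    ``data`` has ``n_row_levels × n_replicates`` rows (replicates stacked
    within each row level) and ``n_column_levels`` columns.  Returns a table
    with SS, df, MS, F and p for Columns, Rows, Interaction, Error, Total;
    degrees of freedom are additive by construction.
    """
    data = np.asarray(data, dtype=float)
    if data.shape != (n_row_levels * n_replicates, n_column_levels):
        raise ValueError(
            f"data shape {data.shape} incompatible with "
            f"{n_row_levels} row levels × {n_replicates} replicates × "
            f"{n_column_levels} columns"
        )
    c, r, reps = n_column_levels, n_row_levels, n_replicates
    cells = data.reshape(r, reps, c)  # (row level, replicate, column)
    grand = data.mean()
    col_means = data.mean(axis=0)  # (c,)
    row_means = cells.mean(axis=(1, 2))  # (r,)
    cell_means = cells.mean(axis=1)  # (r, c)

    ss_col = r * reps * float(((col_means - grand) ** 2).sum())
    ss_row = c * reps * float(((row_means - grand) ** 2).sum())
    ss_int = reps * float(
        ((cell_means - col_means[None, :] - row_means[:, None] + grand) ** 2).sum()
    )
    ss_err = float(((cells - cell_means[:, None, :]) ** 2).sum())
    ss_tot = float(((data - grand) ** 2).sum())

    df_col = c - 1
    df_row = r - 1
    df_int = df_col * df_row
    df_err = c * r * (reps - 1)
    df_tot = c * r * reps - 1

    ms_col, ms_row, ms_int = ss_col / df_col, ss_row / df_row, ss_int / df_int
    ms_err = ss_err / df_err if df_err else np.nan
    def f_and_p(ms: float, df: int) -> tuple[float, float]:
        if not df_err or ms_err == 0:
            return np.nan, np.nan
        f = ms / ms_err
        return f, float(sstats.f.sf(f, df, df_err))

    f_col, p_col = f_and_p(ms_col, df_col)
    f_row, p_row = f_and_p(ms_row, df_row)
    f_int, p_int = f_and_p(ms_int, df_int)

    return pd.DataFrame(
        {
            "SS": [ss_col, ss_row, ss_int, ss_err, ss_tot],
            "df": [df_col, df_row, df_int, df_err, df_tot],
            "MS": [ms_col, ms_row, ms_int, ms_err, np.nan],
            "F": [f_col, f_row, f_int, np.nan, np.nan],
            "p": [p_col, p_row, p_int, np.nan, np.nan],
        },
        index=["Columns", "Rows", "Interaction", "Error", "Total"],
    )
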