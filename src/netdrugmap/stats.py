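"""Statistical layer: chi-square independence test, balanced three-way
ANOVA without replication, and Tukey HSD post-hoc comparisons.

The factorial design analysed here is the rate table of the phase
comparison: factors DISEASE × PHASE × TARGET with exactly one percentage
observation per cell. With no replication the three-way interaction is
confounded with error, so it serves as the residual term — main effects and
two-way interactions are tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


def chi_square_independence(
    table, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r×c count table.

    Returns ``(statistic, dof, p_value)``. Zero marginal rows or columns
    are rejected — such a table has undefined expected counts.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be 2-D with at least 2 rows and 2 columns")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=yates)
    return float(stat), int(dof), float(p)


@dataclass
class AnovaResult:
    """Three-way ANOVA summary for a single-observation-per-cell design."""

    factors: tuple[str, str, str]
    ss: dict[str, float]
    df: dict[str, int]
    f_stats: dict[str, float]
    p_values: dict[str, float]
    residual_ss: float
    residual_df: int
    zero_residual: bool = False
    tukey: dict[str, "TukeyTable"] = field(default_factory=dict)

    @property
    def ms_error(self) -> float:
        return self.residual_ss / self.residual_df

    def summary(self) -> str:
        lines = [f"{'effect':<20}{'df':>4}{'SS':>12}{'F':>10}{'p':>12}  sig"]
        for eff in self.f_stats:
            lines.append(
                f"{eff:<20}{self.df[eff]:>4}{self.ss[eff]:>12.4f}"
                f"{self.f_stats[eff]:>10.3f}{self.p_values[eff]:>12.4g}"
                f"  {significance_stars(self.p_values[eff])}"
            )
        lines.append(f"{'residual':<20}{self.residual_df:>4}{self.residual_ss:>12.4f}")
        return "\n".join(lines)


def _marginal_mean(cells: np.ndarray, keep: tuple[int, ...]) -> np.ndarray:
    drop = tuple(ax for ax in range(cells.ndim) if ax not in keep)
    return cells.mean(axis=drop, keepdims=True)


def three_way_anova(
    cells,
    factors: Sequence[str] = ("DISEASE", "PHASE", "TARGET"),
    levels: Sequence[Sequence[str]] | None = None,
) -> AnovaResult:
    """Balanced three-way ANOVA on an a×b×c array of single observations.

    ``cells`` may be a 3-D array or any object with a ``to_anova_array()``
    method returning ``(array, factors, levels)`` (the rate table provides
    one). Sums of squares follow the standard balanced decomposition from
    marginal means; the three-way interaction is the residual. When the
    residual SS is numerically zero (noise-free constructed data), F values
    are reported as 0 for null effects and ``inf`` otherwise, with the
    ``zero_residual`` flag set.
    """
    if hasattr(cells, "to_anova_array"):
        cells, factors, levels = cells.to_anova_array()
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3:
        raise ValueError("cells must be a 3-D array (one observation per cell)")
    shape = cells.shape
    if min(shape) < 2:
        small = [f for f, n in zip(factors, shape) if n < 2]
        raise ValueError(f"every factor needs at least 2 levels; too few in {small}")
    if np.isnan(cells).any():
        idx = tuple(int(i) for i in np.argwhere(np.isnan(cells))[0])
        cell_name = (
            tuple(levels[ax][i] for ax, i in enumerate(idx)) if levels else idx
        )
        raise ValueError(f"missing cell {cell_name}")

    grand = cells.mean()
    n_total = cells.size
    ss_total = float(((cells - grand) ** 2).sum())

    names = {0: factors[0], 1: factors[1], 2: factors[2]}
    ss: dict[str, float] = {}
    df: dict[str, int] = {}
    # main effects: deviations of one-way marginal means from the grand mean
    for ax in range(3):
        dev = _marginal_mean(cells, (ax,)) - grand
        ss[names[ax]] = float((dev**2).sum() * n_total / shape[ax])
        df[names[ax]] = shape[ax] - 1
    # two-way interactions: cell-mean deviations net of both main effects
    for a, b in combinations(range(3), 2):
        dev = (
            _marginal_mean(cells, (a, b))
            - _marginal_mean(cells, (a,))
            - _marginal_mean(cells, (b,))
            + grand
        )
        key = f"{names[a]}x{names[b]}"
        ss[key] = float((dev**2).sum() * n_total / (shape[a] * shape[b]))
        df[key] = (shape[a] - 1) * (shape[b] - 1)

    residual_ss = ss_total - sum(ss.values())
    residual_ss = max(residual_ss, 0.0)  # guard tiny negative round-off
    residual_df = (shape[0] - 1) * (shape[1] - 1) * (shape[2] - 1)

    zero_residual = residual_ss <= 1e-12 * max(ss_total, 1.0)
    f_stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for key in ss:
        if zero_residual:
            f = 0.0 if ss[key] <= 1e-12 * max(ss_total, 1.0) else float("inf")
            p = 1.0 if f == 0.0 else 0.0
        else:
            ms_e = residual_ss / residual_df
            f = (ss[key] / df[key]) / ms_e
            p = float(sps.f.sf(f, df[key], residual_df))
        f_stats[key] = f
        p_values[key] = p

    return AnovaResult(
        factors=tuple(factors),
        ss=ss, df=df, f_stats=f_stats, p_values=p_values,
        residual_ss=residual_ss, residual_df=residual_df,
        zero_residual=zero_residual,
    )


@dataclass
class TukeyTable:
    """Pairwise Tukey HSD comparisons for one factor's levels."""

    levels: list[str]
    rows: list[dict]  # {level_a, level_b, difference, q, p_adjusted}

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def tukey_hsd(
    cell_means: Mapping[str, float],
    ms_error: float,
    df_error: int,
    group_size: int,
) -> TukeyTable:
    """Tukey HSD on k level means from a balanced design.

    ``group_size`` is the number of observations averaged into each level
    mean. Adjusted p-values come from the studentized-range distribution
    with k groups and ``df_error`` error degrees of freedom.
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    levels = sorted(cell_means)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels")
    se = np.sqrt(ms_error / group_size)
    rows = []
    for a, b in combinations(levels, 2):
        diff = cell_means[a] - cell_means[b]
        if se == 0.0:
            q = 0.0 if diff == 0 else float("inf")
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
        rows.append({
            "level_a": a, "level_b": b,
            "difference": float(diff), "q": float(q),
            "p_adjusted": min(max(p, 0.0), 1.0),
        })
    return TukeyTable(levels=levels, rows=rows)
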