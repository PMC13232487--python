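"""Adipocyte morphometry and nested group statistics.

Size distributions are computed over filter-passing cells; aggregation is
strictly field → animal → group, with the animal as the biological
replicate: per-field values are averaged within each animal first, and
group means ± SEM are taken across animals.  Group differences are tested
with one-way ANOVA followed by Tukey's HSD multiple-comparison test at the
conventional p < 0.05 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cls import ClsScore, field_cls_percentage
from .segmentation import CellRecord

__all__ = [
    "DEFAULT_BIN_EDGES",
    "SizeDistribution",
    "FieldSummary",
    "summarize_field",
    "size_distribution",
    "aggregate",
    "one_way_anova_tukey",
    "AnovaTukeyResult",
]

#: Default area histogram: 500 µm² bins up to 16,000 µm².
DEFAULT_BIN_EDGES = np.arange(0.0, 16_500.0, 500.0)

#: Significance level used for the post hoc flags.
ALPHA = 0.05


@dataclass
class SizeDistribution:
    """Histogram + mean ± SEM of adipocyte areas (µm²)."""

    counts: np.ndarray
    bin_edges: np.ndarray
    n: int
    mean: float
    sem: float | None  # None (undefined) when n == 1


@dataclass
class FieldSummary:
    """Per-field quantification: cell count, %CLS and size statistics."""

    animal_id: str
    group: str
    field_id: str
    n_cells_passed: int
    pct_cls: float
    mean_area_um2: float
    sem_area_um2: float | None
    area_histogram: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "group": self.group,
            "field_id": self.field_id,
            "n_cells_passed": self.n_cells_passed,
            "pct_cls": self.pct_cls,
            "mean_area_um2": self.mean_area_um2,
            "sem_area_um2": self.sem_area_um2,
        }


def size_distribution(
    cells: Sequence[CellRecord] | np.ndarray,
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> SizeDistribution:
    """Area histogram with half-open bins [lo, hi), plus mean ± SEM.

    Accepts either CellRecords (only ``passed_filters`` cells are counted)
    or a plain array of areas in µm².  With a single cell the SEM is
    undefined and reported as ``None``.
    """
    if len(cells) and isinstance(cells[0], CellRecord):
        areas = np.array([c.area_um2 for c in cells if c.passed_filters])
    else:
        areas = np.asarray(cells, dtype=float)
    if areas.size == 0:
        raise ValueError("no passing cells: size distribution is undefined")
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    # np.histogram closes the last bin on the right; enforce [lo, hi)
    # everywhere by digitizing instead.
    idx = np.digitize(areas, bin_edges, right=False)  # 1..nbins for in-range
    counts = np.bincount(idx, minlength=len(bin_edges) + 1)[1 : len(bin_edges)]
    sem = float(stats.sem(areas, ddof=1)) if areas.size > 1 else None
    return SizeDistribution(
        counts=counts,
        bin_edges=bin_edges,
        n=int(areas.size),
        mean=float(areas.mean()),
        sem=sem,
    )


def summarize_field(
    cells: Sequence[CellRecord],
    scores: Sequence[ClsScore],
    animal_id: str = "",
    group: str = "",
    field_id: str = "",
    bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
) -> FieldSummary:
    """Combine segmentation and CLS scoring into one per-field summary."""
    dist = size_distribution(cells, bin_edges)
    return FieldSummary(
        animal_id=animal_id,
        group=group,
        field_id=field_id,
        n_cells_passed=dist.n,
        pct_cls=field_cls_percentage(scores, cells),
        mean_area_um2=dist.mean,
        sem_area_um2=dist.sem,
        area_histogram=dist.counts,
    )


def aggregate(
    field_summaries: Sequence[FieldSummary] | pd.DataFrame,
    min_fields: int = 10,
    strict_min_fields: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Field → animal → group aggregation.

    Parameters
    ----------
    field_summaries:
        Per-field summaries (or an equivalent DataFrame with columns
        ``animal_id, group, field_id, n_cells_passed, pct_cls,
        mean_area_um2``).
    min_fields:
        Minimum number of fields per animal demanded by the acquisition
        protocol (default 10).  Animals below the minimum trigger a
        warning, or a ``ValueError`` when ``strict_min_fields`` is set.

    Returns
    -------
    (animal_table, group_table):
        Per-animal means over fields, and group mean ± SEM over animals
        (SEM = sd/√n_animals, ddof=1).
    """
    if isinstance(field_summaries, pd.DataFrame):
        df = field_summaries.copy()
    else:
        df = pd.DataFrame([s.to_row() for s in field_summaries])
    if df.empty:
        raise ValueError("no field summaries to aggregate")

    n_fields = df.groupby("animal_id").size()
    short = n_fields[n_fields < min_fields]
    if len(short):
        msg = (
            f"animals below the {min_fields}-field minimum: "
            + ", ".join(f"{a} ({n})" for a, n in short.items())
        )
        if strict_min_fields:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    animal = (
        df.groupby(["group", "animal_id"], as_index=False)
        .agg(
            n_fields=("field_id", "size"),
            n_cells_total=("n_cells_passed", "sum"),
            pct_cls=("pct_cls", "mean"),
            # alternative reading reported without endorsement: percent of
            # an animal's fields that contain at least one CLS
            pct_fields_with_cls=("pct_cls", lambda x: 100.0 * (x > 0).mean()),
            mean_area_um2=("mean_area_um2", "mean"),
        )
        .assign(below_min_fields=lambda t: t["n_fields"] < min_fields)
    )

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    group = animal.groupby("group", as_index=False).agg(
        n_animals=("animal_id", "size"),
        pct_cls_mean=("pct_cls", "mean"),
        pct_cls_sem=("pct_cls", _sem),
        mean_area_um2=("mean_area_um2", "mean"),
        sem_area_um2=("mean_area_um2", _sem),
    )
    return animal, group


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairs: pd.DataFrame  # columns: group1, group2, p_adj, significant

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def one_way_anova_tukey(
    group_values: Mapping[str, Sequence[float]],
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's multiple-comparison test.

    Classic fixed-effects one-way ANOVA F statistic, with Tukey's honestly
    significant difference post hoc test on the studentized-range
    distribution; pairs are flagged significant at adjusted p < 0.05.
    Requires at least two groups with at least two values each.
    """
    names = list(group_values)
    samples = [np.asarray(group_values[g], dtype=float) for g in names]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for name, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")

    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    if ss_between == 0:
        # all group means equal: F is 0 by definition even when the
        # within-group variance is also 0 (scipy returns nan there)
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*samples)
    with np.errstate(invalid="ignore"):
        tukey = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            p_adj = float(tukey.pvalue[i, j])
            if np.isnan(p_adj):  # degenerate zero-variance comparison
                p_adj = 1.0 if samples[i].mean() == samples[j].mean() else 0.0
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": p_adj,
                    "significant": p_adj < ALPHA,
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p), pairs=pd.DataFrame(rows)
    )
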