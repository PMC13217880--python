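"""Cohort assembly, inclusion filters, stage binning and dataset-level splits.

A cohort row is one cytometry sample: normalized expression of the eight
maturity markers plus metadata (dataset, subject, day post-immune-intervention
(DPI), age, sex, tissue, absolute ASC count). Inclusion follows the study
rules: ASC count >= 50 (configurable to 10/100 for sensitivity analyses) and
subject age >= 10 years; kinetic samples are those with DPI in [5, 180].

Immune-response stages bin DPI into baseline (<=1), very early [5, 10),
early [10, 19], intermediate [20, 50], late [51, 99] and very late
[100, 180]; DPI values in the gaps (1, 5) and above 180 are unassigned.
The printed very-early and early ranges both contain day 10; the half-open
resolution used here makes the labels a partition.

Training/validation splits are made at the dataset level (samples from one
study never cross arms), balancing the achieved sample fraction against a
75% target with mean DPI as the primary balance parameter and age/sex as
secondary ones, via a seeded greedy swap search with random restarts.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .harmonize import MATURITY_MARKERS

__all__ = [
    "Stage",
    "CohortTable",
    "SplitAssignment",
    "assemble",
    "filter_cohort",
    "assign_stage",
    "assign_stage_column",
    "select_kinetic",
    "trim_values",
    "split_datasets",
    "downsample_equal",
    "METADATA_COLUMNS",
]

logger = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "sample_id", "dataset_id", "subject_id", "dpi", "age", "sex",
    "tissue", "asc_count",
)


class Stage(str, enum.Enum):
    baseline = "baseline"
    very_early = "very_early"
    early = "early"
    intermediate = "intermediate"
    late = "late"
    very_late = "very_late"
    unassigned = "unassigned"


#: Ordered stage bins (lo, hi, closed-right?) after the partition resolution.
STAGE_ORDER = (
    Stage.baseline, Stage.very_early, Stage.early,
    Stage.intermediate, Stage.late, Stage.very_late,
)


@dataclass
class CohortTable:
    """A per-sample table (pandas DataFrame) with an append-only provenance
    log of the filters applied to it."""

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    markers: tuple[str, ...] = MATURITY_MARKERS

    def __post_init__(self) -> None:
        if "sample_id" in self.df.columns and self.df["sample_id"].duplicated().any():
            dupes = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id values: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame, note: str) -> "CohortTable":
        return CohortTable(df=df.reset_index(drop=True),
                          provenance=[*self.provenance, note],
                          markers=self.markers)

    def marker_frame(self) -> pd.DataFrame:
        return self.df[list(self.markers)]


def assemble(expr_table: pd.DataFrame, metadata_table: pd.DataFrame,
             markers=MATURITY_MARKERS) -> CohortTable:
    """Inner-join normalized-expression rows with metadata on ``sample_id``.

    Unmatched rows on either side are logged and dropped; missing metadata
    fields stay missing. Duplicate sample ids raise.
    """
    for name, tab in (("expression", expr_table), ("metadata", metadata_table)):
        if "sample_id" not in tab.columns:
            raise KeyError(f"{name} table lacks a sample_id column")
        if tab["sample_id"].duplicated().any():
            raise ValueError(f"duplicate sample_id in {name} table")
    merged = expr_table.merge(metadata_table, on="sample_id", how="inner",
                              suffixes=("", "_meta"))
    orphans_expr = set(expr_table["sample_id"]) - set(merged["sample_id"])
    orphans_meta = set(metadata_table["sample_id"]) - set(merged["sample_id"])
    if orphans_expr:
        logger.warning("%d expression rows had no metadata match: %s",
                       len(orphans_expr), sorted(orphans_expr)[:5])
    if orphans_meta:
        logger.info("%d metadata rows had no expression match", len(orphans_meta))
    if merged.empty:
        logger.warning("assembled cohort is empty")
    markers = tuple(m for m in markers if m in merged.columns)
    return CohortTable(
        df=merged.reset_index(drop=True),
        provenance=[f"assembled: {len(merged)} records "
                    f"({len(orphans_expr)} expression orphans dropped)"],
        markers=markers or MATURITY_MARKERS,
    )


def filter_cohort(c: CohortTable, min_asc: int = 50, min_age: float = 10.0) -> CohortTable:
    """Inclusion filter: ASC count >= *min_asc* and subject age present and
    >= *min_age* years. ``min_asc`` in {10, 50, 100} reproduces the
    sensitivity analysis around the count cut-off."""
    df = c.df
    ok_asc = df["asc_count"] >= min_asc
    ok_age = df["age"].notna() & (df["age"] >= min_age)
    kept = df[ok_asc & ok_age]
    n_asc = int((~ok_asc).sum())
    n_age = int((ok_asc & ~ok_age).sum())
    if n_asc or n_age:
        logger.info("filter_cohort: excluded %d (ASC count < %d) and %d "
                    "(age missing or < %g y)", n_asc, min_asc, n_age, min_age)
    return c.with_df(kept, f"filter: asc_count>={min_asc}, age>={min_age} "
                           f"({n_asc}+{n_age} excluded)")


def assign_stage(dpi: float | None) -> Stage:
    """Immune-response stage for one DPI value (see module docstring bins)."""
    if dpi is None or (isinstance(dpi, float) and np.isnan(dpi)):
        return Stage.unassigned
    if dpi < 0:
        raise ValueError(f"negative DPI: {dpi}")
    if dpi <= 1:
        return Stage.baseline
    if 5 <= dpi < 10:
        return Stage.very_early
    if 10 <= dpi <= 19:
        return Stage.early
    if 20 <= dpi <= 50:
        return Stage.intermediate
    if 51 <= dpi <= 99:
        return Stage.late
    if 100 <= dpi <= 180:
        return Stage.very_late
    return Stage.unassigned


def assign_stage_column(df: pd.DataFrame, dpi_col: str = "dpi") -> pd.Series:
    return df[dpi_col].map(lambda v: assign_stage(v).value)


def select_kinetic(c: CohortTable, min_dpi: float = 5.0, max_dpi: float = 180.0) -> CohortTable:
    """Keep kinetic samples: DPI present and within [min_dpi, max_dpi] days."""
    df = c.df
    keep = df["dpi"].notna() & (df["dpi"] >= min_dpi) & (df["dpi"] <= max_dpi)
    return c.with_df(df[keep],
                     f"kinetic: {min_dpi}<=dpi<={max_dpi} ({int((~keep).sum())} excluded)")


def trim_values(c: CohortTable, low: float = -2.0, high: float = 5.0) -> CohortTable:
    """Set normalized expression values outside [low, high] to missing.

    Value-level (not sample-level) removal: the sample survives and the
    trimmed cells are filled back in by imputation downstream.
    """
    df = c.df.copy()
    marker_cols = list(c.markers)
    block = df[marker_cols]
    out_of_range = (block < low) | (block > high)
    n_trimmed = int(out_of_range.sum().sum())
    df[marker_cols] = block.mask(out_of_range)
    if n_trimmed:
        logger.info("trim_values: %d values outside [%g, %g] set to missing",
                    n_trimmed, low, high)
    return c.with_df(df, f"trim to [{low},{high}]: {n_trimmed} values -> missing")


@dataclass
class SplitAssignment:
    """Dataset -> arm assignment plus the achieved balance diagnostics."""

    assignment: dict[str, str]  # dataset_id -> "train" | "validation"
    achieved_train_fraction: float
    balance_report: pd.DataFrame
    objective: float

    def arm(self, c: CohortTable, arm: str) -> CohortTable:
        ids = [d for d, a in self.assignment.items() if a == arm]
        return c.with_df(c.df[c.df["dataset_id"].isin(ids)], f"split arm={arm}")


def _split_objective(df: pd.DataFrame, datasets: list[str], is_train: np.ndarray,
                     sizes: np.ndarray, target: float,
                     stats: dict[str, np.ndarray]) -> float:
    n_train = sizes[is_train].sum()
    frac = n_train / sizes.sum()
    obj = abs(frac - target)
    if not is_train.any() or is_train.all():
        return float("inf")
    for key, weight in (("dpi", 1.0), ("age", 0.25), ("sex", 0.25)):
        vals, weights, sd = stats[key]
        tr_w = weights[is_train].sum()
        va_w = weights[~is_train].sum()
        if tr_w == 0 or va_w == 0 or sd == 0:
            continue
        mean_tr = (vals[is_train] * weights[is_train]).sum() / tr_w
        mean_va = (vals[~is_train] * weights[~is_train]).sum() / va_w
        obj += weight * abs(mean_tr - mean_va) / sd
    return float(obj)


def split_datasets(
    c: CohortTable,
    target_fraction: float = 0.75,
    seed: int = 0,
    n_restarts: int = 200,
) -> SplitAssignment:
    """Assign whole datasets to training vs validation arms.

    Greedy swap search with seeded random restarts minimizing
    ``|achieved sample fraction - target|`` plus standardized absolute
    differences of arm-wise mean DPI (weight 1) and mean age / sex proportion
    (weight 0.25 each). Deterministic for a given seed.
    """
    df = c.df
    datasets = sorted(df["dataset_id"].unique())
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to split")
    sizes = np.array([int((df["dataset_id"] == d).sum()) for d in datasets])

    def per_dataset(col: str, transform=None):
        vals, weights = [], []
        for d in datasets:
            sub = df.loc[df["dataset_id"] == d, col]
            if transform is not None:
                sub = transform(sub)
            sub = pd.to_numeric(sub, errors="coerce").dropna()
            if len(sub):
                vals.append(float(sub.mean()))
                weights.append(len(sub))
            else:
                vals.append(0.0)
                weights.append(0)
        v = np.array(vals)
        w = np.array(weights, dtype=float)
        sd = float(np.sqrt(np.average((v - np.average(v, weights=np.maximum(w, 1e-9))) ** 2,
                                      weights=np.maximum(w, 1e-9)))) if len(v) > 1 else 0.0
        return v, w, sd

    stats = {
        "dpi": per_dataset("dpi"),
        "age": per_dataset("age"),
        "sex": per_dataset("sex", transform=lambda s: s.map(
            {"F": 1.0, "M": 0.0, "f": 1.0, "m": 0.0}) if s.dtype == object else s),
    }

    rng = np.random.default_rng(seed)
    k = len(datasets)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(n_restarts):
        is_train = rng.random(k) < target_fraction
        if not is_train.any():
            is_train[rng.integers(k)] = True
        obj = _split_objective(df, datasets, is_train, sizes, target_fraction, stats)
        improved = True
        while improved:
            improved = False
            for i in range(k):
                cand = is_train.copy()
                cand[i] = ~cand[i]
                cand_obj = _split_objective(df, datasets, cand, sizes,
                                            target_fraction, stats)
                if cand_obj < obj - 1e-12:
                    is_train, obj = cand, cand_obj
                    improved = True
        if best is None or obj < best[0]:
            best = (obj, is_train.copy())
    obj, is_train = best
    assignment = {d: ("train" if t else "validation")
                  for d, t in zip(datasets, is_train)}
    frac = float(sizes[is_train].sum() / sizes.sum())

    report_rows = []
    for arm, mask in (("train", is_train), ("validation", ~is_train)):
        row = {"arm": arm, "n_datasets": int(mask.sum()),
               "n_samples": int(sizes[mask].sum())}
        for key in ("dpi", "age", "sex"):
            v, w, _sd = stats[key]
            tot = w[mask].sum()
            row[f"mean_{key}"] = float((v[mask] * w[mask]).sum() / tot) if tot else np.nan
        report_rows.append(row)
    return SplitAssignment(
        assignment=assignment,
        achieved_train_fraction=frac,
        balance_report=pd.DataFrame(report_rows),
        objective=float(obj),
    )


def downsample_equal(c: CohortTable, n_per_dataset: int, seed: int = 0) -> CohortTable:
    """Randomly keep at most *n_per_dataset* samples per dataset (without
    replacement, seeded) — the equal-sample-size sensitivity analysis."""
    if n_per_dataset < 1:
        raise ValueError("n_per_dataset must be >= 1")
    rng = np.random.default_rng(seed)
    kept_idx: list[np.ndarray] = []
    for d in sorted(c.df["dataset_id"].unique()):
        idx = c.df.index[c.df["dataset_id"] == d].to_numpy()
        if len(idx) > n_per_dataset:
            idx = rng.choice(idx, size=n_per_dataset, replace=False)
        kept_idx.append(np.sort(idx))
    keep = np.concatenate(kept_idx) if kept_idx else np.array([], dtype=int)
    return c.with_df(c.df.loc[keep], f"downsample to <= {n_per_dataset}/dataset")
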