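"""Control-population-anchored normalization of ASC marker expression.

Raw median fluorescence (or metal) intensities — MedFI — are not comparable
across instruments, panels and staining protocols. Each sample, however,
contains internal cell populations with known marker expression: T cells are
negative for B-lineage markers, B cells are positive for CD19/CD20/HLA-DR,
and so on. Anchoring the ASC MedFI between a negative and a positive control
population measured in the same tube,

    normalized = (MedFI_ASC - MedFI_neg) / (MedFI_pos - MedFI_neg),

yields a unitless value with 0 at the negative control and 1 at the positive
control that is invariant under any positive affine rescaling of the raw
intensity axis — precisely the per-sample batch effects the anchoring is
meant to remove. Values can fall outside [0, 1] (ASCs brighter than the
positive control, or dimmer than the negative one); downstream modelling
trims to a configured range.

For markers without a natural positive lymphocyte population (CD56, CD138,
Ki67, CD28) the default positive control is the top decile of all live
cells on that marker, materialized as a ``live_<marker>_top10`` population.
All control assignments are overridable via :class:`ControlSpec`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs_io import EventMatrix
from .gating import PopulationResult

__all__ = [
    "MATURITY_MARKERS",
    "MarkerMedFI",
    "ControlSpec",
    "NormalizedExpression",
    "NormalizationError",
    "compute_medfi",
    "normalize_marker",
    "normalize_sample",
    "add_top_decile_controls",
    "qc_overlay_summary",
    "default_control_spec",
]

logger = logging.getLogger(__name__)

#: The eight maturity markers used by the prediction model.
MATURITY_MARKERS: tuple[str, ...] = (
    "CD19", "CD20", "CD28", "CD45", "CD56", "CD138", "HLA-DR", "Ki67",
)


class NormalizationError(ValueError):
    pass


@dataclass
class MarkerMedFI:
    """Median intensity per (population, marker); empty populations absent."""

    values: dict[tuple[str, str], float]
    sample_id: str = ""

    def get(self, population: str, marker: str) -> float | None:
        return self.values.get((population, marker))


@dataclass
class ControlSpec:
    """Per-marker negative/positive control population names."""

    controls: dict[str, tuple[str, str]]  # marker -> (negative, positive)

    def __post_init__(self) -> None:
        for marker, (neg, pos) in self.controls.items():
            if neg == pos:
                raise NormalizationError(
                    f"{marker}: positive and negative control must differ"
                )


def default_control_spec(markers=MATURITY_MARKERS) -> ControlSpec:
    """T cells as negative control throughout; B cells as positive control
    where the marker is B-cell-expressed, else the live top-decile reference."""
    b_cell_positive = {"CD19", "CD20", "CD45", "HLA-DR"}
    controls = {}
    for m in markers:
        pos = "Bcell" if m in b_cell_positive else f"live_{m}_top10"
        controls[m] = ("Tcell", pos)
    return ControlSpec(controls=controls)


def add_top_decile_controls(
    em: EventMatrix,
    pr: PopulationResult,
    markers,
    base_population: str = "live",
) -> PopulationResult:
    """Add ``<base>_<marker>_top10`` populations: the brightest decile of the
    base population on each marker (reference positives for markers lacking a
    positive lymphocyte population)."""
    base = pr.memberships[base_population]
    for marker in markers:
        name = f"{base_population}_{marker}_top10"
        mask = np.zeros_like(base)
        n_base = int(base.sum())
        if n_base:
            vals = em.marker_values(marker)[base]
            cut = np.quantile(vals, 0.9)
            sel = np.flatnonzero(base)[vals >= cut]
            mask[sel] = True
        pr.memberships[name] = mask
    return pr


def compute_medfi(
    em: EventMatrix,
    pr: PopulationResult,
    markers,
    populations=None,
    sample_id: str = "",
) -> MarkerMedFI:
    """Median of each marker over each population's member events.

    Empty populations yield no entry (never 0). Median convention: mean of
    the two middle order statistics for even counts (numpy's default).
    """
    if populations is None:
        populations = list(pr.memberships)
    values: dict[tuple[str, str], float] = {}
    for pop in populations:
        mask = pr.memberships[pop]
        if not mask.any():
            continue
        for marker in markers:
            try:
                vals = em.marker_values(marker)
            except KeyError:
                continue
            values[(pop, marker)] = float(np.median(vals[mask]))
    return MarkerMedFI(values=values, sample_id=sample_id)


def normalize_marker(medfi_asc: float, medfi_neg: float, medfi_pos: float) -> float:
    """Min-max anchor normalization: (asc - neg) / (pos - neg).

    Returns 0 at the negative control and 1 at the positive control; raises
    :class:`NormalizationError` when the controls coincide (undefined scale).
    """
    denom = medfi_pos - medfi_neg
    if denom == 0 or not math.isfinite(denom):
        raise NormalizationError(
            "positive and negative control MedFI coincide; normalization undefined"
        )
    return (medfi_asc - medfi_neg) / denom


@dataclass
class NormalizedExpression:
    """Per-sample normalized expression of the panel markers.

    Markers absent from the panel, or whose controls were empty, are recorded
    as missing (``None``) — never as 0.
    """

    values: dict[str, float | None]
    sample_id: str = ""
    asc_count: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(
            {m: (np.nan if v is None else v) for m, v in self.values.items()},
            name=self.sample_id,
        )


def normalize_sample(
    medfi: MarkerMedFI,
    cs: ControlSpec,
    asc_population: str = "ASC",
    markers=MATURITY_MARKERS,
    asc_count: int | None = None,
) -> NormalizedExpression:
    """Apply :func:`normalize_marker` per panel marker using the per-marker
    control populations of *cs*; missing controls make that marker missing."""
    asc_present = any(pop == asc_population for (pop, _m) in medfi.values)
    if not asc_present:
        raise NormalizationError(f"ASC population {asc_population!r} absent or empty")
    values: dict[str, float | None] = {}
    for marker in markers:
        if marker not in cs.controls:
            values[marker] = None
            continue
        neg_pop, pos_pop = cs.controls[marker]
        asc = medfi.get(asc_population, marker)
        neg = medfi.get(neg_pop, marker)
        pos = medfi.get(pos_pop, marker)
        if asc is None or neg is None or pos is None:
            values[marker] = None
            logger.info("marker %s: control or ASC MedFI missing; recorded missing", marker)
            continue
        try:
            values[marker] = normalize_marker(asc, neg, pos)
        except NormalizationError:
            values[marker] = None
            logger.warning("marker %s: degenerate controls; recorded missing", marker)
    if asc_count is None:
        asc_count = 0
    return NormalizedExpression(values=values, sample_id=medfi.sample_id,
                                asc_count=asc_count)


_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


def qc_overlay_summary(
    em: EventMatrix,
    pr: PopulationResult,
    cs: ControlSpec,
    markers=MATURITY_MARKERS,
    asc_population: str = "ASC",
) -> pd.DataFrame:
    """Numeric stand-in for the overlay-histogram QC plots: per marker, the
    5/25/50/75/95% quantiles of the ASC, positive-control and negative-control
    distributions plus a ``separated`` flag (neg median <= ASC median <= pos
    median — reported, not enforced)."""
    rows = []
    for marker in markers:
        if marker not in cs.controls:
            continue
        neg_pop, pos_pop = cs.controls[marker]
        entry: dict[str, object] = {"marker": marker}
        medians: dict[str, float | None] = {}
        for role, pop in (("asc", asc_population), ("neg", neg_pop), ("pos", pos_pop)):
            mask = pr.memberships.get(pop)
            if mask is None or not mask.any():
                entry[f"{role}_present"] = False
                medians[role] = None
                for q in _QUANTILES:
                    entry[f"{role}_q{int(q * 100)}"] = np.nan
                continue
            try:
                vals = em.marker_values(marker)[mask]
            except KeyError:
                entry[f"{role}_present"] = False
                medians[role] = None
                for q in _QUANTILES:
                    entry[f"{role}_q{int(q * 100)}"] = np.nan
                continue
            entry[f"{role}_present"] = True
            for q in _QUANTILES:
                entry[f"{role}_q{int(q * 100)}"] = float(np.quantile(vals, q))
            medians[role] = float(np.median(vals))
        if None in medians.values():
            entry["separated"] = False
        else:
            entry["separated"] = bool(
                medians["neg"] <= medians["asc"] <= medians["pos"]
            )
        rows.append(entry)
    return pd.DataFrame(rows)
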