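"""Hierarchical gating from raw events to blood antibody-secreting cells.

ASCs are identified as live, single CD3- CD27+ CD38+ events. The default
gate tree depends on the platform: flow cytometry starts with an FSC-A/SSC-A
cleanup rectangle and an FSC-A/FSC-H singlet ratio band; mass cytometry
starts with a DNA1/DNA2 intercalator rectangle (no scatter channels exist).
Both then remove dead cells (viability dye high), take CD3- non-T cells,
and gate CD27+CD38+ ASCs. Control populations (T cells, B cells) are gated
alongside for the normalization step.

Gate positions are acquisition-dependent in practice; the defaults here sit
at the valley points of the simulator's bimodal log-normal mixtures and every
bound is overridable.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .fcs_io import EventMatrix, Platform

__all__ = [
    "GateKind",
    "GateDef",
    "PopulationResult",
    "GatingError",
    "default_gate_tree",
    "apply_gate_tree",
    "subset_population",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)


class GatingError(ValueError):
    pass


class GateKind(str, enum.Enum):
    threshold1d = "threshold1d"
    rectangle2d = "rectangle2d"
    ratio_band = "ratio_band"


@dataclass
class GateDef:
    """One gate: a named selection rule applied within a parent population.

    * ``threshold1d``: one marker, ``bounds = (threshold,)`` with ``direction``
      "above" (>= threshold) or "below" (< threshold).
    * ``rectangle2d``: two markers, ``bounds = (xmin, xmax, ymin, ymax)``
      (use +/-inf for open sides).
    * ``ratio_band``: two markers, keep ``rmin <= m1/m2 <= rmax``.
    """

    name: str
    parent: str
    kind: GateKind
    markers: tuple[str, ...]
    bounds: tuple[float, ...]
    direction: str | None = None

    def __post_init__(self) -> None:
        self.kind = GateKind(self.kind)
        self.markers = tuple(self.markers)
        self.bounds = tuple(float(b) for b in self.bounds)
        if self.kind is GateKind.threshold1d:
            if len(self.markers) != 1 or len(self.bounds) != 1:
                raise GatingError(f"gate {self.name}: threshold1d takes 1 marker, 1 bound")
            if self.direction not in ("above", "below"):
                raise GatingError(f"gate {self.name}: direction must be above/below")
            if not math.isfinite(self.bounds[0]):
                raise GatingError(f"gate {self.name}: threshold must be finite")
        elif self.kind is GateKind.rectangle2d:
            if len(self.markers) != 2 or len(self.bounds) != 4:
                raise GatingError(f"gate {self.name}: rectangle2d takes 2 markers, 4 bounds")
        else:
            if len(self.markers) != 2 or len(self.bounds) != 2:
                raise GatingError(f"gate {self.name}: ratio_band takes 2 markers, 2 bounds")


@dataclass
class PopulationResult:
    """Event memberships per named population (boolean masks over events)."""

    memberships: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {name: int(mask.sum()) for name, mask in self.memberships.items()}

    def indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.memberships[name])


# Valley points of the simulator's default log-normal mixtures: negatives are
# centred at e^4 ~ 55, positives at e^7 ~ 1100 (sd 0.4 in log space), so any
# cut in (e^5, e^6) separates them by >5 SD; e^5.5 ~ 245 is the midpoint.
_MID = float(np.exp(5.5))

DEFAULT_THRESHOLDS: dict[str, float] = {
    "CD3": _MID,
    "CD19": _MID,
    "CD27": _MID,
    "CD38": _MID,
    "viability": _MID,
    "DNA_low": float(np.exp(5.0)),
    "DNA_high": float(np.exp(9.0)),
    "FSC_low": 3.0e4,
    "FSC_high": 2.5e5,
    "SSC_low": 0.0,
    "SSC_high": 2.0e5,
    "singlet_rmin": 0.75,
    "singlet_rmax": 1.25,
}


def default_gate_tree(
    platform: Platform | str,
    thresholds: dict[str, float] | None = None,
) -> list[GateDef]:
    """Build the default hierarchy root -> cleanup -> (singlets) -> live ->
    CD3- -> ASC, plus T-cell and B-cell control gates.

    *thresholds* overrides entries of :data:`DEFAULT_THRESHOLDS`.
    """
    platform = Platform(platform)
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)

    gates: list[GateDef] = []
    if platform is Platform.flow:
        gates.append(
            GateDef("cleanup", "root", GateKind.rectangle2d, ("FSC-A", "SSC-A"),
                    (t["FSC_low"], t["FSC_high"], t["SSC_low"], t["SSC_high"]))
        )
        gates.append(
            GateDef("singlets", "cleanup", GateKind.ratio_band, ("FSC-A", "FSC-H"),
                    (t["singlet_rmin"], t["singlet_rmax"]))
        )
        live_parent = "singlets"
    else:
        gates.append(
            GateDef("cleanup", "root", GateKind.rectangle2d, ("DNA1", "DNA2"),
                    (t["DNA_low"], t["DNA_high"], t["DNA_low"], t["DNA_high"]))
        )
        live_parent = "cleanup"
    gates.append(
        GateDef("live", live_parent, GateKind.threshold1d, ("viability",),
                (t["viability"],), direction="below")
    )
    gates.append(
        GateDef("Tcell", "live", GateKind.threshold1d, ("CD3",),
                (t["CD3"],), direction="above")
    )
    gates.append(
        GateDef("CD3neg", "live", GateKind.threshold1d, ("CD3",),
                (t["CD3"],), direction="below")
    )
    # B cells: CD19+ CD38-low within CD3- (keeps CD19+ ASCs out of the control)
    gates.append(
        GateDef("Bcell", "CD3neg", GateKind.rectangle2d, ("CD19", "CD38"),
                (t["CD19"], math.inf, -math.inf, t["CD38"]))
    )
    gates.append(
        GateDef("ASC", "CD3neg", GateKind.rectangle2d, ("CD27", "CD38"),
                (t["CD27"], math.inf, t["CD38"], math.inf))
    )
    return gates


def _gate_mask(em: EventMatrix, gate: GateDef) -> np.ndarray:
    try:
        vals = [em.marker_values(m) for m in gate.markers]
    except KeyError as exc:
        raise GatingError(f"gate {gate.name!r}: missing marker {exc.args[0]!r}") from exc
    if gate.kind is GateKind.threshold1d:
        (x,) = vals
        thr = gate.bounds[0]
        return x >= thr if gate.direction == "above" else x < thr
    if gate.kind is GateKind.rectangle2d:
        x, y = vals
        x0, x1, y0, y1 = gate.bounds
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    x, y = vals
    rmin, rmax = gate.bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(y != 0, x / np.where(y != 0, y, 1.0), np.inf)
    return (ratio >= rmin) & (ratio <= rmax)


def apply_gate_tree(em: EventMatrix, gates: list[GateDef]) -> PopulationResult:
    """Apply gates in order; each population's membership is its own rule
    intersected with its parent's membership ("root" = all events)."""
    n = em.n_events
    pr = PopulationResult(memberships={"root": np.ones(n, dtype=bool)})
    for gate in gates:
        if gate.parent not in pr.memberships:
            raise GatingError(
                f"gate {gate.name!r}: parent population {gate.parent!r} not yet defined"
            )
        if gate.kind is GateKind.threshold1d and gate.markers[0] == "viability" \
                and _marker_absent(em, "viability"):
            logger.warning(
                "sample lacks a viability channel; skipping gate %r", gate.name
            )
            pr.memberships[gate.name] = pr.memberships[gate.parent].copy()
            continue
        mask = _gate_mask(em, gate) if n else np.zeros(0, dtype=bool)
        pr.memberships[gate.name] = mask & pr.memberships[gate.parent]
    return pr


def _marker_absent(em: EventMatrix, marker: str) -> bool:
    return marker not in em.marker_names and marker not in em.detector_names


def subset_population(
    pr: PopulationResult,
    em: EventMatrix,
    parent: str,
    marker: str,
    threshold: float,
) -> PopulationResult:
    """Partition *parent* at *threshold* into ``<parent>_<marker>+`` (>=) and
    ``<parent>_<marker>-`` (<) subpopulations, added in place and returned.

    Used e.g. to split ASCs into CD19+ and CD19- fractions.
    """
    if parent not in pr.memberships:
        raise GatingError(f"population {parent!r} not gated")
    vals = em.marker_values(marker)  # KeyError if absent
    parent_mask = pr.memberships[parent]
    pos = parent_mask & (vals >= threshold)
    pr.memberships[f"{parent}_{marker}+"] = pos
    pr.memberships[f"{parent}_{marker}-"] = parent_mask & ~pos
    return pr


def gating_report(pr: PopulationResult, gates: list[GateDef]):
    """Tidy per-population table: name, count, fraction of parent."""
    import pandas as pd

    parents = {g.name: g.parent for g in gates}
    rows = []
    counts = pr.counts
    for name, cnt in counts.items():
        parent = parents.get(name)
        parent_cnt = counts.get(parent) if parent else None
        frac = cnt / parent_cnt if parent_cnt else (1.0 if name == "root" else float("nan"))
        rows.append({"population": name, "count": cnt,
                     "parent": parent or "", "fraction_of_parent": frac})
    return pd.DataFrame(rows)
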