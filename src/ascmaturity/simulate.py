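"""Synthetic data generator: a stand-in for the public cytometry corpus.

Two levels of synthesis are provided.

**Cohort level** (:func:`simulate_cohort`): per-sample normalized marker
expressions over a vaccination time course. Each marker follows a smooth
kinetic mean curve mu_k(t) over day post-immune-intervention (DPI) t:

* gamma-pulse ``b + A*(t/tau)*exp(1 - t/tau)`` (single peak at t = tau,
  height b + A) for the markers that transiently rise — CD19, CD45, HLA-DR,
  CD138 and Ki67 (Ki67 with a fast timescale so it decays quickly);
* dip-and-recover ``b - A*(t/tau)*exp(1 - t/tau) + c*t/180`` for CD56,
  which drops in the (very) early response and ends above baseline late;
* flat ``b`` for CD20 and CD28, which do not change during the response.

On top of the mean curve sit a per-dataset batch shift, a per-subject random
effect and residual noise (all Gaussian). Panel differences between datasets
are emulated by marking whole dataset x marker blocks missing; the default
allocation removes 53 of the 23 x 8 dataset-marker slots, i.e. an overall
missing fraction of 28.8%, matching the multi-dataset corpus this generator
emulates. ASC counts are drawn from a shifted negative binomial that
deliberately produces sub-50 values so the inclusion filter has work to do.

**Event level** (:func:`simulate_fcs`): raw cytometry samples as mixtures of
log-normal populations (T cells, B cells, ASCs, debris, doublets, dead
cells) with ground-truth event labels, for exercising gating, MedFI
extraction and normalization end to end.

Ground truth (:class:`SimTruth`) is retained next to every artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .fcs_io import EventMatrix, Platform, write_fcs
from .harmonize import MATURITY_MARKERS

__all__ = [
    "KineticShape",
    "MarkerKinetics",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "kinetic_mean",
    "PopulationSpec",
    "default_sample_spec",
    "simulate_fcs",
    "end_to_end_fixture",
    "DEFAULT_KINETICS",
]


@dataclass(frozen=True)
class MarkerKinetics:
    """Parameters of one marker's mean curve on the normalized scale."""

    shape: str  # pulse | dip_recover | flat | decay
    baseline: float
    amplitude: float = 0.0
    tau: float = 10.0  # days; pulse peak location
    slope: float = 0.0  # late linear recovery (dip_recover only), units per 180 d


#: Default kinetics, calibrated so stage-wise medians reproduce the observed
#: directionality: CD19/CD45/HLA-DR transient increase, CD138 and Ki67 early
#: peak then drop (Ki67 fastest), CD56 early dip with late elevation,
#: CD20/CD28 flat.
DEFAULT_KINETICS: dict[str, MarkerKinetics] = {
    "CD19": MarkerKinetics("pulse", baseline=0.80, amplitude=0.50, tau=18.0),
    "CD20": MarkerKinetics("flat", baseline=0.40),
    "CD28": MarkerKinetics("flat", baseline=0.30),
    "CD45": MarkerKinetics("pulse", baseline=0.60, amplitude=0.55, tau=14.0),
    "CD56": MarkerKinetics("dip_recover", baseline=0.55, amplitude=0.60,
                           tau=8.0, slope=0.40),
    "CD138": MarkerKinetics("pulse", baseline=0.50, amplitude=0.80, tau=8.0),
    "HLA-DR": MarkerKinetics("pulse", baseline=0.50, amplitude=0.70, tau=12.0),
    "Ki67": MarkerKinetics("pulse", baseline=0.25, amplitude=1.40, tau=6.0),
}


def kinetic_mean(k: MarkerKinetics, t) -> np.ndarray:
    """Closed-form mean curve mu_k(t) (vectorized over t, days)."""
    t = np.asarray(t, dtype=float)
    if k.shape == "flat":
        return np.full_like(t, k.baseline)
    pulse = (t / k.tau) * np.exp(1.0 - t / k.tau)
    if k.shape in ("pulse", "decay"):
        return k.baseline + k.amplitude * pulse
    if k.shape == "dip_recover":
        return k.baseline - k.amplitude * pulse + k.slope * t / 180.0
    raise ValueError(f"unknown kinetic shape {k.shape!r}")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_datasets: int = 23
    subjects_per_dataset: int = 10
    sampling_dpis: tuple[float, ...] = (0.0, 7.0, 14.0, 28.0, 90.0, 180.0)
    kinetics: dict[str, MarkerKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS))
    dataset_batch_sd: float = 0.10
    subject_sd: float = 0.15
    residual_sd: float = 0.25
    panel_missingness: dict[str, frozenset[str]] | None = None
    target_overall_missing_fraction: float = 0.287
    age_range: tuple[float, float] = (18.0, 75.0)
    asc_count_shift: int = 10
    asc_count_mean: float = 250.0
    asc_count_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dataset_batch_sd, self.subject_sd, self.residual_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if any(t < 0 or t > 180 for t in self.sampling_dpis):
            raise ValueError("sampling DPIs must lie within [0, 180]")


@dataclass
class SimTruth:
    """Ground truth retained alongside generated artifacts."""

    samples: pd.DataFrame  # sample_id, dpi, latent_maturity, batch shift, ...
    event_labels: np.ndarray | None = None  # FCS mode: per-event population


def _default_panel_map(cfg: SimConfig, rng: np.random.Generator,
                       markers) -> dict[str, frozenset[str]]:
    """Deterministically sized allocation of absent dataset x marker slots.

    Chooses the total number of absent slots so the overall missing fraction
    matches the target exactly at panel granularity; which markers a dataset
    lacks is drawn at random (seeded), never all datasets for one marker.
    """
    d, p = cfg.n_datasets, len(markers)
    total_slots = d * p
    n_absent = int(round(cfg.target_overall_missing_fraction * total_slots))
    base, extra = divmod(n_absent, d)
    counts = np.full(d, base, dtype=int)
    bump = rng.choice(d, size=extra, replace=False)
    counts[bump] += 1
    counts = np.minimum(counts, p - 1)  # every dataset keeps >= 1 marker
    panel: dict[str, frozenset[str]] = {}
    absent_per_marker = np.zeros(p, dtype=int)
    for i in range(d):
        # favour markers least often absent so none disappears corpus-wide
        order = np.argsort(absent_per_marker + rng.random(p))
        chosen = order[: counts[i]]
        absent_per_marker[chosen] += 1
        panel[f"ds{i:02d}"] = frozenset(markers[j] for j in chosen)
    return panel


def simulate_cohort(cfg: SimConfig) -> tuple[CohortTable, SimTruth]:
    """Generate the cohort-level normalized-expression table with truth.

    Latent maturity is, by construction, the time since the immune event
    (DPI itself), so any faithful maturity score must increase with it.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = [m for m in MATURITY_MARKERS if m in cfg.kinetics]
    panel = cfg.panel_missingness
    if panel is None:
        panel = _default_panel_map(cfg, rng, markers)

    rows = []
    truth_rows = []
    for i in range(cfg.n_datasets):
        ds = f"ds{i:02d}"
        batch = rng.normal(0.0, cfg.dataset_batch_sd, size=len(markers))
        absent = panel.get(ds, frozenset())
        for j in range(cfg.subjects_per_dataset):
            subj = f"{ds}_s{j:02d}"
            subj_eff = rng.normal(0.0, cfg.subject_sd, size=len(markers))
            age = float(rng.uniform(*cfg.age_range))
            sex = "F" if rng.random() < 0.5 else "M"
            for t in cfg.sampling_dpis:
                sid = f"{subj}_d{int(t):03d}"
                p_nb = cfg.asc_count_shape / (cfg.asc_count_shape + cfg.asc_count_mean
                                              - cfg.asc_count_shift)
                asc_count = int(cfg.asc_count_shift
                                + rng.negative_binomial(cfg.asc_count_shape, p_nb))
                expr = {}
                for k_idx, mk in enumerate(markers):
                    mu = float(kinetic_mean(cfg.kinetics[mk], t))
                    val = (mu + batch[k_idx] + subj_eff[k_idx]
                           + rng.normal(0.0, cfg.residual_sd))
                    expr[mk] = np.nan if mk in absent else val
                rows.append({
                    "sample_id": sid, "dataset_id": ds, "subject_id": subj,
                    "dpi": float(t), "age": age, "sex": sex, "tissue": "blood",
                    "asc_count": asc_count, **expr,
                })
                truth_rows.append({
                    "sample_id": sid, "dpi": float(t),
                    "latent_maturity": float(t),
                    "dataset_id": ds,
                })
    df = pd.DataFrame(rows)
    truth = SimTruth(samples=pd.DataFrame(truth_rows))
    table = CohortTable(df=df, provenance=[
        f"simulated cohort: {cfg.n_datasets} datasets x "
        f"{cfg.subjects_per_dataset} subjects x {len(cfg.sampling_dpis)} DPIs, "
        f"seed={cfg.seed}"],
        markers=tuple(markers))
    return table, truth


# ---------------------------------------------------------------------------
# Event-level simulation


@dataclass
class PopulationSpec:
    """One cell population: size and per-channel log-normal parameters.

    ``channels`` maps channel name -> (meanlog, sdlog); scatter channels
    (FSC-A, FSC-H, SSC-A) are Gaussian with mean/sd given directly under the
    keys ``FSC_mean/FSC_sd/...`` handled by :func:`simulate_fcs`.
    """

    name: str
    n: int
    channels: dict[str, tuple[float, float]]
    scatter_mean: float = 1.0e5
    scatter_sd: float = 1.5e4
    doublet: bool = False
    debris: bool = False


_LO, _HI = 4.0, 7.0  # meanlog of negative / positive log-normal components
_SDLOG = 0.4


def default_sample_spec(
    n_t: int = 2000,
    n_b: int = 1500,
    n_asc: int = 500,
    n_debris: int = 500,
    n_doublets: int = 300,
    n_dead: int = 300,
    asc_marker_meanlogs: dict[str, float] | None = None,
    platform: Platform | str = Platform.flow,
) -> list[PopulationSpec]:
    """Default six-population sample with >= 5-SD (log-space) separation
    between negative and positive components of every gating marker."""
    platform = Platform(platform)
    asc_extra = asc_marker_meanlogs or {}

    def chans(cd3, cd19, cd27, cd38, viab, extras=None) -> dict:
        base = {
            "CD3": (cd3, _SDLOG), "CD19": (cd19, _SDLOG),
            "CD27": (cd27, _SDLOG), "CD38": (cd38, _SDLOG),
            "viability": (viab, _SDLOG),
        }
        for mk in MATURITY_MARKERS:
            if mk in ("CD19",):
                continue
            base.setdefault(mk, (_LO, _SDLOG))
        if platform is Platform.mass:
            base["DNA1"] = (7.0, 0.2)
            base["DNA2"] = (7.0, 0.2)
        if extras:
            base.update(extras)
        return base

    asc_chan = chans(_LO, 6.5, _HI, _HI, _LO,
                     {mk: (ml, _SDLOG) for mk, ml in asc_extra.items()})
    specs = [
        PopulationSpec("Tcell", n_t, chans(_HI, _LO, 5.0, _LO, _LO,
                                           {"CD45": (_HI, _SDLOG)})),
        PopulationSpec("Bcell", n_b, chans(_LO, _HI, _LO, _LO, _LO,
                                           {"CD20": (_HI, _SDLOG),
                                            "CD45": (_HI, _SDLOG),
                                            "HLA-DR": (_HI, _SDLOG)})),
        PopulationSpec("ASC", n_asc, asc_chan),
        PopulationSpec("dead", n_dead, chans(5.0, 5.0, 5.0, 5.0, _HI)),
    ]
    if platform is Platform.flow:
        specs.append(PopulationSpec("debris", n_debris, chans(_LO, _LO, _LO, _LO, _LO),
                                    scatter_mean=1.0e4, scatter_sd=3.0e3, debris=True))
        specs.append(PopulationSpec("doublet", n_doublets,
                                    chans(_HI, _LO, 5.0, _LO, _LO),
                                    doublet=True))
    else:
        # mass cytometry: debris/doublets show aberrant DNA intercalator signal
        specs.append(PopulationSpec("debris", n_debris,
                                    chans(_LO, _LO, _LO, _LO, _LO,
                                          {"DNA1": (3.0, 0.3), "DNA2": (3.0, 0.3)}),
                                    debris=True))
        specs.append(PopulationSpec("doublet", n_doublets,
                                    chans(_HI, _LO, 5.0, _LO, _LO,
                                          {"DNA1": (9.7, 0.2), "DNA2": (9.7, 0.2)}),
                                    doublet=True))
    return specs


def simulate_fcs(
    specs: list[PopulationSpec],
    platform: Platform | str = Platform.flow,
    seed: int = 0,
) -> tuple[EventMatrix, SimTruth]:
    """Draw labeled events from the per-population log-normal mixtures."""
    platform = Platform(platform)
    rng = np.random.default_rng(seed)
    channel_names: list[str] = []
    for spec in specs:
        for ch in spec.channels:
            if ch not in channel_names:
                channel_names.append(ch)
    if platform is Platform.flow:
        channel_names = ["FSC-A", "FSC-H", "SSC-A"] + channel_names

    blocks = []
    labels = []
    for spec in specs:
        n = int(spec.n)
        if n < 0:
            raise ValueError("population sizes must be >= 0")
        block = np.zeros((n, len(channel_names)))
        for ci, ch in enumerate(channel_names):
            if ch in ("FSC-A", "FSC-H", "SSC-A"):
                continue
            if ch in spec.channels:
                meanlog, sdlog = spec.channels[ch]
                block[:, ci] = rng.lognormal(meanlog, sdlog, size=n)
            else:
                block[:, ci] = rng.lognormal(_LO, _SDLOG, size=n)
        if platform is Platform.flow:
            fsc = np.clip(rng.normal(spec.scatter_mean, spec.scatter_sd, size=n),
                          1.0, None)
            ssc = np.clip(rng.normal(0.4 * spec.scatter_mean, spec.scatter_sd, size=n),
                          1.0, None)
            if spec.doublet:
                fsc_h = fsc / 2.0  # doublets: area ~ 2x height
            else:
                fsc_h = fsc * rng.normal(1.0, 0.03, size=n)
            block[:, 0] = fsc
            block[:, 1] = np.clip(fsc_h, 1.0, None)
            block[:, 2] = ssc
        blocks.append(block)
        labels.extend([spec.name] * n)
    events = np.vstack(blocks) if blocks else np.zeros((0, len(channel_names)))
    labels = np.array(labels)
    order = rng.permutation(len(labels))
    em = EventMatrix(
        events=events[order],
        detector_names=list(channel_names),
        marker_names=list(channel_names),
        platform=platform,
    )
    return em, SimTruth(samples=pd.DataFrame(), event_labels=labels[order])


def end_to_end_fixture(
    out_dir,
    seed: int = 0,
    n_datasets: int = 6,
    subjects_per_dataset: int = 4,
    sampling_dpis: tuple[float, ...] = (0.0, 7.0, 14.0, 28.0, 90.0),
    events_per_sample: int = 3000,
):
    """Write a miniature multi-dataset study: one FCS file per sample plus
    ``metadata.csv`` and ``truth.csv``, exercising every pipeline stage.

    ASC marker intensities encode the kinetic mean curves, so gating +
    normalization downstream recover expressions that track DPI.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    meta_rows = []
    truth_rows = []
    scale = events_per_sample / 5100  # default spec totals 5100 events
    for i in range(n_datasets):
        ds = f"fx{i}"
        platform = Platform.flow if i % 2 == 0 else Platform.mass
        for j in range(subjects_per_dataset):
            subj = f"{ds}_s{j}"
            age = float(rng.uniform(20, 70))
            sex = "F" if rng.random() < 0.5 else "M"
            for t in sampling_dpis:
                sid = f"{subj}_d{int(t):03d}"
                meanlogs = {}
                for mk, kin in DEFAULT_KINETICS.items():
                    mu = float(kinetic_mean(kin, t))
                    # map normalized value mu onto the log-intensity axis
                    # between the negative (4.0) and positive (7.0) anchors
                    meanlogs[mk] = _LO + mu * (_HI - _LO)
                specs = default_sample_spec(
                    n_t=int(2000 * scale), n_b=int(1500 * scale),
                    n_asc=int(500 * scale), n_debris=int(500 * scale),
                    n_doublets=int(300 * scale), n_dead=int(300 * scale),
                    asc_marker_meanlogs=meanlogs, platform=platform,
                )
                em, _tr = simulate_fcs(specs, platform=platform,
                                       seed=int(rng.integers(2**31 - 1)))
                path = os.path.join(out_dir, f"{sid}.fcs")
                write_fcs(em, path)
                meta_rows.append({
                    "sample_id": sid, "dataset_id": ds, "subject_id": subj,
                    "dpi": float(t), "age": age, "sex": sex, "tissue": "blood",
                    "platform": platform.value, "fcs_file": f"{sid}.fcs",
                })
                truth_rows.append({"sample_id": sid, "dpi": float(t),
                                   "latent_maturity": float(t)})
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    meta.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
    return meta, truth
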