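"""Synthetic data with the statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_roi` draws a marked point pattern (tumor / immune / other
  cell centroids) inside a circular 300-um region of interest, in one of
  three topologies — *diffuse* (immune cells interspersed uniformly among
  tumor cells), *focal* (immune cells in compact Thomas-style niches that
  displace tumor cells), and *insignificant* (immune cells effectively
  absent).

* :func:`simulate_counts` draws a digital-spatial-profiling style protein
  count matrix over areas of illumination (AOIs): log-normal counts with a
  per-marker baseline, group fixed effects, patient random intercepts, a
  cell-number size factor, housekeeper counts proportional to nuclei count,
  isotype-control background rising with nuclei count, and an optional
  per-AOI lane factor shared with the hybridization controls.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graphstats import TUMOR, IMMUNE, OTHER
from .dsp import AOIMatrix, MarkerRoles

DEFAULT_TARGETS = [
    "PD-L1", "PD-1", "IDO1", "Tim-3", "CD3", "CD8", "CD4", "CD45",
    "CD163", "CD68", "FOXP3", "CTLA-4", "CD25", "Fibronectin", "GZMB",
    "B2M", "STING", "CD44", "Ki67", "PanCk",
]
DEFAULT_HOUSEKEEPERS = ["GAPDH", "S6", "Histone H3"]
DEFAULT_ISOTYPES = ["msIgG1", "msIgG2a", "rbIgG"]
DEFAULT_HYB_CONTROLS = ["HybPos1", "HybPos2", "HybPos3"]

PATTERNS = ("diffuse", "focal", "insignificant")


@dataclass
class ROISimConfig:
    """Marked point-pattern simulation inside a circular ROI.

    Lengths are microns; the emitted CellTable is in pixels at
    ``pixel_size_um`` per pixel (0.4 um/px reproduces the 30 px = 12 um
    equivalence of 20x DSP scans).  ``tumor_exclusion_factor`` sets, in
    units of ``cluster_sd_um``, the radius around each focal immune-niche
    center from which tumor cells are displaced; it is what makes focal
    niches read as immune aggregates *within* the tumor rather than an
    overlay on it.
    """

    n_tumor: int = 250
    n_immune: int = 80
    pattern: str = "diffuse"
    roi_diameter_um: float = 300.0
    pixel_size_um: float = 0.4
    n_immune_clusters: int = 3
    cluster_sd_um: float = 20.0
    tumor_exclusion_factor: float = 2.5
    n_other: int = 0
    insignificance_cutoff: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.roi_diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("ROI diameter and pixel size must be positive")
        if min(self.n_tumor, self.n_immune, self.n_other) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n_tumor + self.n_immune + self.n_other == 0:
            raise ValueError("at least one cell is required")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.pattern == "focal":
            if self.n_immune_clusters < 1:
                raise ValueError("focal pattern needs n_immune_clusters >= 1")
            if self.cluster_sd_um <= 0:
                raise ValueError("focal pattern needs cluster_sd_um > 0")


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _max_insignificant_immune(n_tumor: int, cutoff: float) -> int:
    # largest k with k / (n_tumor + k) < cutoff
    k = int(np.floor(cutoff * n_tumor / (1.0 - cutoff)))
    while k > 0 and k / (n_tumor + k) >= cutoff:
        k -= 1
    return max(k, 0)


def simulate_roi(config: ROISimConfig, roi_id: str = "ROI001") -> pd.DataFrame:
    """Simulate one classified CellTable (roi_id, cell_id, x_px, y_px, cls).

    diffuse
        tumor and immune positions independent and uniform over the disc;
    focal
        immune cells drawn from ``n_immune_clusters`` Gaussian niches
        (parent centers uniform in the disc, offsets SD ``cluster_sd_um``,
        truncated to the disc); tumor cells uniform over the disc minus an
        exclusion disc of radius ``tumor_exclusion_factor * cluster_sd_um``
        around each niche center, emulating immune aggregates displacing
        tumor;
    insignificant
        diffuse placement with the immune count capped so the immune cell
        ratio stays below ``insignificance_cutoff``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    radius_um = config.roi_diameter_um / 2.0
    n_immune = config.n_immune
    if config.pattern == "insignificant":
        n_immune = min(
            n_immune,
            _max_insignificant_immune(config.n_tumor, config.insignificance_cutoff),
        )

    if config.pattern == "focal" and n_immune > 0:
        centers = _uniform_disc(rng, config.n_immune_clusters, radius_um)
        assign = rng.integers(0, config.n_immune_clusters, n_immune)
        immune = np.empty((n_immune, 2))
        todo = np.arange(n_immune)
        while todo.size:
            pts = centers[assign[todo]] + rng.normal(
                scale=config.cluster_sd_um, size=(todo.size, 2)
            )
            ok = np.hypot(pts[:, 0], pts[:, 1]) <= radius_um
            immune[todo[ok]] = pts[ok]
            todo = todo[~ok]
        excl = config.tumor_exclusion_factor * config.cluster_sd_um
        tumor = np.empty((config.n_tumor, 2))
        filled = 0
        for _ in range(10_000):
            if filled >= config.n_tumor:
                break
            cand = _uniform_disc(rng, max(config.n_tumor - filled, 64), radius_um)
            d = np.hypot(
                cand[:, None, 0] - centers[None, :, 0],
                cand[:, None, 1] - centers[None, :, 1],
            )
            cand = cand[(d > excl).all(axis=1)]
            take = min(len(cand), config.n_tumor - filled)
            tumor[filled:filled + take] = cand[:take]
            filled += take
        else:
            raise ValueError(
                "tumor exclusion zones cover the ROI; reduce "
                "tumor_exclusion_factor or cluster_sd_um"
            )
    else:
        tumor = _uniform_disc(rng, config.n_tumor, radius_um)
        immune = _uniform_disc(rng, n_immune, radius_um)

    other = _uniform_disc(rng, config.n_other, radius_um)
    xy_um = np.vstack([tumor, immune, other])
    cls = ([TUMOR] * config.n_tumor + [IMMUNE] * n_immune + [OTHER] * config.n_other)
    # pixel frame with the ROI center at (R, R) so coordinates are positive
    radius_px = radius_um / config.pixel_size_um
    xy_px = xy_um / config.pixel_size_um + radius_px
    return pd.DataFrame(
        {
            "roi_id": roi_id,
            "cell_id": [f"c{k:05d}" for k in range(len(cls))],
            "x_px": xy_px[:, 0],
            "y_px": xy_px[:, 1],
            "cls": cls,
        }
    )


def simulate_cohort_rois(
    pattern_counts: dict[str, int],
    base_config: ROISimConfig | None = None,
    seed: int = 0,
    rois_per_patient: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of ROIs with known topology labels.

    Patients receive ``rois_per_patient`` ROIs sharing one generative
    pattern (a patient's tumor has one dominant topology).  Returns the
    stacked CellTable and a truth table (roi_id, patient_id, pattern).
    """
    base = base_config or ROISimConfig()
    tables, truth = [], []
    roi_k = 0
    pat_k = 0
    for pattern in sorted(pattern_counts):
        n_rois = pattern_counts[pattern]
        for j in range(n_rois):
            if j % rois_per_patient == 0:
                pat_k += 1
            cfg_kwargs = asdict(base)
            cfg_kwargs.update(pattern=pattern, seed=seed + roi_k)
            if pattern == "insignificant":
                cfg_kwargs["n_immune"] = min(base.n_immune, 5)
            cfg = ROISimConfig(**cfg_kwargs)
            roi_id = f"R{roi_k:04d}"
            tables.append(simulate_roi(cfg, roi_id=roi_id))
            truth.append(
                {"roi_id": roi_id, "patient_id": f"P{pat_k:03d}", "pattern": pattern}
            )
            roi_k += 1
    return pd.concat(tables, ignore_index=True), pd.DataFrame(truth)


@dataclass
class DSPSimConfig:
    """Log-normal DSP protein count simulation over an AOI design table."""

    markers: list[str] = field(default_factory=lambda: list(DEFAULT_TARGETS))
    housekeepers: list[str] = field(default_factory=lambda: list(DEFAULT_HOUSEKEEPERS))
    isotypes: list[str] = field(default_factory=lambda: list(DEFAULT_ISOTYPES))
    hyb_controls: list[str] = field(default_factory=lambda: list(DEFAULT_HYB_CONTROLS))
    fixed_effects: dict = field(default_factory=dict)  # group -> {marker: beta}
    patient_sd: float = 0.5
    noise_sd: float = 0.2
    background_slope: float = 1.0
    lane_sd: float = 0.0
    baseline_log: float = 5.0
    hk_baseline_log: float = 6.0
    iso_baseline_log: float = 3.5
    hyb_baseline_log: float = 7.0
    hyb_noise_sd: float = 0.05
    nuclei_ref: float = 200.0
    marker_noise_sd: dict = field(default_factory=dict)  # per-marker override
    seed: int = 0

    def validate(self) -> None:
        if min(self.patient_sd, self.noise_sd, self.lane_sd, self.hyb_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not self.housekeepers:
            raise ValueError("at least one housekeeper marker is required")
        if not self.isotypes:
            raise ValueError("at least one isotype control is required")

    @property
    def all_markers(self) -> list[str]:
        return (
            list(self.markers)
            + list(self.housekeepers)
            + list(self.isotypes)
            + list(self.hyb_controls)
        )


def make_design(
    n_patients: int,
    rois_per_patient: tuple[int, int] = (1, 3),
    segments: tuple[str, ...] = ("tumor", "immune"),
    nuclei_mean: float = 200.0,
    nuclei_log_sd: float = 0.5,
    seed: int = 0,
    group_col: str | None = None,
    group_levels: tuple[str, ...] = ("A", "B"),
) -> pd.DataFrame:
    """Build an AOI design table (one row per AOI) for simulate_counts.

    Each patient gets 1-3 ROIs; each ROI contributes one AOI per segment
    type.  Nuclei counts are log-normal around ``nuclei_mean``.  If
    ``group_col`` is given, a per-patient group label is assigned
    alternately so group sizes are balanced.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        n_rois = int(rng.integers(rois_per_patient[0], rois_per_patient[1] + 1))
        for r in range(n_rois):
            rid = f"{pid}-R{r}"
            for seg in segments:
                nuc = float(np.round(
                    nuclei_mean * np.exp(rng.normal(scale=nuclei_log_sd))
                ))
                rows.append(
                    {
                        "aoi_id": f"{rid}-{seg}",
                        "roi_id": rid,
                        "patient_id": pid,
                        "segment": seg,
                        "nuclei_count": max(nuc, 1.0),
                        "area": max(nuc, 1.0) * 110.0,  # ~ cell footprint um^2
                        "slide_id": "TMA1" if p % 2 == 0 else "TMA2",
                    }
                )
    design = pd.DataFrame(rows)
    if group_col is not None:
        per_patient = {
            pid: group_levels[i % len(group_levels)]
            for i, pid in enumerate(design["patient_id"].unique())
        }
        design[group_col] = design["patient_id"].map(per_patient)
    return design


def simulate_counts(
    config: DSPSimConfig,
    design: pd.DataFrame,
    group_col: str = "segment",
) -> AOIMatrix:
    """Simulate an AOI x marker count matrix over a design table.

    Natural-log counts per AOI *a* and target marker *m*:

        log y_am = baseline + beta[group_a, m] + b_pat(a) + s_a + lane_a + e

    with size factor ``s_a = log(nuclei_a / nuclei_ref)`` so signal scales
    with cell content.  Housekeepers follow baseline + s_a + lane_a + e
    (proportional to nuclei count, no biology); isotype controls follow
    baseline + background_slope * s_a + lane_a + e (background rising with
    nuclei count); hybridization controls carry only the lane factor and
    their own small noise.  Patient intercepts b ~ N(0, patient_sd^2) apply
    to target markers only, so they survive housekeeper normalization.
    """
    config.validate()
    required = {"aoi_id", "patient_id", "segment", "nuclei_count"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    groups = design[group_col].astype(str)
    unknown = set(config.fixed_effects) - set(groups.unique())
    if unknown:
        raise ValueError(
            f"fixed_effects reference groups absent from the design: {sorted(unknown)}"
        )

    rng = np.random.default_rng(config.seed)
    n = len(design)
    patients = design["patient_id"].to_numpy()
    unique_patients = pd.unique(patients)
    b_pat = dict(
        zip(unique_patients, rng.normal(scale=config.patient_sd, size=len(unique_patients)))
    )
    size = np.log(design["nuclei_count"].to_numpy(dtype=float) / config.nuclei_ref)
    lane = rng.normal(scale=config.lane_sd, size=n) if config.lane_sd > 0 else np.zeros(n)

    def noise(marker, default_sd):
        sd = config.marker_noise_sd.get(marker, default_sd)
        return rng.normal(scale=sd, size=n) if sd > 0 else np.zeros(n)

    cols = {}
    pat_eff = np.array([b_pat[p] for p in patients])
    for m in config.markers:
        beta = groups.map(
            lambda g: config.fixed_effects.get(g, {}).get(m, 0.0)
        ).to_numpy(dtype=float)
        cols[m] = np.exp(
            config.baseline_log + beta + pat_eff + size + lane + noise(m, config.noise_sd)
        )
    for h in config.housekeepers:
        cols[h] = np.exp(
            config.hk_baseline_log + size + lane + noise(h, config.noise_sd)
        )
    for iso in config.isotypes:
        cols[iso] = np.exp(
            config.iso_baseline_log
            + config.background_slope * size
            + lane
            + noise(iso, config.noise_sd)
        )
    for hc in config.hyb_controls:
        cols[hc] = np.exp(config.hyb_baseline_log + lane + noise(hc, config.hyb_noise_sd))

    counts = pd.DataFrame(cols, index=design["aoi_id"].to_numpy())
    counts.index.name = "aoi_id"
    meta = design.set_index("aoi_id")
    roles = MarkerRoles(
        housekeepers=list(config.housekeepers),
        isotypes=list(config.isotypes),
        hyb_controls=list(config.hyb_controls),
    )
    return AOIMatrix(counts=counts, meta=meta, roles=roles)


def simulate_clinical(
    n_patients: int | None = None,
    seed: int = 0,
    consensus_labels: pd.Series | None = None,
    label_hazard: dict[str, float] | None = None,
    censor_years: float = 15.0,
    patient_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a per-patient clinical annotation table.

    Histotype frequencies loosely follow an ovarian-carcinoma cohort
    (HGSC-dominated); Type 2 = HGSC, Type 1 = other malignant histotypes,
    benign/borderline get no type and are excluded from malignant-only
    analyses downstream.  PFS and OS are exponential with an optional
    per-topology hazard multiplier (``label_hazard``), censored
    administratively at ``censor_years``.

    Patient ids come from ``patient_ids``, else from the index of
    ``consensus_labels``, else are generated as P000..P{n-1}.
    """
    if patient_ids is None and consensus_labels is not None:
        patient_ids = list(consensus_labels.index)
    if patient_ids is not None:
        n_patients = len(patient_ids)
    if n_patients is None:
        raise ValueError("give n_patients, patient_ids or consensus_labels")
    rng = np.random.default_rng(seed)
    histotypes = np.array(
        ["HGSC", "LGSC", "endometrioid", "mucinous", "clear cell", "benign/borderline"]
    )
    probs = np.array([0.40, 0.09, 0.18, 0.09, 0.08, 0.16])
    hist = rng.choice(histotypes, size=n_patients, p=probs)
    oc_type = np.where(
        hist == "HGSC", "2", np.where(hist == "benign/borderline", "NA", "1")
    )
    stage = np.where(
        hist == "benign/borderline",
        "NA",
        rng.choice(["I", "II", "III", "IV"], size=n_patients, p=[0.25, 0.1, 0.45, 0.2]),
    )
    pids = patient_ids or [f"P{p:03d}" for p in range(n_patients)]
    base_hazard = 1.0 / 8.0  # mean PFS ~ 8 years, as in a mixed OC cohort
    hz = np.full(n_patients, base_hazard)
    labels = None
    if consensus_labels is not None:
        labels = consensus_labels.reindex(pids)
        if label_hazard:
            hz = hz * labels.map(lambda v: label_hazard.get(v, 1.0)).fillna(1.0).to_numpy()
    pfs = rng.exponential(1.0 / hz)
    os_ = pfs + rng.exponential(2.0, size=n_patients)
    clin = pd.DataFrame(
        {
            "patient_id": pids,
            "histotype": hist,
            "oc_type": oc_type,
            "stage": stage,
            "pfs_years": np.minimum(pfs, censor_years),
            "pfs_event": (pfs <= censor_years).astype(int),
            "os_years": np.minimum(os_, censor_years),
            "os_event": (os_ <= censor_years).astype(int),
        }
    )
    if labels is not None:
        clin["consensus_label"] = labels.to_numpy()
    return clin
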