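"""Config-driven end-to-end orchestration of the topology pipeline.

:func:`run_pipeline` binds the stages together: simulate (or ingest) cell
tables -> spatial features per distance threshold -> topology classification
and per-patient consensus -> DSP count normalization -> differential
expression -> survival.  Every output table carries the config hash; a
machine-readable run log records versions, seeds, thresholds and QC
exclusions.  Reruns with the same config produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as tio
from .classify import (
    DIFFUSE,
    FOCAL,
    INSIGNIFICANT,
    TopologyRule,
    calibrate_rule,
    classify_table,
    consensus_label,
)
from .dsp import normalize_pipeline
from .graphstats import compute_feature_table
from .stats import coxme_screen, km_compare, lmm_differential, volcano_table
from .synthetic import (
    DSPSimConfig,
    ROISimConfig,
    simulate_clinical,
    simulate_cohort_rois,
    simulate_counts,
)


@dataclass
class SimulationPlan:
    """How many ROIs of each generative topology to simulate, and the DSP effects."""

    n_diffuse: int = 16
    n_focal: int = 16
    n_insignificant: int = 8
    rois_per_patient: int = 2
    roi: ROISimConfig = field(default_factory=ROISimConfig)
    # log-scale marker effects per generative pattern, used as DSP fixed effects
    fixed_effects: dict = field(
        default_factory=lambda: {
            "diffuse": {"PD-L1": 0.8, "IDO1": 0.8, "GZMB": 0.6},
            "focal": {"CD163": 0.8},
            "insignificant": {"CD25": 0.6, "Fibronectin": 0.6},
        }
    )
    focal_hazard: float = 1.6  # PFS hazard multiplier for focal-consensus patients


@dataclass
class PipelineConfig:
    output_dir: str = "results/pipeline"
    seed: int = 0
    pixel_size_um: float = 0.4
    thresholds_px: tuple = (30.0, 50.0)
    n_perm: int = 500
    min_nuclei: float = 20
    max_norm_factor: float = 3.0
    housekeepers: tuple = ("GAPDH", "S6")
    rule: TopologyRule = field(default_factory=TopologyRule)
    n_calibration_rois: int = 20  # per pattern, for threshold calibration
    run_diffexp: bool = True
    run_survival: bool = True
    # optional on-disk inputs; when None the simulation plan supplies them
    cell_table_path: str | None = None
    counts_path: str | None = None
    meta_path: str | None = None
    clinical_path: str | None = None
    simulate: SimulationPlan | None = field(default_factory=SimulationPlan)

    def validate(self) -> None:
        if not all(t > 0 for t in self.thresholds_px):
            raise ValueError("thresholds must be positive")
        if self.rule.threshold_px not in tuple(self.thresholds_px):
            raise ValueError("rule.threshold_px must be one of thresholds_px")
        for attr in ("cell_table_path", "counts_path", "meta_path", "clinical_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if self.cell_table_path is None and self.simulate is None:
            raise ValueError("no cell table input and simulation disabled")
        if self.run_diffexp and self.counts_path is None and self.simulate is None:
            raise ValueError("diffexp requested but no count matrix source")
        if self.run_survival and self.clinical_path is None and self.simulate is None:
            raise ValueError("survival requested but no clinical table source")


def config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis configuration (output location excluded)."""
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _calibrated_rule(config: PipelineConfig) -> TopologyRule:
    """Use configured thresholds, or calibrate them on an independent simulation."""
    rule = config.rule
    if rule.gdc_threshold is not None and rule.ccr_tt_threshold is not None:
        return rule
    n = config.n_calibration_rois
    cells, truth = simulate_cohort_rois(
        {DIFFUSE: n, FOCAL: n},
        base_config=config.simulate.roi if config.simulate else ROISimConfig(),
        seed=config.seed + 90_000,
    )
    feats = compute_feature_table(
        cells, (rule.threshold_px,), n_perm=config.n_perm, seed=config.seed + 91_000
    ).merge(truth, on="roi_id")
    return calibrate_rule(feats, feats["pattern"], rule)


def _build_design(truth: pd.DataFrame, features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One tumor AOI per ROI, plus an immune AOI where immune content allows."""
    import numpy as np

    rng = np.random.default_rng(seed)
    feats30 = features.drop_duplicates("roi_id").set_index("roi_id")
    rows = []
    for rec in truth.itertuples():
        f = feats30.loc[rec.roi_id]
        segments = ["tumor"]
        if f["n_immune"] >= 20:
            segments.append("immune")
        for seg in segments:
            n_cells = f["n_tumor"] if seg == "tumor" else f["n_immune"]
            nuc = float(max(np.round(n_cells * rng.uniform(0.8, 1.0)), 1))
            rows.append(
                {
                    "aoi_id": f"{rec.roi_id}-{seg}",
                    "roi_id": rec.roi_id,
                    "patient_id": rec.patient_id,
                    "segment": seg,
                    "nuclei_count": nuc,
                    "area": nuc * 110.0,
                    "slide_id": "TMA1",
                    "pattern": rec.pattern,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns a dict of the main outputs.

    Validation happens before any output is written; any stage failure
    aborts with the stage name in the exception message.
    """
    config.validate()
    chash = config_hash(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "thresholds_px": list(config.thresholds_px),
        "stages": [],
    }
    results: dict = {}

    def stage(name):
        log["stages"].append(name)

    try:
        stage("cells")
        if config.cell_table_path:
            cells = tio.read_cell_table(config.cell_table_path)
            truth = None
        else:
            plan = config.simulate
            cells, truth = simulate_cohort_rois(
                {
                    DIFFUSE: plan.n_diffuse,
                    FOCAL: plan.n_focal,
                    INSIGNIFICANT: plan.n_insignificant,
                },
                base_config=plan.roi,
                seed=config.seed,
                rois_per_patient=plan.rois_per_patient,
            )
            tio.write_table(truth, out / "roi_truth.tsv", chash)
        tio.write_cell_table(cells, out / "cells.tsv", chash)

        stage("features")
        features = compute_feature_table(
            cells, tuple(config.thresholds_px), n_perm=config.n_perm,
            seed=config.seed + 1_000,
        )
        tio.write_table(features, out / "roi_features.tsv", chash)

        stage("classify")
        rule = _calibrated_rule(config)
        tio.write_yaml(rule, out / "topology_rule.yaml")
        labeled = classify_table(features, rule)
        if truth is not None:
            labeled = labeled.merge(truth, on="roi_id")
        else:
            labeled["patient_id"] = labeled["roi_id"]
        tio.write_table(labeled, out / "roi_labels.tsv", chash)
        consensus = consensus_label(labeled).reset_index()
        tio.write_table(consensus, out / "patient_consensus.tsv", chash)
        results.update(features=features, labels=labeled, consensus=consensus,
                       rule=rule)

        if config.run_diffexp:
            stage("normalize")
            if config.counts_path:
                matrix = tio.read_aoi_matrix(config.counts_path, config.meta_path)
            else:
                design = _build_design(truth, features, config.seed + 2_000)
                dsp_cfg = DSPSimConfig(
                    fixed_effects=config.simulate.fixed_effects,
                    seed=config.seed + 3_000,
                )
                matrix = simulate_counts(dsp_cfg, design, group_col="pattern")
                tio.write_aoi_matrix(
                    matrix, out / "counts_raw.tsv", out / "aoi_meta.tsv", chash
                )
            tumor, immune = normalize_pipeline(
                matrix, config.min_nuclei, config.max_norm_factor,
                tuple(config.housekeepers),
            )
            tio.write_table(
                pd.concat([tumor.qc_log, immune.qc_log]).drop_duplicates(),
                out / "qc_log.tsv", chash,
            )
            tio.write_aoi_matrix(
                tumor, out / "counts_tumor_norm.tsv", out / "meta_tumor.tsv", chash
            )
            tio.write_aoi_matrix(
                immune, out / "counts_immune_norm.tsv", out / "meta_immune.tsv", chash
            )

            stage("diffexp")
            roi_to_label = labeled.drop_duplicates("roi_id").set_index("roi_id")["label"]
            for name, part in (("tumor", tumor), ("immune", immune)):
                lab = part.meta["roi_id"].map(roi_to_label)
                keep = lab.isin([DIFFUSE, FOCAL]).to_numpy()
                if keep.sum() < 4 or lab[keep].nunique() < 2:
                    continue
                targets = part.roles.targets(part.counts.columns)
                res = lmm_differential(
                    part.counts.loc[keep, targets],
                    lab[keep],
                    part.meta.loc[keep, "patient_id"],
                )
                tio.write_table(res, out / f"diffexp_{name}_diffuse_vs_focal.tsv", chash)
                tio.write_table(
                    volcano_table(res), out / f"volcano_{name}.tsv", chash
                )
                results[f"diffexp_{name}"] = res

        if config.run_survival:
            stage("survival")
            if config.clinical_path:
                clinical = tio.read_table(config.clinical_path)
            else:
                cons = consensus.set_index("patient_id")["consensus_label"]
                clinical = simulate_clinical(
                    n_patients=len(cons),
                    seed=config.seed + 4_000,
                    consensus_labels=cons,
                    label_hazard={FOCAL: config.simulate.focal_hazard},
                )
            tio.write_table(clinical, out / "clinical.tsv", chash)
            if "consensus_label" in clinical.columns:
                infiltrated = clinical[
                    clinical["consensus_label"].isin([DIFFUSE, FOCAL])
                ]
                if infiltrated["consensus_label"].nunique() == 2 and (
                    infiltrated["pfs_event"].sum() > 0
                ):
                    km = km_compare(infiltrated, groups=(DIFFUSE, FOCAL))
                    tio.write_table(
                        pd.DataFrame(
                            [{"comparison": "diffuse_vs_focal",
                              "logrank_p": km["p_value"]}]
                        ),
                        out / "km_diffuse_vs_focal.tsv", chash,
                    )
                    results["km_p"] = km["p_value"]
            results["clinical"] = clinical

        tio.write_yaml(config, out / "pipeline_config.yaml")
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        return results
    except Exception as err:
        current = log["stages"][-1] if log["stages"] else "validate"
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err
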