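"""QC and normalization of AOI-level digital spatial profiling protein counts.

The processing order mirrors standard DSP protein practice:

1. :func:`hyb_normalize` — scale each AOI by its hybridization-control
   factor (per-AOI geometric mean of the positive hybridization controls,
   re-centered at the cohort geometric mean) to remove lane effects;
2. :func:`qc_filter` — drop AOIs with low nuclei count (< 20) or a high
   hybridization normalization factor (> 3, indicating low probe binding);
3. :func:`split_by_segment` — separate tumor and immune AOIs so segment
   size differences do not bias scaling;
4. :func:`housekeeper_normalize` — scale each AOI by the geometric mean of
   its housekeeper proteins (GAPDH and S6 by default), removing cell-content
   driven signal, including the isotype-background vs nuclei correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_MIN_NUCLEI = 20
DEFAULT_MAX_NORM_FACTOR = 3.0
DEFAULT_HOUSEKEEPER_PAIR = ("GAPDH", "S6")


@dataclass
class MarkerRoles:
    """Which matrix columns are controls rather than biological targets."""

    housekeepers: list[str] = field(default_factory=list)
    isotypes: list[str] = field(default_factory=list)
    hyb_controls: list[str] = field(default_factory=list)

    def targets(self, columns) -> list[str]:
        ctrl = set(self.housekeepers) | set(self.isotypes) | set(self.hyb_controls)
        return [c for c in columns if c not in ctrl]


@dataclass
class AOIMatrix:
    """AOI x marker count matrix with per-AOI metadata and QC state.

    ``counts`` is indexed by aoi_id with one column per marker; ``meta``
    shares the index and carries roi_id, patient_id, segment, nuclei_count,
    area and slide_id; ``qc_log`` accumulates one row per excluded/flagged
    AOI with the reason.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    roles: MarkerRoles = field(default_factory=MarkerRoles)
    qc_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["aoi_id", "reason"])
    )

    def __post_init__(self):
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.reindex(self.counts.index)
            if self.meta.isna().all(axis=1).any():
                raise ValueError("counts and meta must cover the same AOIs")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def aoi_ids(self) -> pd.Index:
        return self.counts.index

    def subset(self, mask) -> "AOIMatrix":
        return replace(
            self, counts=self.counts.loc[mask].copy(), meta=self.meta.loc[mask].copy()
        )

    def log_flags(self, aoi_ids, reason: str) -> "AOIMatrix":
        add = pd.DataFrame({"aoi_id": list(aoi_ids), "reason": reason})
        return replace(self, qc_log=pd.concat([self.qc_log, add], ignore_index=True))


def _geomean(frame: pd.DataFrame) -> pd.Series:
    return np.exp(np.log(frame).mean(axis=1))


def hyb_normalize(matrix: AOIMatrix) -> AOIMatrix:
    """Scale each AOI by its positive hybridization-control factor.

    The factor is the AOI's geometric mean over hybridization controls,
    divided by the cohort geometric mean of those per-AOI values, so counts
    stay on their original scale.  The factor is stored in
    ``meta["hyb_norm_factor"]``; AOIs with a non-positive control count are
    flagged and keep factor NA (counts untouched).
    """
    hyb = matrix.roles.hyb_controls
    if not hyb:
        raise ValueError("no hybridization-control columns declared")
    sub = matrix.counts[hyb]
    valid = (sub > 0).all(axis=1)
    per_aoi = pd.Series(np.nan, index=matrix.counts.index, dtype=float)
    per_aoi[valid] = _geomean(sub[valid])
    cohort = np.exp(np.log(per_aoi[valid]).mean()) if valid.any() else np.nan
    factor = per_aoi / cohort

    counts = matrix.counts.copy()
    counts.loc[valid] = counts.loc[valid].div(factor[valid], axis=0)
    meta = matrix.meta.copy()
    meta["hyb_norm_factor"] = factor
    out = replace(matrix, counts=counts, meta=meta)
    if (~valid).any():
        out = out.log_flags(matrix.counts.index[~valid], "nonpositive hyb control")
    return out


def qc_filter(
    matrix: AOIMatrix,
    min_nuclei: float = DEFAULT_MIN_NUCLEI,
    max_norm_factor: float = DEFAULT_MAX_NORM_FACTOR,
) -> AOIMatrix:
    """Drop AOIs failing nuclei-count or normalization-factor QC.

    Exclusion rules (strict inequalities; equality passes): nuclei_count <
    ``min_nuclei``, hybridization normalization factor > ``max_norm_factor``,
    or factor NA (invalid hybridization controls).  Every exclusion is
    appended to the QC log with its reason.  Idempotent.
    """
    if "hyb_norm_factor" not in matrix.meta.columns:
        raise ValueError("run hyb_normalize before qc_filter")
    nuclei = matrix.meta["nuclei_count"].astype(float)
    factor = matrix.meta["hyb_norm_factor"].astype(float)
    low_nuclei = nuclei < min_nuclei
    high_factor = factor > max_norm_factor
    bad_factor = factor.isna()
    keep = ~(low_nuclei | high_factor | bad_factor)
    if not keep.any():
        raise ValueError(
            "QC removed every AOI; review min_nuclei/max_norm_factor thresholds"
        )
    out = matrix.subset(keep)
    out = out.log_flags(matrix.aoi_ids[low_nuclei], f"nuclei_count < {min_nuclei}")
    out = out.log_flags(
        matrix.aoi_ids[high_factor], f"hyb norm factor > {max_norm_factor}"
    )
    out = out.log_flags(matrix.aoi_ids[bad_factor & ~low_nuclei], "hyb norm factor NA")
    return out


def split_by_segment(matrix: AOIMatrix) -> tuple[AOIMatrix, AOIMatrix]:
    """Partition AOIs into (tumor, immune) matrices; union equals the input."""
    seg = matrix.meta["segment"].astype(str)
    unknown = set(seg.unique()) - {"tumor", "immune"}
    if unknown:
        raise ValueError(f"unknown segment labels: {sorted(unknown)}")
    return matrix.subset(seg == "tumor"), matrix.subset(seg == "immune")


def select_housekeepers(
    matrix: AOIMatrix, candidates: list[str] | None = None
) -> tuple[tuple[str, str], pd.DataFrame]:
    """Pick the two most strongly correlated housekeeper candidates.

    Correlations are Pearson on natural-log counts across AOIs.  Returns
    the winning pair and the full candidate correlation table.  Candidates
    with zero variance (or non-positive counts) are ineligible (NA
    correlations).
    """
    cand = list(candidates) if candidates is not None else list(matrix.roles.housekeepers)
    if len(cand) < 2:
        raise ValueError("need at least two housekeeper candidates")
    logs = {}
    for c in cand:
        col = matrix.counts[c].astype(float)
        logs[c] = np.log(col.where(col > 0))
    logframe = pd.DataFrame(logs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = logframe.corr(method="pearson")
    # constant columns yield NaN correlation -> ineligible
    for c in cand:
        if logframe[c].std(ddof=1) == 0 or logframe[c].isna().any():
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    best, best_r = None, -np.inf
    for i, a in enumerate(cand):
        for b in cand[i + 1:]:
            r = corr.loc[a, b]
            if pd.notna(r) and r > best_r:
                best, best_r = (a, b), r
    if best is None:
        if len(cand) == 2:
            best = (cand[0], cand[1])
        else:
            raise ValueError("no eligible housekeeper pair (all correlations NA)")
    return best, corr


def housekeeper_normalize(
    matrix: AOIMatrix, housekeepers: tuple[str, str] = DEFAULT_HOUSEKEEPER_PAIR
) -> AOIMatrix:
    """Scale each AOI by the geometric mean of its housekeeper counts.

    AOIs with a non-positive housekeeper count cannot be scaled; they are
    flagged and dropped from the output.  Applied separately to the tumor
    and the immune matrix in the standard pipeline.
    """
    hk = list(housekeepers)
    missing = [h for h in hk if h not in matrix.counts.columns]
    if missing:
        raise ValueError(f"housekeeper columns missing: {missing}")
    sub = matrix.counts[hk].astype(float)
    valid = (sub > 0).all(axis=1)
    out = matrix.subset(valid)
    divisor = _geomean(sub[valid])
    counts = out.counts.div(divisor, axis=0)
    meta = out.meta.copy()
    meta["housekeeper_factor"] = divisor
    out = replace(out, counts=counts, meta=meta)
    if (~valid).any():
        out = out.log_flags(
            matrix.aoi_ids[~valid], "nonpositive housekeeper count"
        )
    return out


def normalize_pipeline(
    matrix: AOIMatrix,
    min_nuclei: float = DEFAULT_MIN_NUCLEI,
    max_norm_factor: float = DEFAULT_MAX_NORM_FACTOR,
    housekeepers: tuple[str, str] = DEFAULT_HOUSEKEEPER_PAIR,
) -> tuple[AOIMatrix, AOIMatrix]:
    """Full chain: hyb_normalize -> qc_filter -> split -> housekeeper_normalize."""
    m = qc_filter(hyb_normalize(matrix), min_nuclei, max_norm_factor)
    tumor, immune = split_by_segment(m)
    out = []
    for part in (tumor, immune):
        out.append(
            housekeeper_normalize(part, housekeepers) if len(part.counts) else part
        )
    return out[0], out[1]
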