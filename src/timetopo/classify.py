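"""Rule-based topology classification of ROIs and per-patient consensus.

An ROI is *insignificant* when immune cells are effectively absent
(immune cell ratio below a cutoff, or too few immune cells for reliable
segmentation); otherwise it is *diffuse* when tumor-immune mixing is high
(high group degree centrality, tumor-tumor co-occurrence near its random
expectation) and *focal* when immune cells sit in self-aggregated niches.

The diffuse/focal thresholds are not universal constants — they are
calibrated on labeled training data (:func:`calibrate_rule`) and recorded
with every emitted label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

INSIGNIFICANT = "insignificant"
FOCAL = "focal"
DIFFUSE = "diffuse"
LABELS = (DIFFUSE, FOCAL, INSIGNIFICANT)

#: consensus tie-break order (earlier wins)
TIE_BREAK = (DIFFUSE, FOCAL, INSIGNIFICANT)


@dataclass
class TopologyRule:
    """Thresholds that turn ROI spatial features into a topology label."""

    insignificance_cutoff: float = 0.2
    min_immune_cells: int = 20
    gdc_threshold: float | None = None
    ccr_tt_threshold: float | None = None
    threshold_px: float = 30.0

    def validate(self) -> None:
        if not 0 <= self.insignificance_cutoff <= 1:
            raise ValueError("insignificance_cutoff must be in [0, 1]")
        if self.min_immune_cells < 0:
            raise ValueError("min_immune_cells must be non-negative")
        if self.gdc_threshold is not None and not 0 <= self.gdc_threshold <= 1:
            raise ValueError("gdc_threshold must be in [0, 1]")
        if self.ccr_tt_threshold is not None and self.ccr_tt_threshold <= 0:
            raise ValueError("ccr_tt_threshold must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _get(features, name: str):
    if isinstance(features, pd.Series):
        if name not in features.index:
            raise ValueError(f"missing required feature: {name}")
        return features[name]
    if isinstance(features, dict):
        if name not in features:
            raise ValueError(f"missing required feature: {name}")
        return features[name]
    if not hasattr(features, name):
        raise ValueError(f"missing required feature: {name}")
    return getattr(features, name)


def classify_roi(features, rule: TopologyRule) -> str:
    """Label one ROI's feature record as diffuse / focal / insignificant.

    Insignificance is decided first, from immune presence alone (strict
    inequalities: ratio < cutoff or immune count < minimum).  Otherwise the
    ROI is diffuse when gdc >= gdc_threshold AND ccr_tt <= ccr_tt_threshold,
    else focal.  NA spatial statistics on a non-insignificant ROI are a
    classification error, never silently mapped to a label.
    """
    rule.validate()
    immune_ratio = float(_get(features, "immune_ratio"))
    n_immune = float(_get(features, "n_immune"))
    feat_thr = _get(features, "threshold_px")
    if feat_thr is not None and not np.isnan(float(feat_thr)):
        if float(feat_thr) != float(rule.threshold_px):
            raise ValueError(
                f"features computed at {feat_thr} px but rule expects "
                f"{rule.threshold_px} px"
            )
    if np.isnan(immune_ratio) or immune_ratio < rule.insignificance_cutoff:
        return INSIGNIFICANT
    if n_immune < rule.min_immune_cells:
        return INSIGNIFICANT
    if rule.gdc_threshold is None or rule.ccr_tt_threshold is None:
        raise ValueError("rule is not calibrated: gdc/ccr thresholds unset")
    gdc = float(_get(features, "gdc"))
    ccr_tt = float(_get(features, "ccr_tt"))
    if np.isnan(gdc) or np.isnan(ccr_tt):
        raise ValueError(
            "gdc/ccr_tt undefined for a non-insignificant ROI; cannot classify"
        )
    if gdc >= rule.gdc_threshold and ccr_tt <= rule.ccr_tt_threshold:
        return DIFFUSE
    return FOCAL


def classify_table(features: pd.DataFrame, rule: TopologyRule) -> pd.DataFrame:
    """Apply :func:`classify_roi` to a feature table (rows at rule.threshold_px)."""
    sub = features[features["threshold_px"] == rule.threshold_px]
    if sub.empty:
        raise ValueError(f"no feature rows at threshold {rule.threshold_px} px")
    out = sub.copy()
    out["label"] = [classify_roi(row, rule) for _, row in sub.iterrows()]
    return out


def balanced_accuracy(truth, predicted) -> float:
    """Mean per-class recall (insensitive to class imbalance)."""
    truth = pd.Series(list(truth))
    predicted = pd.Series(list(predicted))
    recalls = [
        (predicted[truth == c] == c).mean() for c in truth.unique()
    ]
    return float(np.mean(recalls))


def _sweep_threshold(values: np.ndarray, labels: np.ndarray,
                     positive: str, direction: str) -> tuple[float, float]:
    """1-D threshold sweep maximizing balanced accuracy of a single-feature rule.

    ``direction='ge'`` predicts ``positive`` when value >= t, ``'le'`` when
    value <= t.  Candidates are midpoints between consecutive sorted unique
    values (plus just-outside sentinels); the first argmax in sweep order is
    returned, so the result is deterministic given input order.
    """
    finite = np.isfinite(values)
    values, labels = values[finite], labels[finite]
    uniq = np.unique(values)
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = np.concatenate(
            [[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1e-9]]
        )
    best_t, best_acc = candidates[0], -1.0
    other = labels[labels != positive]
    neg = other[0] if len(other) else positive
    for t in candidates:
        pred = np.where(
            values >= t if direction == "ge" else values <= t, positive, neg
        )
        acc = balanced_accuracy(labels, pred)
        if acc > best_acc:
            best_t, best_acc = float(t), float(acc)
    return best_t, best_acc


def calibrate_rule(
    features: pd.DataFrame,
    labels: pd.Series,
    base_rule: TopologyRule | None = None,
) -> TopologyRule:
    """Learn gdc / ccr_tt thresholds from labeled training features.

    Only diffuse vs focal rows drive the sweeps (insignificance is governed
    by the fixed immune-presence cutoffs).  Each threshold maximizes
    balanced accuracy of its own single-feature rule over midpoint
    candidates; deterministic given input order.
    """
    rule = base_rule or TopologyRule()
    labels = pd.Series(list(labels))
    if labels.nunique() < 2:
        raise ValueError("calibration needs at least two label classes")
    mask = labels.isin([DIFFUSE, FOCAL]).to_numpy()
    sub = features.iloc[np.flatnonzero(mask)]
    sub_labels = labels[mask].to_numpy()
    if len(np.unique(sub_labels)) < 2:
        raise ValueError("calibration needs both diffuse and focal examples")
    gdc_t, _ = _sweep_threshold(
        sub["gdc"].to_numpy(dtype=float), sub_labels, DIFFUSE, "ge"
    )
    ccr_t, _ = _sweep_threshold(
        sub["ccr_tt"].to_numpy(dtype=float), sub_labels, DIFFUSE, "le"
    )
    return replace(rule, gdc_threshold=gdc_t, ccr_tt_threshold=ccr_t)


def consensus_label(roi_labels: pd.DataFrame,
                    patient_col: str = "patient_id",
                    label_col: str = "label") -> pd.Series:
    """Majority vote over each patient's ROI labels.

    Ties break in the fixed order diffuse > focal > insignificant, so a
    patient with one diffuse and one focal ROI is called diffuse.
    """
    def vote(vals: pd.Series) -> str:
        counts = vals.value_counts()
        top = counts.max()
        winners = set(counts[counts == top].index)
        for label in TIE_BREAK:
            if label in winners:
                return label
        return counts.idxmax()  # unknown labels: plain plurality

    out = roi_labels.groupby(patient_col)[label_col].apply(vote)
    out.name = "consensus_label"
    return out
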