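"""Published annotation bookkeeping for the ovarian-carcinoma DSP cohort.

The cohort this workflow targets annotated each ROI's immune topology by
visual review as diffuse, focal or insignificant.  The per-label ROI counts
ship with the package as a small data table and back sanity checks such as
the infiltrated-ROI total (infiltrated = diffuse or focal).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import DIFFUSE, FOCAL, LABELS

INFILTRATED_LABELS = (DIFFUSE, FOCAL)


def load_roi_annotation_counts() -> pd.DataFrame:
    """ROI topology annotation counts (columns: label, n_rois)."""
    ref = resources.files("timetopo.data") / "cohort_roi_annotation.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    unknown = set(table["label"]) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown topology labels in annotation table: {unknown}")
    return table


def count_infiltrated(annotation: pd.DataFrame) -> int:
    """Total ROIs whose topology label marks them as immune-infiltrated."""
    mask = annotation["label"].isin(INFILTRATED_LABELS)
    return int(annotation.loc[mask, "n_rois"].sum())
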