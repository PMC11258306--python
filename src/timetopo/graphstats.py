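"""Distance-band cell graphs and spatial tumor-immune topology statistics.

Cells classified as tumor / immune / other are treated as a marked point
pattern; an undirected graph connects every pair of cells whose centroid
distance is at most a threshold (a *distance band*, closed boundary).  On
that graph four statistics summarise tumor-immune topology:

``group degree centrality (gdc)``
    fraction of tumor cells with at least one immune neighbor,
``attribute assortativity``
    Newman's attribute assortativity of the tumor/immune label,
``cluster co-occurrence ratio (ccr)``
    observed edge count for a class pair divided by its expectation under
    random relabeling of the same positions (class counts preserved),
``immune cell ratio``
    immune / (tumor + immune) cell count.

"other" cells are carried as graph nodes but excluded from all class
statistics.  Degenerate statistics are reported as NaN, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

TUMOR = "tumor"
IMMUNE = "immune"
OTHER = "other"
CLASSES = (TUMOR, IMMUNE, OTHER)

#: CellTable columns expected by every operation in this module.
CELL_COLUMNS = ["roi_id", "cell_id", "x_px", "y_px", "cls"]


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check CellTable schema; returns the (unmodified) frame for chaining."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"CellTable missing columns: {missing}")
    xy = cells[["x_px", "y_px"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("CellTable coordinates must be finite")
    bad = set(cells["cls"].unique()) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown cell classes: {sorted(bad)}")
    dup = cells.duplicated(subset=["roi_id", "cell_id"])
    if dup.any():
        raise ValueError("cell_id values must be unique within an ROI")
    return cells


def px_to_um(distance_px: float, pixel_size_um: float) -> float:
    """Convert a pixel distance to microns (e.g. 30 px at 0.4 um/px = 12 um)."""
    if distance_px < 0 or pixel_size_um < 0:
        raise ValueError("distances and pixel sizes must be non-negative")
    return distance_px * pixel_size_um


def build_distance_graph(cells: pd.DataFrame, threshold_px: float) -> nx.Graph:
    """Build the undirected distance-band graph over one ROI's cells.

    An edge joins cells i, j iff their Euclidean centroid distance is
    <= ``threshold_px`` (closed boundary); the edge weight is the distance.
    Nodes carry the ``cls`` attribute; "other" cells are included as nodes.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    validate_cell_table(cells)
    ids = cells["cell_id"].to_numpy()
    xy = cells[["x_px", "y_px"]].to_numpy(dtype=float)
    g = nx.Graph(threshold_px=float(threshold_px))
    g.add_nodes_from(
        (i, {"cls": c, "x": x, "y": y})
        for i, c, (x, y) in zip(ids, cells["cls"], xy)
    )
    if len(cells) > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=threshold_px, output_type="ndarray")
        if len(pairs):
            d = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
            g.add_weighted_edges_from(
                zip(ids[pairs[:, 0]], ids[pairs[:, 1]], d)
            )
    return g


def group_degree_centrality(g: nx.Graph) -> float:
    """Fraction of tumor cells with >= 1 immune neighbor in the band graph.

    Returns NaN (with a warning) if the graph has no tumor cells.
    """
    cls = nx.get_node_attributes(g, "cls")
    tumor_nodes = [n for n, c in cls.items() if c == TUMOR]
    if not tumor_nodes:
        warnings.warn("group degree centrality undefined: no tumor cells")
        return float("nan")
    hit = sum(
        any(cls[m] == IMMUNE for m in g.neighbors(n)) for n in tumor_nodes
    )
    return hit / len(tumor_nodes)


def attribute_assortativity(g: nx.Graph) -> float:
    """Newman attribute assortativity of the tumor/immune label.

    Computed on the subgraph of tumor and immune nodes only ("other" cells
    and their edges are dropped).  +1 means edges connect like classes only,
    -1 a perfectly bipartite tumor-immune mixing.  NaN when the subgraph has
    no edges or only one class participates in edges.
    """
    cls = nx.get_node_attributes(g, "cls")
    keep = [n for n, c in cls.items() if c in (TUMOR, IMMUNE)]
    sub = g.subgraph(keep)
    if sub.number_of_edges() == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.attribute_assortativity_coefficient(sub, "cls")
    return float(r)


def _pair_counts(labels: np.ndarray, u: np.ndarray, v: np.ndarray,
                 pair: tuple[str, str]) -> np.ndarray:
    """Unordered edge counts for a class pair; labels may be 1-D or (m, n)."""
    a, b = pair
    lu, lv = labels[..., u], labels[..., v]
    if a == b:
        hit = (lu == a) & (lv == a)
    else:
        hit = ((lu == a) & (lv == b)) | ((lu == b) & (lv == a))
    return hit.sum(axis=-1)


def cluster_cooccurrence_ratio(
    g: nx.Graph,
    pair: str,
    n_perm: int = 1000,
    seed: int = 0,
    return_se: bool = False,
):
    """Cluster co-occurrence ratio for a class pair under a permutation null.

    Observed edge count between the requested classes divided by its mean
    over ``n_perm`` random relabelings of tumor/immune over the same nodes
    (coordinates and edge set fixed, class counts preserved).  Values > 1
    mean the pair co-occurs within the distance band more than random
    labeling predicts.  ``pair`` is one of ``"tumor-tumor"``,
    ``"immune-immune"``, ``"tumor-immune"``.

    Returns NaN when the null expectation is zero (e.g. fewer than two
    members of a within-class pair).  With ``return_se=True`` also returns
    the Monte-Carlo standard error of the null mean, propagated to the
    ratio scale.
    """
    pair_map = {
        "tumor-tumor": (TUMOR, TUMOR),
        "immune-immune": (IMMUNE, IMMUNE),
        "tumor-immune": (TUMOR, IMMUNE),
        "immune-tumor": (TUMOR, IMMUNE),
    }
    if pair not in pair_map:
        raise ValueError(f"unknown pair {pair!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    classes = pair_map[pair]

    cls = nx.get_node_attributes(g, "cls")
    nodes = [n for n, c in cls.items() if c in (TUMOR, IMMUNE)]
    index = {n: k for k, n in enumerate(nodes)}
    labels = np.array([cls[n] for n in nodes], dtype=object)
    edges = [
        (index[a], index[b])
        for a, b in g.edges()
        if a in index and b in index
    ]
    nan = (float("nan"), float("nan")) if return_se else float("nan")
    if not edges:
        return nan
    u = np.fromiter((e[0] for e in edges), int)
    v = np.fromiter((e[1] for e in edges), int)
    observed = float(_pair_counts(labels, u, v, classes))

    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(labels, (n_perm, len(labels))), axis=1
    )
    null_counts = _pair_counts(perm, u, v, classes).astype(float)
    mean_null = null_counts.mean()
    if mean_null == 0:
        return nan
    ratio = observed / mean_null
    if not return_se:
        return ratio
    se_mean = null_counts.std(ddof=1) / np.sqrt(n_perm) if n_perm > 1 else 0.0
    # delta method: d(obs/mu)/dmu = -obs/mu^2
    se_ratio = observed / mean_null**2 * se_mean
    return ratio, se_ratio


@dataclass
class ROIFeatureRecord:
    """Per-ROI spatial statistics plus the provenance needed to rerun them."""

    roi_id: str
    n_tumor: int
    n_immune: int
    n_other: int
    immune_ratio: float
    gdc: float
    assortativity: float
    ccr_tt: float
    ccr_ii: float
    ccr_ti: float
    threshold_px: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_roi_features(
    cells: pd.DataFrame,
    threshold_px: float = 30.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ROIFeatureRecord:
    """All spatial statistics for one ROI at one distance threshold."""
    if len(cells) == 0:
        raise ValueError("empty CellTable")
    validate_cell_table(cells)
    roi_ids = cells["roi_id"].unique()
    if len(roi_ids) != 1:
        raise ValueError("compute_roi_features expects a single ROI")
    g = build_distance_graph(cells, threshold_px)
    counts = cells["cls"].value_counts()
    n_tumor = int(counts.get(TUMOR, 0))
    n_immune = int(counts.get(IMMUNE, 0))
    n_other = int(counts.get(OTHER, 0))
    denom = n_tumor + n_immune
    immune_ratio = n_immune / denom if denom else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gdc = group_degree_centrality(g) if n_tumor else float("nan")
    return ROIFeatureRecord(
        roi_id=str(roi_ids[0]),
        n_tumor=n_tumor,
        n_immune=n_immune,
        n_other=n_other,
        immune_ratio=immune_ratio,
        gdc=gdc,
        assortativity=attribute_assortativity(g),
        ccr_tt=cluster_cooccurrence_ratio(g, "tumor-tumor", n_perm, seed),
        ccr_ii=cluster_cooccurrence_ratio(g, "immune-immune", n_perm, seed + 1),
        ccr_ti=cluster_cooccurrence_ratio(g, "tumor-immune", n_perm, seed + 2),
        threshold_px=float(threshold_px),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def compute_feature_table(
    cells: pd.DataFrame,
    thresholds_px: tuple[float, ...] = (30.0, 50.0),
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature records for every ROI in a multi-ROI CellTable, per threshold."""
    rows = []
    for k, (roi, sub) in enumerate(cells.groupby("roi_id", sort=True)):
        for t in thresholds_px:
            rec = compute_roi_features(sub, t, n_perm=n_perm, seed=seed + k)
            rows.append(rec.to_dict())
    return pd.DataFrame(rows)
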