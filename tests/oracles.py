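"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (O(n^2) scans, closed-form
expectations, exhaustive sweeps) and shares no code with the package paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def brute_edges(cells: pd.DataFrame, threshold: float) -> set:
    """All unordered cell-id pairs within the distance band, by O(n^2) scan."""
    rows = list(cells.itertuples())
    out = set()
    for a, b in itertools.combinations(rows, 2):
        d = math.hypot(a.x_px - b.x_px, a.y_px - b.y_px)
        if d <= threshold:
            out.add(frozenset((a.cell_id, b.cell_id)))
    return out


def brute_gdc(cells: pd.DataFrame, threshold: float) -> float:
    """Fraction of tumor cells with an immune cell within the band."""
    tumor = cells[cells.cls == "tumor"]
    immune = cells[cells.cls == "immune"]
    if len(tumor) == 0:
        return float("nan")
    if len(immune) == 0:
        return 0.0
    hits = 0
    for t in tumor.itertuples():
        for i in immune.itertuples():
            if math.hypot(t.x_px - i.x_px, t.y_px - i.y_px) <= threshold:
                hits += 1
                break
    return hits / len(tumor)


def brute_assortativity(cells: pd.DataFrame, threshold: float) -> float:
    """Newman attribute assortativity from the mixing matrix, first principles.

    Classified (tumor/immune) nodes only; each undirected edge contributes
    to the mixing matrix in both directions.  NaN when no classified edges
    or the denominator vanishes.
    """
    sub = cells[cells.cls.isin(["tumor", "immune"])]
    labels = {r.cell_id: r.cls for r in sub.itertuples()}
    cats = ["tumor", "immune"]
    e = np.zeros((2, 2))
    for pair in brute_edges(sub, threshold):
        a, b = tuple(pair)
        i, j = cats.index(labels[a]), cats.index(labels[b])
        e[i, j] += 1
        e[j, i] += 1
    if e.sum() == 0:
        return float("nan")
    e = e / e.sum()
    a_marg = e.sum(axis=1)
    b_marg = e.sum(axis=0)
    denom = 1.0 - float(a_marg @ b_marg)
    if denom == 0:
        return float("nan")
    return (float(np.trace(e)) - float(a_marg @ b_marg)) / denom


def exact_null_pair_expectation(
    n_tumor: int, n_immune: int, n_edges: int, pair: str
) -> float:
    """Expected pair edge count under uniform label permutation, closed form.

    Each edge's endpoints are a uniform random distinct pair of the
    n = n_tumor + n_immune classified nodes, so the expectation is
    n_edges times the pair-type probability.
    """
    n = n_tumor + n_immune
    total_pairs = n * (n - 1) / 2
    if pair == "tumor-tumor":
        w = n_tumor * (n_tumor - 1) / 2
    elif pair == "immune-immune":
        w = n_immune * (n_immune - 1) / 2
    else:
        w = n_tumor * n_immune
    return n_edges * w / total_pairs


def brute_sweep(values, labels, positive, direction):
    """Exhaustive midpoint-threshold sweep maximizing balanced accuracy."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    finite = np.isfinite(values)
    values, labels = values[finite], labels[finite]
    uniq = np.unique(values)
    if len(uniq) == 1:
        cands = [uniq[0]]
    else:
        cands = (
            [uniq[0] - 1e-9]
            + [(uniq[k] + uniq[k + 1]) / 2 for k in range(len(uniq) - 1)]
            + [uniq[-1] + 1e-9]
        )
    classes = list(dict.fromkeys(labels))

    def balanced(pred):
        recalls = []
        for c in classes:
            m = labels == c
            recalls.append((pred[m] == c).mean())
        return np.mean(recalls)

    neg = next((c for c in classes if c != positive), positive)
    best_t, best = None, -1.0
    for t in cands:
        if direction == "ge":
            pred = np.where(values >= t, positive, neg)
        else:
            pred = np.where(values <= t, positive, neg)
        acc = balanced(pred)
        if acc > best:
            best_t, best = float(t), float(acc)
    return best_t, best
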