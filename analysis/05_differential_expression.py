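"""Mixed-model differential expression between topology classes.

Per marker and segment, fits log(normalized signal) ~ topology label with a
patient random intercept, contrasting diffuse vs focal ROIs, and writes
volcano tables and figures (reference line at p = 0.05; raw p-values govern
significance, a BH column is informational).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUT

import matplotlib.pyplot as plt

import timetopo as tt
from timetopo import io as tio
from timetopo.plots import volcano


def main():
    labels = tio.read_table(OUT / "roi_labels.tsv")
    roi_to_label = labels.drop_duplicates("roi_id").set_index("roi_id")["label"]

    for segment in ("tumor", "immune"):
        part = tio.read_aoi_matrix(
            OUT / f"counts_{segment}_norm.tsv", OUT / f"meta_{segment}.tsv"
        )
        lab = part.meta["roi_id"].map(roi_to_label)
        keep = lab.isin(["diffuse", "focal"]).to_numpy()
        if keep.sum() < 4 or lab[keep].nunique() < 2:
            print(f"{segment}: too few labeled AOIs, skipped")
            continue
        targets = part.roles.targets(part.counts.columns)
        res = tt.lmm_differential(
            part.counts.loc[keep, targets], lab[keep],
            part.meta.loc[keep, "patient_id"],
        )
        tio.write_table(res, OUT / f"diffexp_{segment}_diffuse_vs_focal.tsv")
        sig = res[(res.converged) & (res.p_value < 0.05)].sort_values("p_value")
        print(f"{segment} AOIs, diffuse vs focal (n={int(keep.sum())}): "
              f"{len(sig)} markers at p < 0.05")
        if len(sig):
            print(sig[["marker", "coefficient", "p_value"]].round(4)
                  .to_string(index=False))
        fig, ax = plt.subplots()
        volcano(res, ax=ax)
        ax.set_title(f"{segment} AOIs: diffuse vs focal")
        fig.tight_layout()
        fig.savefig(OUT / f"volcano_{segment}.svg")


if __name__ == "__main__":
    main()
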