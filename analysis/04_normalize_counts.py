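"""QC and normalize the AOI protein counts.

Applies the standard DSP protein chain — hybridization-control scaling, QC
exclusion (nuclei < 20 or normalization factor > 3), tumor/immune split,
and per-AOI housekeeper (GAPDH/S6 geometric mean) scaling — and verifies on
this cohort that the isotype-background vs nuclei-count correlation is
neutralized.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, OUT

import pandas as pd
from scipy.stats import pearsonr

import timetopo as tt
from timetopo import io as tio


def main():
    matrix = tio.read_aoi_matrix(DATA / "counts_raw.tsv", DATA / "aoi_meta.tsv")

    pair, corr = tt.select_housekeepers(matrix)
    print(f"most correlated housekeeper pair: {pair} "
          f"(r = {corr.loc[pair[0], pair[1]]:.3f})")
    tio.write_table(corr.reset_index(), OUT / "housekeeper_correlations.tsv")

    pre_r, _ = pearsonr(matrix.counts["msIgG1"], matrix.meta["nuclei_count"])
    tumor, immune = tt.normalize_pipeline(matrix)
    post = pd.concat([tumor.counts["msIgG1"], immune.counts["msIgG1"]])
    post_nuc = pd.concat([tumor.meta["nuclei_count"], immune.meta["nuclei_count"]])
    post_r, _ = pearsonr(post, post_nuc)
    print(f"isotype msIgG1 vs nuclei correlation: {pre_r:.3f} before, "
          f"{post_r:.3f} after normalization")

    qc = pd.concat([tumor.qc_log, immune.qc_log]).drop_duplicates()
    tio.write_table(qc, OUT / "qc_log.tsv")
    print(f"QC excluded {qc.aoi_id.nunique()} AOIs "
          f"({len(tumor.counts)} tumor / {len(immune.counts)} immune retained)")

    tio.write_aoi_matrix(tumor, OUT / "counts_tumor_norm.tsv", OUT / "meta_tumor.tsv")
    tio.write_aoi_matrix(immune, OUT / "counts_immune_norm.tsv", OUT / "meta_immune.tsv")


if __name__ == "__main__":
    main()
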