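# timetopo

Spatial tumor–immune microenvironment (TIME) topology scoring for ovarian
carcinoma tissue profiling — graph statistics on classified cell centroids,
digital spatial profiling (DSP) protein QC and normalization, mixed-model
differential expression, rule-based topology classification, and survival
analysis, all exercisable end to end on synthetic data with known ground
truth.

## Who this is for

Groups running GeoMx-style DSP protein panels on tumor tissue with
accompanying immunofluorescence ROI images (nuclei / PanCk / CD45) who want
a reproducible, objective alternative to visual scoring of immune
infiltration patterns: *diffuse* (immune cells interspersed among tumor
cells), *focal* (immune niches aggregated within the tumor), or
*insignificant* (immune cells effectively absent).

## The statistics at the core

Cells in a 300-µm circular ROI are nodes of an undirected graph with an
edge wherever two centroids lie within a distance band *d* (30 px = 12 µm
and 50 px = 20 µm at the 20× pixel scale of 0.4 µm/px). On that graph:

- **group degree centrality** — gdc = |{tumor cells with ≥ 1 immune
  neighbor}| / |{tumor cells}| ∈ [0, 1];
- **cluster co-occurrence ratio** — for a class pair *ab*,
  ccr_ab = E_ab(observed) / E̅_ab(null), where the null permutes the
  tumor/immune labels over the same positions (class counts preserved,
  edge set fixed); ccr ≈ 1 means random mixing, ccr_tt > 1 tumor
  self-aggregation;
- **attribute assortativity** — Newman's categorical assortativity of the
  tumor/immune label, in [−1, 1];
- **immune cell ratio** — n_immune / (n_tumor + n_immune).

Diffuse infiltration shows high gdc with ccr_tt ≈ 1; focal niches show low
gdc and ccr_tt > 1; the immune ratio (cutoff 0.2, minimum 20 immune cells)
separates insignificant ROIs. Protein counts are processed as
hybridization-control scaling → QC (nuclei < 20 or factor > 3 excluded) →
tumor/immune split → per-AOI housekeeper (geomean of GAPDH and S6)
scaling, then per-marker linear mixed models `log signal ~ group +
(1 | patient)` with raw p < 0.05 as the significance rule.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (40 ROIs, 20 patients, 66 AOIs × 29 markers):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_spatial_features.py
python analysis/03_classify_topology.py
python analysis/04_normalize_counts.py
python analysis/05_differential_expression.py
python analysis/06_survival.py
```

Selected output:

```
mean spatial statistics at 30 px by generative pattern:
               immune_ratio    gdc  ccr_tt  ccr_ii
diffuse               0.242  0.378   1.011   1.077
focal                 0.242  0.022   1.210   4.967
insignificant         0.020  0.035   0.994   1.006

calibrated rule: gdc >= 0.198 and ccr_tt <= 1.099 -> diffuse
ROI label agreement with generative truth: 100.0% (balanced accuracy 1.000)

isotype msIgG1 vs nuclei correlation: 0.895 before, -0.182 after normalization

tumor AOIs, diffuse vs focal (n=26): 2 markers at p < 0.05
marker  coefficient  p_value
  IDO1      -1.0824   0.0166
 PD-L1      -1.0257   0.0294
```

Reading these: diffuse and focal ROIs carry the *same* immune ratio
(0.242), so abundance alone cannot distinguish them — but gdc separates
them by more than an order of magnitude and ccr_tt moves in the opposite
direction, which is exactly what the classification rule exploits.
Housekeeper normalization removes the nuclei-count-driven background
signal, and the mixed models recover the markers simulated as elevated in
diffuse regions (negative coefficients on the focal-vs-diffuse contrast).

Alternatively, `timetopo.run_pipeline(PipelineConfig(...))` executes the
same chain from one config, writing every table with a config hash and a
machine-readable run log; reruns are byte-identical.

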