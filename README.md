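# svzlineage

Analysis pipeline for studying **dorsal vs. ventral neurogenic lineages in
the ventricular–subventricular zone (V-SVZ)** from single-cell and
single-nucleus RNA-seq, exercised end to end on synthetic data with known
ground truth.

The adult V-SVZ harbors neural stem cells (B cells) that give rise to
transit-amplifying progenitors (C cells) and migrating neuroblasts
(A cells). Dorsal and ventral territories of the niche produce distinct
neuron types, and regional gene programs persist along the whole
B→C→A lineage. This package implements the computational machinery needed
to detect and characterize those lineages:

- **Quality control and demultiplexing** — percentile-based cell filtering
  (UMI depth within [P5, P95], gene count ≥ P5, mitochondrial fraction
  ≤ 10%) and sample-barcode classification with doublet flagging.
- **Preprocessing** — log-normalization, CLR for antibody tags, PCA,
  Leiden clustering at resolutions {0.5, 0.8, 1.0, 1.5, 2.0}, and
  cell-cycle (S/G2M) module scoring against expression-matched controls.
- **Marker discovery** — Wilcoxon rank-sum differential expression with
  Benjamini–Hochberg correction (significant at p_adj < 0.05) and the
  candidate-marker filter: significantly upregulated genes expressed in no
  more than 40% of cells of the other cluster.
- **Regional label transfer** — a region-balanced reference (equal cells
  per region, drawn from the middle 50% by genes-per-cell), a shared CCA
  embedding (30 dims), mutual-nearest-neighbor anchors, and per-cell
  dorsal/ventral predicted-identity scores with a net score
  `d − v ∈ [−1, 1]`.
- **Signature scoring** — per-cell gene-set activity as the normalized
  area under the recovery curve `R(k) = |set ∩ top-k genes|` for
  `k ≤ ⌈0.05·n_genes⌉`; min-max normalization; High-Score dorsal/ventral
  selection as the top/bottom quartiles of the score difference.
- **Gene regulatory networks** — random-forest link importance per target
  gene, top-300 marker-anchored networks, two-ring gene-centric expansion,
  component sizes and mean local clustering coefficients.
- **Spatial quantification** — projection of in situ spots onto a
  measurement polyline, normalized axis coordinate t ∈ [0, 1]
  (0 = ventral-most, 1 = dorso-lateral wedge tip), density/median
  profiles, dorsal domain `t ≥ 2/3`, co-labeling percentages, and
  two-group t tests.

A first-class synthetic data generator (`svzlineage.simulate`) produces the
whole study: negative-binomial counts for a five-stage lineage crossed
with persistent regional programs, sample barcodes with configurable
doublet rates, four region-dissected nucleus samples (dorsal: fewer cells,
higher depth), and Beta-distributed spot positions — all with truth tables
so every recovery claim is scored against ground truth.

## Worked example

```python
from svzlineage import preprocess as pp
from svzlineage.qc import QcReport
from svzlineage.scoring import auc_score, high_score_selection, minmax_normalize
from svzlineage.simulate import SimConfig, simulate_lineage_counts

report = QcReport(n_input=35025, n_retained=30897, doublet_count=4128)
print(report.doublet_percent)            # 11.7%  (truncated, not rounded)

ds = simulate_lineage_counts(SimConfig(seed=20))
expr = pp.normalize(ds.counts.subset_cells((~ds.truth["doublet"]).to_numpy()))
d = auc_score(expr, ds.program_genes["dorsal"], top_frac=0.05, seed=3)["auc"]
v = auc_score(expr, ds.program_genes["ventral"], top_frac=0.05, seed=3)["auc"]
labels = high_score_selection(minmax_normalize(d), minmax_normalize(v))
print((labels == "HighDorsal").sum())    # 235
```

Running the numbered drivers in `analysis/` reproduces the full study on
the synthetic data, e.g. `python analysis/06_signatures.py` prints:

```
HighDorsal 235 cells (dorsal purity 1.00); HighVentral 235 cells (ventral purity 1.00)
per-stage dorsal composite means: {'B': 0.197, 'C': 0.192, 'A': 0.190} (spread 3.5%)
dorsal lineage signature: 50 genes
```

i.e. the quartile High-Score rule selects pure regional populations, the
composite regional score stays flat along the B→C→A lineage (the lineages
retain their regional identity), and intersecting B-cell and A-cell
markers recovers the full planted regional program.

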