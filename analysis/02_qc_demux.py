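"""Demultiplex sample barcodes and apply percentile QC.

Reports the doublet percentage (truncated to one decimal, as in the study's
'4128 out of 35,025 cells, 11.7%' convention) and the per-rule removals.
"""

import os

from common import dataset, outdir, study_config
from svzlineage.qc import QcThresholds, classify_barcodes, qc_filter, qc_summary
from svzlineage.simulate import simulate_barcode_counts

out = outdir("02_qc_demux")
ds = dataset()
cfg = study_config()

calls = classify_barcodes(simulate_barcode_counts(ds, cfg))
calls.to_csv(os.path.join(out, "demux_calls.csv"))

singlets = calls.index[calls["call"] == "singlet"]
kept, report = qc_filter(
    ds.counts.subset_cells(singlets), QcThresholds(), ds.program_genes["mito"]
)
report.n_input = ds.counts.n_cells
report.doublet_count = int((calls["call"] == "doublet").sum())

with open(os.path.join(out, "qc_report.json"), "w") as fh:
    fh.write(report.to_json())
kept.cell_meta.to_csv(os.path.join(out, "cells_retained.csv"))

truth_doub = ds.truth["doublet"]
called_doub = calls["call"] == "doublet"
print(qc_summary(report))
print(
    f"doublet recall: {(called_doub & truth_doub).sum()}/{truth_doub.sum()}"
    f" | false calls: {(called_doub & ~truth_doub).sum()}"
)
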