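"""Generate the synthetic V-SVZ study: whole-cell lineage counts with
sample barcodes, four region-dissected nucleus samples, and in situ spots.

Writes the CellRanger-style triplet layout plus truth tables so later
stages (and any outside tool) can consume them.
"""

import os

import pandas as pd

from common import dataset, outdir, spot_config, study_config
from svzlineage.io import write_10x
from svzlineage.simulate import (
    simulate_barcode_counts,
    simulate_nucleus_samples,
    simulate_spots,
)

out = outdir("01_simulate")
ds = dataset()
cfg = study_config()

write_10x(ds.counts, os.path.join(out, "whole_cell"))
ds.truth.to_csv(os.path.join(out, "truth.csv"))
pd.Series({k: ",".join(v) for k, v in ds.program_genes.items()}).to_csv(
    os.path.join(out, "program_genes.csv"), header=["genes"]
)

bc = simulate_barcode_counts(ds, cfg)
pd.DataFrame(bc.dense(), index=bc.cell_ids, columns=bc.barcode_names).to_csv(
    os.path.join(out, "barcode_counts.csv")
)

nuc = simulate_nucleus_samples(ds, cfg)
for name, cm in nuc.items():
    write_10x(cm, os.path.join(out, f"nucleus_{name}"))

spots = simulate_spots(spot_config())
spots.to_csv(os.path.join(out, "spots.csv"), index=False)

print(f"cells: {ds.counts.n_cells}, genes: {ds.counts.n_genes}")
print(f"doublets: {int(ds.truth['doublet'].sum())}")
print({k: cm.n_cells for k, cm in nuc.items()})
print(f"spots: {len(spots)} across {spots['probe'].nunique()} probes -> {out}")
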