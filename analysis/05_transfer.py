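"""Regional label transfer: build a region-balanced nucleus B-cell
reference (middle 50% by gene count, equal cells per region), anchor it to
the whole-cell B cells, and score each query cell's dorsal/ventral
predicted identity.
"""

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp

from common import dataset, outdir, study_config
from svzlineage import preprocess as pp
from svzlineage.simulate import simulate_nucleus_samples
from svzlineage.transfer import (
    TransferConfig,
    downsample_reference,
    predicted_class_counts,
    transfer_pipeline,
)
from svzlineage.types import CountMatrix

out = outdir("05_transfer")
ds = dataset()
cfg = study_config()

nuc = simulate_nucleus_samples(ds, cfg)
ref_meta = pd.concat([cm.cell_meta for cm in nuc.values()])
ref = CountMatrix(
    sp.vstack([cm.counts for cm in nuc.values()]).tocsr(),
    ref_meta,
    ds.counts.gene_meta.copy(),
)
ref_b = ref.subset_cells(ref_meta["stage"].str.startswith("B").to_numpy())

tcfg = TransferConfig(seed=2)
chosen = downsample_reference(
    ref_b.cell_ids, ref_b.cell_meta["region"], ref_b.genes_per_cell(), tcfg
)
ref_bal = ref_b.subset_cells(chosen)
print(
    "balanced reference:",
    ref_bal.cell_meta["region"].value_counts().to_dict(),
)

singlet = ~ds.truth["doublet"].to_numpy()
expr = pp.normalize(ds.counts.subset_cells(singlet))
truth = ds.truth.loc[expr.cell_ids]
b = truth["stage"].str.startswith("B").to_numpy()
query = expr.subset_cells(b)

pred = transfer_pipeline(
    pp.normalize(ref_bal), ref_bal.cell_meta["region"], query, tcfg
)
pred.to_csv(os.path.join(out, "predicted_identity.csv"))

qt = truth.loc[b]
sign_truth = np.where(qt["region"] == "dorsal", 1.0, -1.0)
acc = (np.sign(pred["net_score"].to_numpy()) == sign_truth).mean()
print("predicted class counts:", predicted_class_counts(pred))
print(f"net-score sign accuracy vs truth: {acc:.3f}")
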