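"""Composite lineage scoring: AUC activity of the dorsal and ventral
programs per cell, min-max normalization, quartile High-Score selection,
the B-and-A lineage-signature intersection, and a binomial
over-representation check of the recovered markers.
"""

import os

import numpy as np
import pandas as pd

from common import dataset, outdir
from svzlineage import preprocess as pp
from svzlineage.markers import candidate_markers, wilcoxon_de
from svzlineage.scoring import (
    GeneSet,
    auc_score,
    high_score_selection,
    lineage_signature,
    minmax_normalize,
    ora_enrichment,
)

out = outdir("06_signatures")
ds = dataset()
singlet = ~ds.truth["doublet"].to_numpy()
expr = pp.normalize(ds.counts.subset_cells(singlet))
truth = ds.truth.loc[expr.cell_ids]

auc_d = auc_score(expr, ds.program_genes["dorsal"], top_frac=0.05, seed=3)
auc_v = auc_score(expr, ds.program_genes["ventral"], top_frac=0.05, seed=3)
nd = minmax_normalize(auc_d["auc"])
nv = minmax_normalize(auc_v["auc"])
labels = high_score_selection(nd, nv)

scores = pd.DataFrame(
    {"auc_dorsal": auc_d["auc"], "auc_ventral": auc_v["auc"], "high_score": labels},
    index=expr.cell_ids,
)
scores.to_csv(os.path.join(out, "composite_scores.csv"))

hs_d = labels == "HighDorsal"
hs_v = labels == "HighVentral"
purity_d = (truth.loc[hs_d, "region"] == "dorsal").mean()
purity_v = (truth.loc[hs_v, "region"] == "ventral").mean()
print(
    f"HighDorsal {hs_d.sum()} cells (dorsal purity {purity_d:.2f}); "
    f"HighVentral {hs_v.sum()} cells (ventral purity {purity_v:.2f})"
)

# per-stage constancy of the dorsal composite in dorsal cells
dm = (truth["region"] == "dorsal").to_numpy()
comp = auc_d["auc"].to_numpy()[dm]
coarse = truth.loc[dm, "stage"].str[0].to_numpy()
means = {s: float(comp[coarse == s].mean()) for s in "BCA"}
spread = (max(means.values()) - min(means.values())) / comp.mean()
print(f"per-stage dorsal composite means: {means} (spread {100*spread:.1f}%)")

# lineage signature: markers shared by the B and A ends of each side
b_mask = truth["stage"].str.startswith("B").to_numpy()
a_mask = truth["stage"].str.startswith("A").to_numpy()


def side_markers(mask, side):
    sub = expr.subset_cells(mask)
    tr = truth.loc[mask]
    de = wilcoxon_de(
        sub,
        tr.index[tr["region"] == side],
        tr.index[tr["region"] != side],
    )
    return de[(de["p_adj"] < 0.05) & (de["log_fc"] > 0)]["gene"].tolist()


for side in ("dorsal", "ventral"):
    sig = lineage_signature(side_markers(b_mask, side), side_markers(a_mask, side))
    print(f"{side} lineage signature: {len(sig)} genes")
    with open(os.path.join(out, f"signature_{side}.txt"), "w") as fh:
        fh.write("\n".join(sig))
    # over-representation of the recovered signature in the true program
    res = ora_enrichment(
        sig,
        [GeneSet(f"true_{side}", ds.program_genes[side])],
        list(expr.gene_names),
    )
    print(
        f"  ORA vs true {side} program: p_adj = {res['p_adj'].iloc[0]:.3g}, "
        f"hits {int(res['n_hits'].iloc[0])}/{len(sig)}"
    )
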