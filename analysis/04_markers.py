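"""Differential expression between dorsal and ventral B cells, the
candidate-marker filter (significant, upregulated, expressed in at most 40%
of the other side), and the top-10 marker lists.
"""

import os

import numpy as np

from common import dataset, outdir
from svzlineage import preprocess as pp
from svzlineage.markers import candidate_markers, top_n_markers, wilcoxon_de

out = outdir("04_markers")
ds = dataset()
singlet = ~ds.truth["doublet"].to_numpy()
expr = pp.normalize(ds.counts.subset_cells(singlet))
truth = ds.truth.loc[expr.cell_ids]

b = truth["stage"].str.startswith("B")
bexpr = expr.subset_cells(b.to_numpy())
btr = truth.loc[b]
d_cells = btr.index[btr["region"] == "dorsal"]
v_cells = btr.index[btr["region"] == "ventral"]

de_d = wilcoxon_de(bexpr, d_cells, v_cells)
de_v = wilcoxon_de(bexpr, v_cells, d_cells)
de_d.to_csv(os.path.join(out, "de_dorsal.csv"), index=False)
de_v.to_csv(os.path.join(out, "de_ventral.csv"), index=False)

for side, de, true_set in (
    ("dorsal", de_d, set(ds.program_genes["dorsal"])),
    ("ventral", de_v, set(ds.program_genes["ventral"])),
):
    signif = de[(de["p_adj"] < 0.05) & (de["log_fc"] > 0)]
    cand = candidate_markers(de)
    top10 = top_n_markers(signif, 10)
    precision = np.mean([g in true_set for g in top10]) if top10 else 0.0
    print(
        f"{side}: {len(signif)} significant upregulated, "
        f"{len(cand)} pass the 40% filter, top-10 precision {precision:.2f}"
    )
    with open(os.path.join(out, f"top10_{side}.txt"), "w") as fh:
        fh.write("\n".join(top10))
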