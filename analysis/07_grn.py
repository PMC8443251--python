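"""Gene regulatory networks for dorsal and ventral B cells: tree-ensemble
link inference, top-300 marker-anchored networks, gene-centric expansion,
component sizes and clustering coefficients.
"""

import os

import networkx as nx

from common import dataset, outdir
from svzlineage import preprocess as pp
from svzlineage.grn import (
    build_marker_network,
    gene_centric_network,
    infer_links,
    network_metrics,
)
from svzlineage.markers import top_n_markers, wilcoxon_de

out = outdir("07_grn")
ds = dataset()
singlet = ~ds.truth["doublet"].to_numpy()
expr = pp.normalize(ds.counts.subset_cells(singlet))
truth = ds.truth.loc[expr.cell_ids]
b = truth["stage"].str.startswith("B").to_numpy()
bexpr = expr.subset_cells(b)
btr = truth.loc[b]

d_cells = btr.index[btr["region"] == "dorsal"]
v_cells = btr.index[btr["region"] == "ventral"]

for side, g1, g2 in (("dorsal", d_cells, v_cells), ("ventral", v_cells, d_cells)):
    de = wilcoxon_de(bexpr, g1, g2)
    markers = top_n_markers(de[(de["p_adj"] < 0.05) & (de["log_fc"] > 0)], 10)
    # restrict the expression matrix to the markers plus a pool of other
    # variable genes so inference stays desk-sized
    pool = markers + [g for g in bexpr.gene_names if g not in markers][:90]
    sub = bexpr.subset_genes([g for g in pool if g in bexpr.gene_names])
    cells = g1 if side == "dorsal" else g2
    links = infer_links(sub.subset_cells(cells), n_trees=100, seed=4)
    links.to_csv(os.path.join(out, f"links_{side}.tsv"), sep="\t", index=False)

    net = build_marker_network(links, markers, top_links=300)
    sizes, cc = network_metrics(net)
    print(
        f"{side}: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges; "
        f"components {sizes[:4]}; clustering coefficient {cc:.3f}"
    )
    nx.write_graphml(net, os.path.join(out, f"marker_network_{side}.graphml"))

    hub = markers[0]
    ring_net = gene_centric_network(links, hub, top_k=20)
    print(f"  {hub}-centric network: {ring_net.number_of_nodes()} genes")
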