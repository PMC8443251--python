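"""Tree-ensemble regulatory-link inference and marker-network construction.

For each target gene, expression (scaled to unit variance) is regressed on
all candidate regulators with a random-forest ensemble (mtry = floor(sqrt p));
a regulator's link importance is its impurity-reduction importance. Links
pooled over targets and sorted by importance form the link list from which
marker-centered and gene-centric networks are built; component sizes and
the mean local clustering coefficient are computed on the undirected
simple graph.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .preprocess import ExpressionMatrix
from .simulate import derive_seed

LINK_COLUMNS = ["regulator", "target", "importance"]


def infer_links(
    expr: ExpressionMatrix,
    regulators: Optional[Sequence[str]] = None,
    targets: Optional[Sequence[str]] = None,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> pd.DataFrame:
    """Ranked regulator -> target link list (descending importance).

    Zero-variance targets are skipped with a warning; a gene may be both
    regulator and target but never links to itself.
    """
    genes = expr.gene_names
    regulators = list(regulators) if regulators is not None else list(genes)
    targets = list(targets) if targets is not None else list(genes)
    for g in set(regulators) | set(targets):
        if g not in genes:
            raise KeyError(f"gene not in universe: {g}")
    reg_idx = genes.get_indexer(regulators)
    x_all = expr.values
    rows = []
    for t_name in targets:
        ti = genes.get_loc(t_name)
        y = x_all[:, ti]
        sd = y.std()
        if sd == 0:
            warnings.warn(f"target {t_name} has zero variance; skipped")
            continue
        y = y / sd
        use = [i for i, g in zip(reg_idx, regulators) if g != t_name]
        use_names = [g for g in regulators if g != t_name]
        if not use:
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=derive_seed(seed, f"rf_{t_name}") % (2**32),
        )
        rf.fit(x_all[:, use], y)
        for g, imp in zip(use_names, rf.feature_importances_):
            rows.append((g, t_name, float(imp)))
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return links.sort_values(
        ["importance", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def build_marker_network(
    links: pd.DataFrame, markers: Sequence[str], top_links: int = 300
) -> nx.DiGraph:
    """Top links among genes predicted to regulate or be regulated by the
    markers; ties at the truncation boundary resolved by (regulator,
    target) lexicographic order."""
    markers = set(markers)
    sub = links[
        links["regulator"].isin(markers) | links["target"].isin(markers)
    ].copy()
    sub = sub.sort_values(
        ["importance", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    if len(sub) < top_links:
        warnings.warn(
            f"only {len(sub)} qualifying links (< top_links={top_links})"
        )
    sub = sub.head(top_links)
    g = nx.DiGraph()
    for reg, tgt, imp in sub.itertuples(index=False):
        g.add_edge(reg, tgt, importance=imp)
    return g


def gene_centric_network(
    links: pd.DataFrame, gene: str, top_k: int = 20
) -> nx.DiGraph:
    """Two-ring neighborhood of ``gene``: its top_k partners by importance
    (as regulator or target), then each partner's top_k partners; edges are
    all links among the included nodes."""
    present = set(links["regulator"]) | set(links["target"])
    if gene not in present:
        raise KeyError(f"gene not in link list: {gene}")

    def partners(g: str) -> List[str]:
        if top_k <= 0:
            return []
        m = links[(links["regulator"] == g) | (links["target"] == g)]
        m = m.sort_values(
            ["importance", "regulator", "target"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        out: List[str] = []
        for reg, tgt, _ in m.itertuples(index=False):
            other = tgt if reg == g else reg
            if other not in out and other != g:
                out.append(other)
            if len(out) >= top_k:
                break
        return out

    ring1 = partners(gene)
    if len(ring1) < top_k:
        warnings.warn(f"{gene} has only {len(ring1)} partners (< {top_k})")
    nodes = {gene, *ring1}
    for g1 in ring1:
        nodes.update(partners(g1))
    net = nx.DiGraph()
    net.add_node(gene)
    net.add_nodes_from(nodes)
    sub = links[links["regulator"].isin(nodes) & links["target"].isin(nodes)]
    for reg, tgt, imp in sub.itertuples(index=False):
        net.add_edge(reg, tgt, importance=imp)
    return net


def network_metrics(net: nx.Graph) -> Tuple[List[int], float]:
    """Component sizes (descending) and mean local clustering coefficient.

    Metrics are computed on the undirected simple graph (directions and
    self-loops ignored); nodes with degree < 2 contribute 0 to the mean.
    An empty network returns ([], 0.0).
    """
    u = nx.Graph(net)
    u.remove_edges_from(nx.selfloop_edges(u))
    if u.number_of_nodes() == 0:
        warnings.warn("empty network; clustering coefficient undefined, using 0")
        return [], 0.0
    sizes = sorted((len(c) for c in nx.connected_components(u)), reverse=True)
    return sizes, float(nx.average_clustering(u))


def global_transitivity(net: nx.Graph) -> float:
    """Alternative global clustering coefficient (triangle transitivity)."""
    u = nx.Graph(net)
    u.remove_edges_from(nx.selfloop_edges(u))
    return float(nx.transitivity(u)) if u.number_of_nodes() else 0.0
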