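"""Rank-based gene-set activity scoring and composite lineage selection.

Per cell, genes are ranked by descending expression and a recovery curve
R(k) = |set intersect top-k| is accumulated up to a rank threshold
T = ceil(top_frac * n_genes); the score is the area under that curve
normalized by the maximum attainable area, so scores lie in [0, 1].
Composite dorsal - ventral scores are min-max normalized, and the top and
bottom quartiles of their difference define the High-Score dorsal and
ventral lineages. A binomial over-representation test scores gene-set
enrichment of a query list against a background universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix
from .simulate import derive_seed


@dataclass
class GeneSet:
    name: str
    genes: List[str]


def auc_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Area-under-recovery-curve activity of ``gene_set`` per cell.

    Ties in a cell's expression ranking are broken by one global seeded
    random permutation of the gene universe, so identical profiles receive
    identical scores.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    genes = expr.gene_names
    members = [g for g in gene_set if g in genes]
    if not members:
        raise ValueError("gene set does not intersect the expression universe")
    n_genes = len(genes)
    t = math.ceil(top_frac * n_genes)
    in_set = np.asarray(genes.isin(members))
    rng = np.random.default_rng(derive_seed(seed, "auc_tiebreak"))
    tiebreak = rng.permutation(n_genes)

    n_set = in_set.sum()
    max_area = sum(min(k, n_set) for k in range(1, t + 1))
    aucs = np.empty(expr.n_cells)
    for i in range(expr.n_cells):
        x = expr.values[i]
        order = np.lexsort((tiebreak, -x))  # descending expr, seeded tiebreak
        hits = in_set[order[:t]]
        r = np.cumsum(hits)
        aucs[i] = r.sum() / max_area
    return pd.DataFrame(
        {"auc": aucs, "threshold_rank": t}, index=expr.cell_ids
    )


def minmax_normalize(scores: Sequence[float]) -> np.ndarray:
    """(x - min)/(max - min); an all-equal vector maps to all zeros."""
    x = np.asarray(scores, float)
    if x.size == 0:
        raise ValueError("empty score vector")
    rng = np.ptp(x)
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def high_score_selection(
    dorsal: Sequence[float], ventral: Sequence[float]
) -> np.ndarray:
    """Quartile High-Score labels from normalized dorsal/ventral scores.

    d = dorsal - ventral; HighDorsal = cells with d >= Q3, HighVentral =
    cells with d <= Q1 (linear-interpolation quartiles, boundary ties
    included). Zero-range input yields 'neither' for every cell, and a cell
    qualifying for both sides (only possible when Q1 == Q3) is 'neither'.
    """
    d = np.asarray(dorsal, float) - np.asarray(ventral, float)
    if d.size < 4:
        raise ValueError("need at least 4 cells for quartile selection")
    if np.ptp(d) == 0:
        return np.full(d.size, "neither", dtype=object)
    q1, q3 = np.percentile(d, [25.0, 75.0])
    hi = d >= q3
    lo = d <= q1
    out = np.full(d.size, "neither", dtype=object)
    out[hi & ~lo] = "HighDorsal"
    out[lo & ~hi] = "HighVentral"
    return out


def lineage_signature(
    markers_b: Sequence[str], markers_a: Sequence[str]
) -> List[str]:
    """Genes enriched in both the B-cell and A-cell ends of one regional
    lineage: the intersection, in markers_b order."""
    a = set(markers_a)
    return [g for g in markers_b if g in a]


def ora_enrichment(
    query: Sequence[str],
    sets: Sequence[GeneSet],
    background: Sequence[str],
    fdr: float = 0.05,
    test: str = "binomial",
) -> pd.DataFrame:
    """One-sided over-representation of ``query`` in each gene set.

    Binomial by default: P(X >= k), X ~ Binomial(|query|, |set|/|background|)
    with k observed hits; ``test='hypergeometric'`` uses the exact urn model.
    BH across sets; ``significant`` = adjusted p < fdr.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = [g for g in query if g in bg]
    if set(query) - bg:
        raise ValueError("query must be a subset of the background")
    rows = []
    for gs in sets:
        members = set(gs.genes) & bg
        k = len(set(q) & members)
        frac = len(members) / len(bg)
        if test == "binomial":
            p = float(binom.sf(k - 1, len(q), frac)) if len(q) else 1.0
        elif test == "hypergeometric":
            p = float(hypergeom.sf(k - 1, len(bg), len(members), len(q)))
        else:
            raise ValueError(f"unknown test: {test}")
        rows.append(
            {"set": gs.name, "n_set": len(members), "n_hits": k, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    out["significant"] = out["p_adj"] < fdr
    return out.sort_values("p_adj", kind="mergesort").reset_index(drop=True)
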