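"""Differential expression between cell groups and the candidate-marker filter.

Per-gene two-group testing uses the Wilcoxon rank-sum test (exact for small
untied samples, normal approximation with tie and continuity correction
otherwise) with Benjamini-Hochberg adjustment across genes. Candidate
markers are the significantly upregulated genes expressed in no more than
40% of cells of the other cluster.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix
from .types import CountMatrix

LOGFC_EPS = 1e-9

DE_COLUMNS = ["gene", "log_fc", "p", "p_adj", "pct_1", "pct_2", "mean_1", "mean_2"]


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    n = a.size + b.size
    has_ties = len(np.unique(np.concatenate([a, b]))) < n
    method = "exact" if (n <= 25 and not has_ties) else "asymptotic"
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_de(
    expr: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
) -> pd.DataFrame:
    """Two-group DE table sorted by ascending p_adj then descending |log_fc|.

    log_fc = log((m1+eps)/(m2+eps)) on group means of expm1-transformed
    normalized expression; pct_1/pct_2 are fractions of cells with
    normalized expression > 0 (equivalently raw count > 0).
    """
    g1 = set(group1)
    g2 = set(group2)
    if g1 & g2:
        raise ValueError("groups overlap")
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs at least 3 cells")
    i1 = expr.cell_ids.get_indexer(list(group1))
    i2 = expr.cell_ids.get_indexer(list(group2))
    if (i1 < 0).any() or (i2 < 0).any():
        raise KeyError("group contains unknown cell ids")
    x1 = expr.values[i1]
    x2 = expr.values[i2]
    e1 = np.expm1(x1)
    e2 = np.expm1(x2)
    mean_1 = e1.mean(axis=0)
    mean_2 = e2.mean(axis=0)
    log_fc = np.log((mean_1 + LOGFC_EPS) / (mean_2 + LOGFC_EPS))
    pct_1 = (x1 > 0).mean(axis=0)
    pct_2 = (x2 > 0).mean(axis=0)
    pvals = np.array(
        [_wilcoxon_p(x1[:, j], x2[:, j]) for j in range(expr.values.shape[1])]
    )
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    de = pd.DataFrame(
        {
            "gene": expr.gene_names,
            "log_fc": log_fc,
            "p": pvals,
            "p_adj": p_adj,
            "pct_1": pct_1,
            "pct_2": pct_2,
            "mean_1": np.log1p(mean_1),
            "mean_2": np.log1p(mean_2),
        }
    )
    de = de.sort_values(
        ["p_adj", "log_fc"],
        ascending=[True, False],
        key=lambda s: s.abs() if s.name == "log_fc" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return de[DE_COLUMNS]


def find_all_markers(
    expr: ExpressionMatrix, labels: Sequence
) -> Dict[object, pd.DataFrame]:
    """One-vs-rest DE per cluster; only upregulated (log_fc > 0) genes kept."""
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    out: Dict[object, pd.DataFrame] = {}
    ids = np.asarray(expr.cell_ids)
    for c in uniq:
        inside = ids[labels == c]
        outside = ids[labels != c]
        if len(inside) < 3:
            warnings.warn(f"cluster {c} has fewer than 3 cells; skipped")
            continue
        de = wilcoxon_de(expr, inside, outside)
        out[c] = de[de["log_fc"] > 0].reset_index(drop=True)
    return out


def candidate_markers(
    de: pd.DataFrame, alpha: float = 0.05, max_other_frac: float = 0.40
) -> List[str]:
    """Significantly upregulated genes expressed in at most ``max_other_frac``
    of the other cluster's cells; order preserved from the DE table."""
    keep = (de["p_adj"] < alpha) & (de["log_fc"] > 0) & (de["pct_2"] <= max_other_frac)
    return de.loc[keep, "gene"].tolist()


def merge_clusters(labels: Sequence, to_merge: Iterable, new_name) -> np.ndarray:
    """Relabel every cell of the merged clusters; all other labels unchanged."""
    labels = np.asarray(labels, dtype=object)
    to_merge = set(to_merge)
    present = set(labels)
    unknown = to_merge - present
    if unknown:
        raise KeyError(f"unknown clusters: {sorted(map(str, unknown))}")
    out = labels.copy()
    out[np.isin(labels, list(to_merge))] = new_name
    return out


def top_n_markers(de: pd.DataFrame, n: int = 10) -> List[str]:
    """First n genes of a DE table (already sorted per its invariant)."""
    if n > len(de):
        warnings.warn(f"requested {n} markers but table has {len(de)} rows")
    return de["gene"].head(n).tolist()


def expression_fractions(
    counts: CountMatrix, labels: Sequence, gene: str
) -> Dict[object, float]:
    """Per-cluster fraction of cells with raw count > 0 for ``gene``."""
    if gene not in counts.gene_names:
        raise KeyError(f"unknown gene: {gene}")
    j = counts.gene_names.get_loc(gene)
    expressed = np.asarray((counts.counts[:, j] > 0).todense()).ravel()
    labels = np.asarray(labels)
    return {
        c: float(expressed[labels == c].mean()) for c in pd.unique(labels)
    }
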