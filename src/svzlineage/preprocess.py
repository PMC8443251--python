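"""Normalization, embedding, clustering and cell-cycle phase assignment.

Counts are depth-normalized to ``log(1 + scale * count / total)`` (natural
log); antibody-capture tags use centered log-ratio (CLR) normalization.
Embedding is PCA on gene-standardized expression with a fixed sign
convention; clustering is Leiden community detection on a nearest-neighbor
graph at the study's five resolutions (0.5, 0.8, 1.0, 1.5, 2.0).
Cell-cycle phases come from S and G2M module scores against
expression-matched control genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import derive_seed
from .types import CountMatrix

RESOLUTIONS = (0.5, 0.8, 1.0, 1.5, 2.0)


@dataclass
class ExpressionMatrix:
    """Cells x genes normalized expression with provenance metadata."""

    values: np.ndarray
    cell_ids: pd.Index
    gene_names: pd.Index
    method: str = "lognorm"
    scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_names = pd.Index(self.gene_names)
        if self.values.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValueError("values shape does not match metadata")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def subset_cells(self, keep) -> "ExpressionMatrix":
        idx = CountMatrix._resolve(keep, self.cell_ids)
        return ExpressionMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_names,
            self.method, self.scale, self.pseudocount,
        )

    def subset_genes(self, keep) -> "ExpressionMatrix":
        idx = CountMatrix._resolve(keep, self.gene_names)
        return ExpressionMatrix(
            self.values[:, idx], self.cell_ids, self.gene_names[idx],
            self.method, self.scale, self.pseudocount,
        )


@dataclass
class Embedding:
    coords: np.ndarray  # cells x k
    cell_ids: pd.Index
    variance_explained: np.ndarray  # fraction per component, decreasing
    loadings: Optional[np.ndarray] = None  # genes x k

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def normalize(
    counts: CountMatrix, scale: float = 1e4, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log(pseudocount + scale * count / cell_total), natural log."""
    totals = counts.total_counts().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; run QC first")
    dense = np.asarray(counts.counts.todense(), float)
    vals = np.log(pseudocount + scale * dense / totals[:, None])
    return ExpressionMatrix(
        vals, counts.cell_ids, counts.gene_names, "lognorm", scale, pseudocount
    )


def clr_normalize(tag_counts: np.ndarray) -> np.ndarray:
    """Centered log-ratio per cell: log1p(x_i) - mean_j log1p(x_j)."""
    x = np.log1p(np.asarray(tag_counts, float))
    return x - x.mean(axis=1, keepdims=True)


def highly_variable_genes(expr: ExpressionMatrix, n_top: int = 2000) -> np.ndarray:
    """Boolean mask of the top-n genes by standardized dispersion.

    Dispersion = var/mean of the back-transformed expression, z-scored
    within 20 mean-expression bins (scanpy's 'seurat' flavor in spirit).
    """
    x = np.expm1(expr.values)
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp})
    df["bin"] = pd.cut(df["mean"], bins=20, labels=False, duplicates="drop")
    z = df.groupby("bin")["disp"].transform(
        lambda s: (s - s.mean()) / (s.std(ddof=1) if s.std(ddof=1) > 0 else 1.0)
    )
    z = z.fillna(0.0).to_numpy()
    n_top = min(n_top, len(z))
    cutoff = np.sort(z)[::-1][n_top - 1]
    mask = z >= cutoff
    # break ties at the cutoff deterministically by gene order
    if mask.sum() > n_top:
        extra = np.flatnonzero(mask & (z == cutoff))
        drop = extra[n_top - mask.sum():] if n_top < mask.sum() else []
        mask[drop] = False
    return mask


def _fix_signs(u: np.ndarray, loadings: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sign convention: largest-magnitude loading of each component positive."""
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    return u, loadings


def embed(expr: ExpressionMatrix, n_components: int = 50) -> Embedding:
    """PCA of gene-standardized expression, deterministic up to fixed sign."""
    x = expr.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    rank = min(z.shape)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating"
        )
        n_components = rank
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T.copy()
    coords, loadings = _fix_signs(coords, loadings)
    total_var = (s**2).sum()
    var_exp = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return Embedding(coords, expr.cell_ids, var_exp, loadings)


def cluster(
    emb: Embedding,
    resolution: float = 1.5,
    k_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a k-nearest-neighbor graph.

    Returns integer labels 0..K-1 ordered by decreasing cluster size.
    """
    n = emb.coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb.coords)
    _, ind = nn.kneighbors(emb.coords)
    neigh = [set(row) for row in ind]  # includes self
    edges = sorted({(min(i, j), max(i, j)) for i in range(n) for j in ind[i, 1:]})
    # shared-nearest-neighbor weights: Jaccard overlap of neighbor sets
    weights = [
        len(neigh[i] & neigh[j]) / len(neigh[i] | neigh[j]) for i, j in edges
    ]
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        weights=weights,
        seed=derive_seed(seed, f"leiden_{resolution}"),
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size, ties by first occurrence
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


# ----------------------------------------------------------------------
# cell-cycle scoring


def _module_score(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    rng: np.random.Generator,
    n_bins: int,
    n_ctrl: int,
) -> np.ndarray:
    universe = expr.gene_names
    present = [g for g in genes if g in universe]
    if not present:
        raise ValueError("gene set does not intersect the expression universe")
    mean_expr = expr.values.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    # equal-count expression bins over the gene universe
    bins = np.empty(len(universe), int)
    bins[order] = np.minimum(
        (np.arange(len(universe)) * n_bins) // len(universe), n_bins - 1
    )
    prog_idx = universe.get_indexer(present)
    in_prog = np.zeros(len(universe), bool)
    in_prog[prog_idx] = True
    ctrl_idx: list = []
    for gi in prog_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_prog)
        if pool.size == 0:  # bin holds only program genes
            pool = np.flatnonzero(~in_prog)
        take = min(n_ctrl, pool.size)
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(np.concatenate(ctrl_idx))
    return expr.values[:, prog_idx].mean(axis=1) - expr.values[:, ctrl_idx].mean(axis=1)


def cell_cycle_score(
    expr: ExpressionMatrix,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """S/G2M module scores and phase call per cell.

    score = mean(program genes) - mean(control genes matched per program
    gene from its expression-level bin). Phase = G1 when both scores <= 0,
    otherwise argmax; the tie s_score == g2m_score > 0 resolves to S.
    """
    rng = np.random.default_rng(derive_seed(seed, "cycle"))
    s_score = _module_score(expr, s_genes, rng, n_bins, n_ctrl)
    g2m_score = _module_score(expr, g2m_genes, rng, n_bins, n_ctrl)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=expr.cell_ids,
    )


def phase_fraction_summary(phases: Iterable[str], phase: str = "S") -> str:
    """Truncated one-decimal percentage of cells in ``phase``, e.g. '69.6%'."""
    from .qc import truncated_percent

    phases = list(phases)
    return truncated_percent(sum(p == phase for p in phases), len(phases))
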