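"""Balanced-reference, anchor-based transfer of regional dissection labels.

A region-balanced reference is drawn from the middle 50% of cells by gene
count (per region), a shared low-dimensional embedding links reference and
query (diagonalized cross-covariance, i.e. CCA via SVD of the standardized
ref x query product, or reference-PCA projection), anchors are mutual
nearest neighbor pairs scored by neighborhood overlap, and each query cell
receives per-class predicted-identity scores (summing to 1) from a
Gaussian-weighted vote over its nearest anchors, plus a net
dorsal - ventral score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .preprocess import ExpressionMatrix, _fix_signs
from .simulate import derive_seed


@dataclass
class TransferConfig:
    n_dims: int = 30
    k_anchor: int = 5
    k_weight: int = 50
    k_filter: int = 200
    nfeature_low_pct: float = 25.0
    nfeature_high_pct: float = 75.0
    min_anchor_score: float = 0.1
    method: str = "cca"  # or "pcaproject"
    seed: int = 0

    def __post_init__(self):
        if self.k_anchor > self.k_filter:
            raise ValueError("k_anchor must be <= k_filter")
        if not (0 <= self.nfeature_low_pct < self.nfeature_high_pct <= 100):
            raise ValueError("nfeature percentile bounds must be ordered")


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor (reference cell, query cell) pairs."""

    ref_index: np.ndarray  # positional, into reference cells
    query_index: np.ndarray
    score: np.ndarray  # in [0, 1]
    ref_coords: np.ndarray  # shared-embedding coordinates of reference cells
    query_coords: np.ndarray

    def __len__(self) -> int:
        return len(self.ref_index)


def downsample_reference(
    ref_cells: Sequence[str],
    region_labels: Sequence[str],
    genes_per_cell: Sequence[float],
    config: TransferConfig = TransferConfig(),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Region-balanced reference cell ids.

    Within each region, candidates are restricted to the inclusive
    [P25, P75] genes-per-cell band (percentiles computed per region); the
    minimum candidate count over regions is sampled uniformly without
    replacement from each region.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(seed, "downsample"))
    cells = np.asarray(ref_cells)
    regions = np.asarray(region_labels)
    nfeat = np.asarray(genes_per_cell, float)
    uniq = pd.unique(regions)
    if len(uniq) < 2:
        raise ValueError("need at least 2 regions")
    candidates: Dict[str, np.ndarray] = {}
    for r in uniq:
        m = regions == r
        lo, hi = np.percentile(
            nfeat[m], [config.nfeature_low_pct, config.nfeature_high_pct]
        )
        cand = cells[m & (nfeat >= lo) & (nfeat <= hi)]
        if cand.size == 0:
            raise ValueError(f"region {r} has no candidate cells in the band")
        candidates[r] = cand
    n = min(len(v) for v in candidates.values())
    chosen = [rng.choice(candidates[r], size=n, replace=False) for r in uniq]
    return np.concatenate(chosen)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def build_shared_embedding(
    ref_expr: ExpressionMatrix,
    query_expr: ExpressionMatrix,
    config: TransferConfig = TransferConfig(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Joint embedding of reference and query cells.

    Default is CCA: SVD of Zr @ Zq.T over the shared genes (per-dataset
    gene standardization); left/right singular vectors give paired
    coordinates, L2-normalized per cell. ``method='pcaproject'`` instead
    projects the query onto the reference PCA basis.
    Deterministic up to sign; sign fixed as in PCA embedding.
    """
    shared = ref_expr.gene_names.intersection(query_expr.gene_names)
    if len(shared) < config.n_dims:
        raise ValueError(
            f"only {len(shared)} shared genes for n_dims={config.n_dims}"
        )
    zr = _standardize(ref_expr.subset_genes(shared).values)
    zq = _standardize(query_expr.subset_genes(shared).values)
    d = config.n_dims
    if config.method == "cca":
        m = zr @ zq.T
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        # coordinates weighted by sqrt of singular value, so each canonical
        # dimension contributes in proportion to its cross-covariance
        w = np.sqrt(s[:d])
        ref_c = u[:, :d] * w
        qry_c = vt[:d].T * w
        # common sign convention keyed on the reference side
        ref_c, flip_ref = _signfix_pair(ref_c)
        qry_c *= flip_ref
    elif config.method == "pcaproject":
        mu = zr.mean(axis=0)
        u, s, vt = np.linalg.svd(zr - mu, full_matrices=False)
        load = vt[:d].T.copy()
        ref_c = (zr - mu) @ load
        ref_c, load = _fix_signs(ref_c, load)
        qry_c = (zq - mu) @ load
    else:
        raise ValueError(f"unknown method: {config.method}")
    ref_c = _l2(ref_c)
    qry_c = _l2(qry_c)
    return ref_c, qry_c


def _signfix_pair(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    flip = np.ones(coords.shape[1])
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            flip[j] = -1.0
    return coords * flip, flip


def _l2(x: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return x / norm


def find_anchors(
    ref_coords: np.ndarray,
    query_coords: np.ndarray,
    config: TransferConfig = TransferConfig(),
) -> AnchorSet:
    """Mutual nearest neighbors across datasets, scored by the Jaccard
    overlap of the pair's k_filter joint neighborhoods (min-max rescaled
    to [0, 1]; anchors scoring below ``min_anchor_score`` are dropped)."""
    ka = min(config.k_anchor, len(ref_coords), len(query_coords))
    nn_r = NearestNeighbors(n_neighbors=ka).fit(ref_coords)
    nn_q = NearestNeighbors(n_neighbors=ka).fit(query_coords)
    _, q_of_r = nn_q.kneighbors(ref_coords)  # for each ref, nearest queries
    _, r_of_q = nn_r.kneighbors(query_coords)
    pairs = []
    qsets = [set(row) for row in q_of_r]
    for qi, row in enumerate(r_of_q):
        for ri in row:
            if qi in qsets[ri]:
                pairs.append((ri, qi))
    if not pairs:
        raise ValueError("no mutual nearest neighbor pairs; raise k_anchor")
    ref_idx = np.array([p[0] for p in pairs])
    qry_idx = np.array([p[1] for p in pairs])

    # joint neighborhoods in the combined embedding
    joint = np.vstack([ref_coords, query_coords])
    kf = min(config.k_filter, len(joint) - 1)
    nn_j = NearestNeighbors(n_neighbors=kf + 1).fit(joint)
    _, jn = nn_j.kneighbors(joint)
    nbh = [set(row[1:]) for row in jn]
    n_ref = len(ref_coords)
    raw = np.array(
        [
            len(nbh[ri] & nbh[n_ref + qi]) / len(nbh[ri] | nbh[n_ref + qi])
            for ri, qi in pairs
        ]
    )
    rng = np.ptp(raw)
    score = (raw - raw.min()) / rng if rng > 0 else np.ones_like(raw)
    keep = score >= config.min_anchor_score
    if not keep.any():
        keep = np.ones_like(keep)
    return AnchorSet(
        ref_index=ref_idx[keep],
        query_index=qry_idx[keep],
        score=score[keep],
        ref_coords=ref_coords,
        query_coords=query_coords,
    )


def transfer_labels(
    anchors: AnchorSet,
    ref_labels: Sequence[str],
    config: TransferConfig = TransferConfig(),
    query_ids: Optional[Sequence[str]] = None,
    classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-query-cell predicted-identity scores over reference classes.

    Each query cell is scored by a Gaussian-kernel weighted vote over its
    k_weight nearest anchors (kernel bandwidth = distance to the
    k_weight-th anchor, weights scaled by anchor score and normalized to
    sum 1); ``net_score`` = score(dorsal) - score(ventral) when both
    classes are present. Query cells with no informative anchors receive
    uniform scores and ``flagged=True``.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    ref_labels = np.asarray(ref_labels)
    anchor_labels = ref_labels[anchors.ref_index]
    if classes is None:
        classes = sorted(pd.unique(ref_labels))
    onehot = np.stack([(anchor_labels == c).astype(float) for c in classes], axis=1)

    n_query = anchors.query_coords.shape[0]
    anchor_pos = anchors.query_coords[anchors.query_index]
    kw = min(config.k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=kw).fit(anchor_pos)
    dist, ind = nn.kneighbors(anchors.query_coords)
    bandwidth = dist[:, -1].copy()
    bandwidth[bandwidth == 0] = 1.0
    w = np.exp(-0.5 * (dist / bandwidth[:, None]) ** 2)
    w *= anchors.score[ind]
    flagged = w.sum(axis=1) <= 0
    w[flagged] = 1.0
    w /= w.sum(axis=1, keepdims=True)

    scores = np.einsum("qk,qkc->qc", w, onehot[ind])
    scores /= scores.sum(axis=1, keepdims=True)
    out = pd.DataFrame(scores, columns=[f"score_{c}" for c in classes])
    if query_ids is not None:
        out.index = pd.Index(query_ids)
    lc = [c.lower() for c in classes]
    if "dorsal" in lc and "ventral" in lc:
        d = scores[:, lc.index("dorsal")]
        v = scores[:, lc.index("ventral")]
        out["net_score"] = d - v
    out["predicted_class"] = _argmax_class(scores, list(classes))
    out["flagged"] = flagged
    return out


def _argmax_class(scores: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Argmax with ties broken toward 'dorsal' (case-insensitive) then
    lexicographic class order."""
    lc = [c.lower() for c in classes]
    pref = sorted(
        range(len(classes)), key=lambda i: (lc[i] != "dorsal", classes[i])
    )
    best = np.empty(scores.shape[0], dtype=object)
    maxv = scores.max(axis=1)
    for i in range(scores.shape[0]):
        for j in pref:
            if scores[i, j] >= maxv[i] - 1e-12:
                best[i] = classes[j]
                break
    return best


def predicted_class_counts(pred: pd.DataFrame) -> Dict[str, int]:
    """Tally of argmax predicted classes."""
    return pred["predicted_class"].value_counts().to_dict()


def transfer_pipeline(
    ref_expr: ExpressionMatrix,
    ref_labels: Sequence[str],
    query_expr: ExpressionMatrix,
    config: TransferConfig = TransferConfig(),
) -> pd.DataFrame:
    """Shared embedding -> anchors -> label transfer, end to end."""
    ref_c, qry_c = build_shared_embedding(ref_expr, query_expr, config)
    anchors = find_anchors(ref_c, qry_c, config)
    return transfer_labels(
        anchors, ref_labels, config, query_ids=query_expr.cell_ids
    )
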