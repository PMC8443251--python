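"""Cell-level quality filtering and sample demultiplexing.

Cells are retained when their UMI total lies inside the inclusive
[P5, P95] band, their gene count is at or above P5, and their
mitochondrial-read fraction is at most 10% (all thresholds configurable).
Percentiles use linear interpolation on the *input* population, so QC is
population-relative: re-running on already-filtered output can remove more
cells. High-UMI doublets fall under the upper UMI percentile rule.

Demultiplexing assigns each cell to the sample barcodes whose log1p count
exceeds a per-barcode threshold: one barcode -> singlet, two or more ->
doublet, none -> negative.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .types import BarcodeMatrix, CountMatrix


def truncated_percent(k: int, n: int) -> str:
    """Percentage truncated (not rounded) to one decimal, e.g. 4128/35025 -> '11.7%'."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    value = math.floor(1000.0 * k / n) / 10.0
    return f"{value:.1f}%"


@dataclass
class QcThresholds:
    umi_low_pct: float = 5.0
    umi_high_pct: float = 95.0
    genes_low_pct: float = 5.0
    mito_max_frac: float = 0.10

    def __post_init__(self):
        if not (0 <= self.umi_low_pct < self.umi_high_pct <= 100):
            raise ValueError("require 0 <= umi_low_pct < umi_high_pct <= 100")
        if not (0 < self.mito_max_frac <= 1):
            raise ValueError("mito_max_frac must lie in (0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_removed_by_rule: Dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    doublet_count: int = 0

    @property
    def doublet_percent(self) -> str:
        return truncated_percent(self.doublet_count, self.n_input)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_by_rule": dict(self.n_removed_by_rule),
            "n_retained": self.n_retained,
            "doublet_count": self.doublet_count,
            "doublet_percent": self.doublet_percent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def qc_filter(
    counts: CountMatrix,
    thresholds: QcThresholds = QcThresholds(),
    mito_gene_set: Iterable[str] = (),
) -> Tuple[CountMatrix, QcReport]:
    """Filter cells by UMI band, gene-count floor and mito fraction.

    A cell failing several rules is attributed to the first failing rule in
    the fixed order UMI, genes, mito, so reports are deterministic.
    """
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    umi = counts.total_counts()
    ngenes = counts.genes_per_cell()
    lo, hi = np.percentile(umi, [thresholds.umi_low_pct, thresholds.umi_high_pct])
    g_lo = np.percentile(ngenes, thresholds.genes_low_pct)

    fail_umi = (umi < lo) | (umi > hi)
    fail_genes = ngenes < g_lo

    mito_genes = [g for g in mito_gene_set if g in counts.gene_names]
    if mito_genes:
        mito_frac = counts.fraction_counts(mito_genes)
        fail_mito = mito_frac > thresholds.mito_max_frac
    else:
        if list(mito_gene_set):
            warnings.warn("mito gene set does not intersect universe; rule skipped")
        else:
            warnings.warn("empty mito gene set; mito rule skipped")
        fail_mito = np.zeros(counts.n_cells, bool)

    removed_by = {
        "umi": int(fail_umi.sum()),
        "genes": int((fail_genes & ~fail_umi).sum()),
        "mito": int((fail_mito & ~fail_umi & ~fail_genes).sum()),
    }
    keep = ~(fail_umi | fail_genes | fail_mito)
    report = QcReport(
        n_input=counts.n_cells,
        n_removed_by_rule=removed_by,
        n_retained=int(keep.sum()),
    )
    return counts.subset_cells(keep), report


# ----------------------------------------------------------------------
# barcode classification


def _barcode_threshold(log_counts: np.ndarray) -> float:
    """Split one barcode's log1p counts between its two highest density modes.

    Threshold = minimum-density point between the two tallest KDE modes;
    falls back to the 75th percentile when the density is unimodal or the
    column is degenerate.
    """
    fallback = float(np.percentile(log_counts, 75.0))
    if np.ptp(log_counts) < 1e-12:
        return fallback
    try:
        kde = gaussian_kde(log_counts)
    except np.linalg.LinAlgError:
        return fallback
    grid = np.linspace(log_counts.min(), log_counts.max(), 512)
    dens = kde(grid)
    maxima = argrelmax(dens)[0]
    # boundary points can be modes too
    if dens[0] > dens[1]:
        maxima = np.concatenate([[0], maxima])
    if dens[-1] > dens[-2]:
        maxima = np.concatenate([maxima, [len(grid) - 1]])
    if len(maxima) < 2:
        return fallback
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    a, b = sorted(top2)
    between = dens[a : b + 1]
    return float(grid[a + int(np.argmin(between))])


def classify_barcodes(bc: BarcodeMatrix) -> pd.DataFrame:
    """Per-cell demultiplexing call.

    Returns a DataFrame indexed by cell id with columns ``call`` in
    {singlet, doublet, negative}, ``sample`` (the barcode name for
    singlets, '' otherwise) and ``n_positive``.
    """
    x = np.log1p(bc.dense().astype(float))
    n_cells, n_bc = x.shape
    positive = np.zeros((n_cells, n_bc), bool)
    for j in range(n_bc):
        col = x[:, j]
        if not np.any(col > 0):
            warnings.warn(f"barcode {bc.barcode_names[j]} is all-zero; no calls")
            continue
        positive[:, j] = col > _barcode_threshold(col)
    n_pos = positive.sum(axis=1)
    call = np.where(n_pos == 0, "negative", np.where(n_pos == 1, "singlet", "doublet"))
    sample = np.where(
        n_pos == 1,
        np.asarray(bc.barcode_names, dtype=object)[np.argmax(positive, axis=1)],
        "",
    )
    return pd.DataFrame(
        {"call": call, "sample": sample, "n_positive": n_pos}, index=bc.cell_ids
    )


def qc_summary(report: QcReport) -> str:
    """Human-readable summary; percentages truncated to one decimal."""
    lines = [
        f"cells in:      {report.n_input}",
        f"cells kept:    {report.n_retained}",
    ]
    for rule, n in report.n_removed_by_rule.items():
        lines.append(f"removed ({rule}): {n}")
    lines.append(
        f"doublets:      {report.doublet_count} of {report.n_input} "
        f"({report.doublet_percent})"
    )
    return "\n".join(lines)
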