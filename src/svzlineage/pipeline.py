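"""End-to-end orchestration of the analysis on synthetic data.

``run_all`` executes simulate -> QC/demux -> preprocess -> markers ->
regional transfer -> signature scoring -> GRN -> spatial quantification,
writing each stage's tables, the effective configuration, a structured log
and a manifest of output hashes into one artifact directory. A single
global seed fans out to per-stage seeds through
:func:`svzlineage.simulate.derive_seed`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import grn as grn_mod
from . import io as io_mod
from . import markers as mk
from . import preprocess as pp
from . import qc as qc_mod
from . import scoring as sc
from . import spatial as sq
from . import transfer as tr
from .simulate import (
    SimConfig,
    SpotConfig,
    derive_seed,
    simulate_barcode_counts,
    simulate_lineage_counts,
    simulate_nucleus_samples,
    simulate_spots,
    simulate_transfer_pair,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    sim: SimConfig = None
    spots: SpotConfig = None
    qc: qc_mod.QcThresholds = field(default_factory=qc_mod.QcThresholds)
    transfer: tr.TransferConfig = None
    n_pcs: int = 30
    resolution: float = 1.0
    k_neighbors: int = 15
    n_hvg: int = 1000
    de_alpha: float = 0.05
    max_other_frac: float = 0.40
    top_n_markers: int = 10
    auc_top_frac: float = 0.05
    grn_n_trees: int = 100
    grn_top_links: int = 300
    grn_top_k: int = 20
    spatial_bins: int = 50

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.spots is None:
            self.spots = SpotConfig(seed=self.seed)
        if self.transfer is None:
            self.transfer = tr.TransferConfig(seed=self.seed)

    def to_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {str(k): enc(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [enc(v) for v in x]
            return x

        return {k: enc(v) for k, v in dataclasses.asdict(self).items()}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage; returns a summary dict (also written as JSON)."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    log_path = os.path.join(out, "pipeline.log")
    log = open(log_path, "a")
    summary: Dict[str, object] = {"seed": config.seed}

    def stage(name, **info):
        rec = {"stage": name, "time": time.time(), **info}
        log.write(json.dumps(rec) + "\n")
        log.flush()

    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)

    # --- simulate -----------------------------------------------------
    ds = simulate_lineage_counts(config.sim)
    bc = simulate_barcode_counts(ds)
    ds.truth.to_csv(os.path.join(out, "truth.csv"))
    stage("simulate", n_cells=ds.counts.n_cells, n_genes=ds.counts.n_genes)

    # --- demux + QC ---------------------------------------------------
    calls = classify = qc_mod.classify_barcodes(bc)
    calls.to_csv(os.path.join(out, "demux_calls.csv"))
    singlet_ids = calls.index[calls["call"] == "singlet"]
    kept = ds.counts.subset_cells(singlet_ids)
    mito = ds.program_genes["mito"]
    filtered, report = qc_mod.qc_filter(kept, config.qc, mito)
    report.doublet_count = int((calls["call"] == "doublet").sum())
    report.n_input = ds.counts.n_cells
    with open(os.path.join(out, "qc_report.json"), "w") as fh:
        fh.write(report.to_json())
    summary["n_cells_simulated"] = ds.counts.n_cells
    summary["n_cells_retained"] = filtered.n_cells
    summary["doublet_percent"] = report.doublet_percent
    stage("qc_demux", retained=filtered.n_cells, doublets=report.doublet_count)

    # --- preprocess ---------------------------------------------------
    expr = pp.normalize(filtered)
    hvg = pp.highly_variable_genes(expr, config.n_hvg)
    emb = pp.embed(expr.subset_genes(hvg), config.n_pcs)
    labels = pp.cluster(
        emb, config.resolution, config.k_neighbors, seed=config.seed
    )
    cycle = pp.cell_cycle_score(
        expr,
        ds.program_genes["s_phase"],
        ds.program_genes["g2m_phase"],
        seed=config.seed,
    )
    obs = filtered.cell_meta.copy()
    obs["cluster"] = labels
    obs = obs.join(cycle, rsuffix="_called")
    obs.to_csv(os.path.join(out, "cells.csv"))
    summary["n_clusters"] = int(len(np.unique(labels)))
    truth_phase = ds.truth.loc[expr.cell_ids, "phase"]
    summary["phase_accuracy"] = float((cycle["phase"] == truth_phase).mean())
    stage("preprocess", n_clusters=summary["n_clusters"])

    # --- markers: dorsal vs ventral B cells ---------------------------
    truth = ds.truth.loc[expr.cell_ids]
    b_mask = truth["stage"].str.startswith("B").to_numpy()
    b_expr = expr.subset_cells(b_mask)
    b_truth = truth.loc[b_mask]
    d_cells = b_truth.index[b_truth["region"] == "dorsal"]
    v_cells = b_truth.index[b_truth["region"] == "ventral"]
    de_d = mk.wilcoxon_de(b_expr, d_cells, v_cells)
    de_v = mk.wilcoxon_de(b_expr, v_cells, d_cells)
    de_d.to_csv(os.path.join(out, "de_dorsal_vs_ventral_B.csv"), index=False)
    cand_d = mk.candidate_markers(de_d, config.de_alpha, config.max_other_frac)
    cand_v = mk.candidate_markers(de_v, config.de_alpha, config.max_other_frac)
    top_d = mk.top_n_markers(de_d[de_d["log_fc"] > 0], config.top_n_markers)
    top_v = mk.top_n_markers(de_v[de_v["log_fc"] > 0], config.top_n_markers)
    true_d = set(ds.program_genes["dorsal"])
    true_v = set(ds.program_genes["ventral"])
    summary["n_candidate_dorsal_markers"] = len(cand_d)
    summary["n_candidate_ventral_markers"] = len(cand_v)
    summary["dorsal_marker_precision"] = (
        float(np.mean([g in true_d for g in cand_d])) if cand_d else 0.0
    )
    summary["ventral_marker_precision"] = (
        float(np.mean([g in true_v for g in cand_v])) if cand_v else 0.0
    )
    stage("markers", dorsal=len(cand_d), ventral=len(cand_v))

    # --- regional label transfer --------------------------------------
    nuc = simulate_nucleus_samples(ds)
    ref_meta = pd.concat([cm.cell_meta for cm in nuc.values()])
    ref_counts = None
    from .types import CountMatrix
    import scipy.sparse as sp

    ref_counts = CountMatrix(
        sp.vstack([cm.counts for cm in nuc.values()]).tocsr(),
        ref_meta,
        ds.counts.gene_meta.copy(),
    )
    ref_b = ref_counts.subset_cells(
        ref_meta["stage"].str.startswith("B").to_numpy()
    )
    chosen = tr.downsample_reference(
        ref_b.cell_ids,
        ref_b.cell_meta["region"],
        ref_b.genes_per_cell(),
        config.transfer,
    )
    ref_bal = ref_b.subset_cells(chosen)
    ref_expr = pp.normalize(ref_bal)
    pred = tr.transfer_pipeline(
        ref_expr, ref_bal.cell_meta["region"], b_expr, config.transfer
    )
    pred.to_csv(os.path.join(out, "predicted_identity.csv"))
    truth_sign = np.where(b_truth["region"] == "dorsal", 1.0, -1.0)
    ok = np.sign(pred["net_score"].to_numpy()) == truth_sign
    summary["transfer_sign_accuracy"] = float(ok.mean())
    summary["predicted_class_counts"] = {
        str(k): int(v) for k, v in tr.predicted_class_counts(pred).items()
    }
    stage("transfer", accuracy=summary["transfer_sign_accuracy"])

    # --- signature scoring --------------------------------------------
    lineage_mask = truth["stage"].isin(
        ["B_quiescent", "B_active", "C", "A_dividing", "A_migrating"]
    ).to_numpy()
    lin_expr = expr.subset_cells(lineage_mask)
    sig_d = cand_d or ds.program_genes["dorsal"]
    sig_v = cand_v or ds.program_genes["ventral"]
    auc_d = sc.auc_score(lin_expr, sig_d, config.auc_top_frac, seed=config.seed)
    auc_v = sc.auc_score(lin_expr, sig_v, config.auc_top_frac, seed=config.seed)
    nd = sc.minmax_normalize(auc_d["auc"])
    nv = sc.minmax_normalize(auc_v["auc"])
    highs = sc.high_score_selection(nd, nv)
    scores = pd.DataFrame(
        {
            "auc_dorsal": auc_d["auc"],
            "auc_ventral": auc_v["auc"],
            "high_score": highs,
        },
        index=lin_expr.cell_ids,
    )
    scores.to_csv(os.path.join(out, "composite_scores.csv"))
    lin_truth = ds.truth.loc[lin_expr.cell_ids]
    hs_d = highs == "HighDorsal"
    summary["high_dorsal_purity"] = (
        float((lin_truth.loc[hs_d, "region"] == "dorsal").mean())
        if hs_d.any()
        else 0.0
    )
    # composite constancy along the lineage (dorsal cells, dorsal score)
    d_cells_mask = (lin_truth["region"] == "dorsal").to_numpy()
    comp = auc_d["auc"].to_numpy()[d_cells_mask]
    stages_d = lin_truth.loc[d_cells_mask, "stage"].to_numpy()
    coarse = np.array([s[0] for s in stages_d])  # B/C/A
    stage_means = [comp[coarse == s].mean() for s in "BCA" if (coarse == s).any()]
    grand = comp.mean()
    summary["composite_stage_variation"] = (
        float((max(stage_means) - min(stage_means)) / grand) if grand > 0 else 0.0
    )
    stage("scoring", variation=summary["composite_stage_variation"])

    # --- GRN ----------------------------------------------------------
    grn_genes = list(dict.fromkeys(top_d + top_v))[: config.grn_top_k]
    pool = grn_genes + [
        g for g in lin_expr.gene_names if g.startswith("Bg")
    ][:40]
    grn_expr = b_expr.subset_genes([g for g in pool if g in b_expr.gene_names])
    links = grn_mod.infer_links(
        grn_expr, n_trees=config.grn_n_trees, seed=config.seed
    )
    links.to_csv(os.path.join(out, "link_list.tsv"), sep="\t", index=False)
    net = grn_mod.build_marker_network(links, top_d, config.grn_top_links)
    sizes, cc = grn_mod.network_metrics(net)
    summary["dorsal_network_components"] = sizes[:5]
    summary["dorsal_clustering_coefficient"] = cc
    stage("grn", clustering_coefficient=cc)

    # --- spatial ------------------------------------------------------
    spots = simulate_spots(config.spots)
    axis = sq.AxisPolyline(config.spots.axis)
    spots = sq.normalize_positions(spots, axis)
    spots.to_csv(os.path.join(out, "spots.csv"), index=False)
    spatial_summary = {}
    for probe, grp in spots.groupby("probe"):
        _, _, med = sq.density_profile(grp["t"], config.spatial_bins)
        doms = sq.domain_assign(grp["t"])
        spatial_summary[probe] = {
            "median_t": med,
            "dorsal_fraction": float((doms == "dorsal").mean()),
        }
    summary["spatial"] = spatial_summary
    stage("spatial", probes=list(spatial_summary))

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    manifest = {
        f: _sha256(os.path.join(out, f))
        for f in sorted(os.listdir(out))
        if f not in {"manifest.json", "pipeline.log"}
        and os.path.isfile(os.path.join(out, f))
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.close()
    return summary
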