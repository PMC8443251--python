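"""Synthetic V-SVZ neurogenic-lineage data generator.

Emulates the statistical structure the downstream analysis assumes: a
B (quiescent/active) -> C -> A (dividing/migrating) lineage crossed with
persistent dorsal/ventral regional gene programs; negative-binomial counts
with cell-specific sequencing depth; a mitochondrial gene set; sample
barcoding with a doublet fraction carrying two barcodes; four
region-dissected "nucleus" samples (dorsal samples have fewer cells but
higher depth); and in situ spots positioned on a normalized [0,1]
ventral -> dorsal axis.

Every dataset carries a truth table so downstream recovery can be scored
without access to generator internals.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import BarcodeMatrix, CountMatrix

STAGES = ["B_quiescent", "B_active", "C", "A_dividing", "A_migrating"]
REGIONS = ["dorsal", "ventral"]

#: default per-stage cell-cycle phase probabilities (G1, S, G2M); the C and
#: dividing-A compartments cycle, quiescent B and migrating A are mostly G1.
DEFAULT_PHASE_PROBS: Dict[str, Tuple[float, float, float]] = {
    "B_quiescent": (1.0, 0.0, 0.0),
    "B_active": (0.8, 0.15, 0.05),
    "C": (0.1, 0.7, 0.2),
    "A_dividing": (0.2, 0.4, 0.4),
    "A_migrating": (1.0, 0.0, 0.0),
}


def derive_seed(seed: int, label: str) -> int:
    """Deterministically fan a global seed out to per-stage seeds.

    sha256 of ``"{seed}:{label}"`` reduced modulo 2**31.
    """
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    effect_size is the multiplicative fold-change of program genes in
    expressing cells (>= 1); nb_dispersion is the negative-binomial
    dispersion alpha with var = mu + alpha * mu**2; depth_lognormal gives
    (mean, sd) of log library size.
    """

    seed: int = 0
    n_genes: int = 2000
    stage_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "B_quiescent": 300,
            "B_active": 150,
            "C": 200,
            "A_dividing": 150,
            "A_migrating": 200,
        }
    )
    region_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"dorsal": 0.4, "ventral": 0.6}
    )
    n_stage_program_genes: int = 50
    n_region_program_genes: int = 50
    n_mito_genes: int = 13
    n_s_genes: int = 10
    n_g2m_genes: int = 10
    effect_size: float = 2.0
    phase_effect: float = 3.0
    nb_dispersion: float = 0.3
    depth_lognormal: Tuple[float, float] = (math.log(5000), 0.35)
    doublet_rate: float = 0.05
    n_barcodes: int = 4
    barcode_signal_to_noise: float = 50.0
    barcode_signal_mean: float = 500.0
    nucleus_region_depth_factor: Mapping[str, float] = field(
        default_factory=lambda: {"dorsal": 2.0, "ventral": 1.0}
    )
    nucleus_dorsal_cell_fraction: float = 0.5
    mito_baseline_fraction: float = 0.05
    phase_probs: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_PROBS)
    )

    def __post_init__(self):
        if abs(sum(self.region_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("region_fractions must sum to 1")
        if any(v < 0 for v in self.stage_sizes.values()):
            raise ConfigurationError("stage sizes must be >= 0")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ConfigurationError("doublet_rate must lie in [0, 1]")
        if self.effect_size < 1.0:
            raise ConfigurationError("effect_size must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.barcode_signal_to_noise <= 1:
            raise ConfigurationError("barcode_signal_to_noise must be > 1")
        n_program = (
            len(STAGES) * self.n_stage_program_genes
            + 2 * self.n_region_program_genes
            + self.n_mito_genes
            + self.n_s_genes
            + self.n_g2m_genes
        )
        if n_program > self.n_genes:
            raise ConfigurationError(
                f"program gene sets ({n_program}) exceed gene universe "
                f"({self.n_genes}); sets must be disjoint"
            )

    @property
    def n_cells(self) -> int:
        return int(sum(self.stage_sizes.values()))


@dataclass
class SimulatedDataset:
    """Counts plus ground truth for downstream recovery scoring."""

    counts: CountMatrix
    truth: pd.DataFrame
    program_genes: Dict[str, List[str]]
    #: per-cell expected gene proportions (rows sum to 1), retained so the
    #: nucleus samples can be re-drawn at a different depth
    rates: np.ndarray = None
    config: SimConfig = None


# ----------------------------------------------------------------------
# gene universe and programs


def _gene_universe(config: SimConfig) -> Tuple[pd.Index, Dict[str, List[str]]]:
    programs: Dict[str, List[str]] = {}
    names: List[str] = []
    cursor = 0

    def take(prefix: str, n: int) -> List[str]:
        nonlocal cursor
        block = [f"{prefix}{i:04d}" for i in range(cursor, cursor + n)]
        cursor += n
        names.extend(block)
        return block

    for stage in STAGES:
        programs[f"stage_{stage}"] = take(f"{stage[:4]}g", config.n_stage_program_genes)
    programs["dorsal"] = take("Dors", config.n_region_program_genes)
    programs["ventral"] = take("Vent", config.n_region_program_genes)
    programs["mito"] = [f"mt-G{i:03d}" for i in range(config.n_mito_genes)]
    names.extend(programs["mito"])
    cursor += config.n_mito_genes
    programs["s_phase"] = take("Sph", config.n_s_genes)
    programs["g2m_phase"] = take("G2m", config.n_g2m_genes)
    n_bg = config.n_genes - cursor
    names.extend(f"Bg{i:05d}" for i in range(n_bg))
    return pd.Index(names, name="gene"), programs


def _stage_shape_multipliers(
    n_genes: int,
    effect: float,
    rng: np.random.Generator,
    base_weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-gene multipliers over the 5 lineage stages for a regional program.

    Individual genes follow one of a few shapes along the lineage (constant,
    ramp up, ramp down, mid-peak) but each stage column is rescaled so the
    baseline-weighted composite program amplitude equals ``effect`` at every
    stage: the composite regional signal is constant along the lineage even
    though single genes are dynamic.
    """
    n_stages = len(STAGES)
    x = np.linspace(0.0, 1.0, n_stages)
    a = 0.3  # per-gene dynamic range; modest so the composite stays flat
    shapes = np.stack(
        [
            np.ones(n_stages),
            1.0 - a + 2 * a * x,  # ramp up
            1.0 + a - 2 * a * x,  # ramp down
            1.0 + a - 2 * a * np.abs(2 * x - 1.0),  # peak at C
        ]
    )
    which = rng.integers(0, shapes.shape[0], size=n_genes)
    raw = shapes[which]
    w = np.ones(n_genes) if base_weights is None else np.asarray(base_weights, float)
    w = w / w.sum()
    # rescale columns so sum_g w_g * raw_gs == 1 at every stage, making the
    # expected total program expression stage-constant
    raw = raw / (w @ raw)[None, :]
    return 1.0 + (effect - 1.0) * raw


# ----------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + alpha*mu^2 (gamma-Poisson)."""
    lam = np.where(
        mu > 0, rng.gamma(shape=1.0 / alpha, scale=np.maximum(mu, 1e-300) * alpha), 0.0
    )
    return rng.poisson(lam)


def simulate_lineage_counts(config: SimConfig) -> SimulatedDataset:
    """Draw the whole-cell lineage dataset.

    Each cell's expected expression is baseline x effect_size for genes in
    its stage program, its region program (stage-shaped, constant composite
    amplitude), and its phase program, rescaled to proportions and
    multiplied by a lognormal library size; counts are negative binomial.
    Doublets are sums of two randomly paired singlet profiles (and depths)
    before sampling, and carry two sample-barcode identities.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "lineage"))
    genes, programs = _gene_universe(config)
    n_genes = len(genes)

    # baseline relative expression; mitochondrial genes share a fixed
    # baseline fraction of total expression so QC mito fractions are realistic
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # program genes are detectable markers by construction, so their
    # baselines come from the upper half of the expression distribution
    # (folded normal in log space)
    prog_idx = genes.get_indexer(
        [g for k, v in programs.items() if k != "mito" for g in v]
    )
    base[prog_idx] = np.exp(np.abs(rng.normal(0.0, 1.0, size=prog_idx.size)))
    mito_idx = genes.get_indexer(programs["mito"])
    non_mito = np.ones(n_genes, bool)
    non_mito[mito_idx] = False
    f = config.mito_baseline_fraction
    base[mito_idx] = (
        base[non_mito].sum() * f / (1 - f) / max(len(mito_idx), 1)
    )

    # cell assignments
    stages = np.concatenate(
        [np.repeat(s, config.stage_sizes.get(s, 0)) for s in STAGES]
    )
    n_cells = stages.size
    if n_cells == 0:
        raise ConfigurationError("no cells requested")
    perm = rng.permutation(n_cells)
    stages = stages[perm]
    region_p = [config.region_fractions.get(r, 0.0) for r in REGIONS]
    regions = rng.choice(REGIONS, size=n_cells, p=region_p)
    samples = rng.integers(0, config.n_barcodes, size=n_cells)
    phases = np.empty(n_cells, dtype=object)
    for s in STAGES:
        m = stages == s
        if not m.any():
            continue
        p = np.asarray(config.phase_probs[s], float)
        phases[m] = rng.choice(["G1", "S", "G2M"], size=m.sum(), p=p / p.sum())

    # expected proportion matrix
    stage_order = {s: i for i, s in enumerate(STAGES)}
    mult = np.ones((n_cells, n_genes))
    for s in STAGES:
        m = stages == s
        idx = genes.get_indexer(programs[f"stage_{s}"])
        mult[np.ix_(m, idx)] *= config.effect_size
    for reg in REGIONS:
        idx = genes.get_indexer(programs[reg])
        shape_mult = _stage_shape_multipliers(
            len(idx),
            config.effect_size,
            np.random.default_rng(derive_seed(config.seed, f"shapes_{reg}")),
            base_weights=base[idx],
        )  # (n_prog, n_stages)
        m = regions == reg
        stage_col = np.array([stage_order[s] for s in stages[m]])
        mult[np.ix_(m, idx)] *= shape_mult[:, stage_col].T
    for prog, phase in (("s_phase", "S"), ("g2m_phase", "G2M")):
        m = phases == phase
        idx = genes.get_indexer(programs[prog])
        mult[np.ix_(m, idx)] *= config.phase_effect

    rates = mult * base[None, :]
    rates /= rates.sum(axis=1, keepdims=True)

    mu_log, sd_log = config.depth_lognormal
    depths = rng.lognormal(mean=mu_log, sigma=sd_log, size=n_cells)

    # doublets: Bernoulli(doublet_rate); partner drawn from another sample
    is_doublet = rng.random(n_cells) < config.doublet_rate
    partner = np.full(n_cells, -1)
    partner_sample = samples.copy()
    for i in np.flatnonzero(is_doublet):
        others = np.flatnonzero(samples != samples[i])
        if others.size == 0:
            is_doublet[i] = False
            continue
        partner[i] = rng.choice(others)
        partner_sample[i] = samples[partner[i]]

    eff_rates = rates.copy()
    eff_depths = depths.copy()
    doub_idx = np.flatnonzero(is_doublet)
    if doub_idx.size:
        eff_depths[doub_idx] = depths[doub_idx] + depths[partner[doub_idx]]
        mix = (
            rates[doub_idx] * depths[doub_idx, None]
            + rates[partner[doub_idx]] * depths[partner[doub_idx], None]
        )
        eff_rates[doub_idx] = mix / mix.sum(axis=1, keepdims=True)

    counts = _nb_sample(rng, eff_rates * eff_depths[:, None], config.nb_dispersion)

    cell_ids = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    truth = pd.DataFrame(
        {
            "stage": stages,
            "region": regions,
            "phase": phases.astype(str),
            "doublet": is_doublet,
            "sample": [f"S{s}" for s in samples],
            "sample_2": [
                f"S{partner_sample[i]}" if is_doublet[i] else ""
                for i in range(n_cells)
            ],
            "depth": eff_depths,
        },
        index=cell_ids,
    )
    gene_meta = pd.DataFrame(index=genes)
    gene_meta["mito"] = gene_meta.index.str.startswith("mt-")
    cm = CountMatrix(sp.csr_matrix(counts), truth.copy(), gene_meta)
    return SimulatedDataset(
        counts=cm,
        truth=truth,
        program_genes={k: list(v) for k, v in programs.items()},
        rates=eff_rates,
        config=config,
    )


def simulate_barcode_counts(
    dataset: SimulatedDataset, config: Optional[SimConfig] = None
) -> BarcodeMatrix:
    """Sample-barcode counts: high on each cell's own sample barcode(s),
    ``signal/signal_to_noise`` Poisson background elsewhere."""
    config = config or dataset.config
    samples = dataset.truth["sample"].str.lstrip("S").astype(int).to_numpy()
    if config.n_barcodes < samples.max() + 1:
        raise ConfigurationError("n_barcodes < number of distinct sample identities")
    rng = np.random.default_rng(derive_seed(config.seed, "barcodes"))
    n_cells = len(dataset.truth)
    mean = np.full((n_cells, config.n_barcodes),
                   config.barcode_signal_mean / config.barcode_signal_to_noise)
    mean[np.arange(n_cells), samples] = config.barcode_signal_mean
    doub = dataset.truth["doublet"].to_numpy()
    if doub.any():
        s2 = (
            dataset.truth.loc[doub, "sample_2"].str.lstrip("S").astype(int).to_numpy()
        )
        mean[np.flatnonzero(doub), s2] = config.barcode_signal_mean
    counts = rng.poisson(np.where(np.isfinite(mean), mean, 0.0))
    return BarcodeMatrix(
        sp.csr_matrix(counts),
        dataset.truth.index,
        [f"BC{i}" for i in range(config.n_barcodes)],
    )


def simulate_nucleus_samples(
    dataset: SimulatedDataset, config: Optional[SimConfig] = None
) -> Dict[str, CountMatrix]:
    """Four region-dissected nucleus samples (AD, PD, AV, PV).

    Dorsal samples are downsampled in cells (``nucleus_dorsal_cell_fraction``)
    and re-drawn at depth x ``nucleus_region_depth_factor[region]``, matching
    dissections where dorsal samples had fewer cells but higher depth.
    """
    config = config or dataset.config
    rng = np.random.default_rng(derive_seed(config.seed, "nucleus"))
    out: Dict[str, CountMatrix] = {}
    singlet = ~dataset.truth["doublet"].to_numpy()
    for region, tag in (("dorsal", "D"), ("ventral", "V")):
        idx = np.flatnonzero((dataset.truth["region"].to_numpy() == region) & singlet)
        if idx.size == 0:
            warnings.warn(f"region {region} has zero cells; emitting empty samples")
        if region == "dorsal" and idx.size:
            n_keep = max(1, int(round(idx.size * config.nucleus_dorsal_cell_fraction)))
            idx = rng.choice(idx, size=n_keep, replace=False)
        rng.shuffle(idx)
        half = idx.size // 2
        factor = config.nucleus_region_depth_factor.get(region, 1.0)
        for prefix, sub in (("A", idx[:half]), ("P", idx[half:])):
            name = f"{prefix}{tag}"
            mu = dataset.rates[sub] * (
                dataset.truth["depth"].to_numpy()[sub, None] * factor
            )
            counts = _nb_sample(rng, mu, config.nb_dispersion)
            meta = dataset.truth.iloc[sub].copy()
            meta.index = pd.Index(
                [f"{name}_{c}" for c in meta.index], name="cell"
            )
            meta["nucleus_sample"] = name
            out[name] = CountMatrix(
                sp.csr_matrix(counts), meta, dataset.counts.gene_meta.copy()
            )
    return out


# ----------------------------------------------------------------------
# spatial spots


@dataclass
class SpotConfig:
    """Per-probe in situ spot generation on a normalized [0,1] axis."""

    seed: int = 0
    #: probe -> Beta(a, b) shape pair for the axis-position distribution
    probe_beta: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"Crym": (2.0, 5.0), "Urah": (5.0, 2.0)}
    )
    spots_per_probe: int = 500
    #: probe -> probability a spot carries the co-label flag
    colabel_prob: Mapping[str, float] = field(default_factory=dict)
    axis: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [400.0, 300.0], [700.0, 800.0]])
    )

    def __post_init__(self):
        for probe, (a, b) in self.probe_beta.items():
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"Beta parameters for {probe} must be > 0")


def _polyline_point(axis: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Map normalized arclength t in [0,1] to 2-D points on the polyline."""
    seg = np.diff(axis, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    s = np.clip(t, 0, 1) * total
    k = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[k]) / seglen[k]
    return axis[k] + seg[k] * frac[:, None]


def simulate_spots(config: SpotConfig) -> pd.DataFrame:
    """Spots with a true axis coordinate t ~ Beta per probe, 2-D coordinates
    on the polyline, and Bernoulli co-label channel flags."""
    rng = np.random.default_rng(derive_seed(config.seed, "spots"))
    frames = []
    for probe, (a, b) in config.probe_beta.items():
        t = rng.beta(a, b, size=config.spots_per_probe)
        xy = _polyline_point(np.asarray(config.axis, float), t)
        p_co = config.colabel_prob.get(probe, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "spot_id": [f"{probe}_{i:05d}" for i in range(t.size)],
                    "probe": probe,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "t_true": t,
                    "nucleus": True,
                    "colabel": rng.random(t.size) < p_co,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# paired reference/query helper for the label-transfer study


def simulate_transfer_pair(
    effect_size: float = 2.0,
    n_ref: int = 500,
    n_query: int = 500,
    n_region_genes: int = 50,
    n_genes: int = 500,
    seed: int = 0,
    depth: float = 3000.0,
    nb_dispersion: float = 0.3,
) -> Tuple[CountMatrix, CountMatrix]:
    """Two-region B-cell reference and query sharing dorsal/ventral programs.

    Returns (reference, query); each ``cell_meta`` has a ``region`` column
    (the query's is ground truth to recover, not an input to transfer).
    """
    rng = np.random.default_rng(derive_seed(seed, "transfer_pair"))
    genes = pd.Index(
        [f"Dors{i:04d}" for i in range(n_region_genes)]
        + [f"Vent{i:04d}" for i in range(n_region_genes)]
        + [f"Bg{i:05d}" for i in range(n_genes - 2 * n_region_genes)],
        name="gene",
    )
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    # region program genes are detectable markers: upper-half baselines
    base[: 2 * n_region_genes] = np.exp(
        np.abs(rng.normal(0.0, 1.0, size=2 * n_region_genes))
    )

    def draw(n: int, prefix: str) -> CountMatrix:
        regions = rng.choice(REGIONS, size=n)
        mult = np.ones((n, n_genes))
        mult[regions == "dorsal", :n_region_genes] = effect_size
        mult[regions == "ventral", n_region_genes : 2 * n_region_genes] = effect_size
        rates = mult * base[None, :]
        rates /= rates.sum(axis=1, keepdims=True)
        counts = _nb_sample(rng, rates * depth, nb_dispersion)
        meta = pd.DataFrame(
            {"region": regions},
            index=pd.Index([f"{prefix}{i:05d}" for i in range(n)], name="cell"),
        )
        return CountMatrix(sp.csr_matrix(counts), meta, pd.DataFrame(index=genes))

    return draw(n_ref, "ref"), draw(n_query, "qry")
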