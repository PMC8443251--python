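"""Shared configuration for the numbered analysis drivers.

Every driver regenerates the same synthetic study from one seed so each can
be run independently; all computation lives in the svzlineage package.
"""

import os

from svzlineage.simulate import SimConfig, SpotConfig, simulate_lineage_counts

SEED = 20
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def study_config() -> SimConfig:
    return SimConfig(seed=SEED)


def spot_config() -> SpotConfig:
    return SpotConfig(
        seed=SEED,
        probe_beta={"Crym": (2.0, 5.0), "Urah": (5.0, 2.0), "Dio2": (6.0, 2.5)},
        spots_per_probe=800,
        colabel_prob={"Crym": 0.9, "Urah": 0.4, "Dio2": 0.5},
    )


def dataset():
    return simulate_lineage_counts(study_config())


def outdir(name: str) -> str:
    path = os.path.join(RESULTS, name)
    os.makedirs(path, exist_ok=True)
    return path
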