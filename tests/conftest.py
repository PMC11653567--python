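"""Shared fixtures: small simulated crosses reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ssdom.data_io import CountMatrix
from ssdom.pipeline import run_from_memory
from ssdom.simulate import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def small_sim():
    """One small cross with every feature class present (seeded)."""
    cfg = SimConfig(n_genes=250, crosses=(("A", "B"),), seed=0)
    return cfg, *simulate_cross(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Full pipeline output on the small cross."""
    _, counts, samples, genes, truth = small_sim
    return run_from_memory(counts, samples, genes), truth


@pytest.fixture()
def tiny_counts():
    """Hand-built 4-gene x 4-sample matrix with exact values."""
    return CountMatrix(
        ["g1", "g2", "g3", "g4"],
        ["s1", "s2", "s3", "s4"],
        np.array([
            [10, 20, 30, 40],
            [1, 1, 1, 1],
            [0, 0, 5, 5],
            [7, 7, 7, 7],
        ]),
    )


def make_samples(n_reps=3, lines=("A", "B"), cross="I"):
    """Minimal valid design table for one cross."""
    rows = []
    l1, l2 = lines
    for dam, sire in ((l1, l1), (l2, l2), (l1, l2), (l2, l1)):
        for sex in ("female", "male"):
            for rep in range(1, n_reps + 1):
                rows.append({
                    "sample_id": f"{cross}_{dam}{sire}_{sex[0]}{rep}",
                    "sex": sex, "dam": dam, "sire": sire,
                    "cross": cross, "replicate": rep,
                    "genotype": dam + sire, "homozygous": dam == sire,
                    "excluded": False, "exclude_reason": "",
                })
    return pd.DataFrame(rows)
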