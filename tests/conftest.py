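import numpy as np
import pandas as pd
import pytest

from mgblup.kernels import grm_vanraden
from mgblup.simulate import SimulationConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort small enough for sub-second fits."""
    return SimulationConfig(
        n_individuals=60, n_snps=200, n_asvs=40,
        depth_mean=2000.0, depth_sd=400.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_G(small_config):
    geno = simulate_genotypes(small_config)
    return grm_vanraden(geno.dosages, geno.sample_ids)


@pytest.fixture(scope="session")
def growth_records():
    """Deterministic 6-individual weekly BW/FI records for trait derivation.

    Body weights follow individual linear trajectories; feed intake is an
    exact linear function of ADG and MBW^0.75 plus a fixed per-individual
    deviation, so the RFI regression has a known answer.
    """
    rng = np.random.default_rng(7)
    ids = [f"I{i}" for i in range(1, 7)]
    start = rng.uniform(600, 900, size=6)
    slope = rng.uniform(180, 320, size=6)  # g/week
    delta = np.array([3.0, -2.0, 1.0, 0.0, -1.5, -0.5])
    rows = []
    for i, ind in enumerate(ids):
        bw = {w: start[i] + slope[i] * (w - 4) for w in range(4, 11)}
        for w in range(4, 11):
            if w == 4:
                fi = np.nan
            else:
                adg = (bw[w] - bw[w - 1]) / 7.0
                mbw = 0.5 * (bw[w] + bw[w - 1])
                fi = 7.0 * (-5.0 + 0.6 * adg + 0.4 * mbw**0.75 + delta[i])
            rows.append((ind, w, bw[w], fi))
    return pd.DataFrame(rows, columns=["id", "week", "bw", "fi"])
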