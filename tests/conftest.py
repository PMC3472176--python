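import numpy as np
import pytest

import gvarpart as gv


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across read-only tests."""
    cfg = gv.SimConfig(n_founders=60, n_generations=2, sires_per_generation=6,
                       offspring_per_sire=10, n_chromosomes=3,
                       markers_per_chromosome=80, n_qtl=40, seed=11)
    return gv.simulate_dataset(cfg)


@pytest.fixture
def toy_geno():
    """Tiny 4-individual, 5-marker panel with known frequencies."""
    codes = np.array([
        [0, 1, 2, 0, 1],
        [2, 1, 0, 1, 2],
        [1, 0, 1, 2, 0],
        [1, 2, 1, 1, 1],
    ], dtype=float)
    return gv.GenotypeMatrix(
        ids=["i1", "i2", "i3", "i4"],
        marker_ids=[f"m{j}" for j in range(1, 6)],
        chrom=np.array([1, 1, 1, 2, 2]),
        pos=np.array([100, 200, 300, 100, 200]),
        codes=codes,
    )
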