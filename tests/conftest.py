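import numpy as np
import pytest

from transqtl.genotypes import GenotypeMatrix, SimPopConfig, simulate_f2_population, simulate_wild_population
from transqtl.pheno_sim import PhenotypeVector


@pytest.fixture(scope="session")
def bari_like_panels():
    """One simulated wild + F2 panel pair at the post-filter study scale."""
    cfg = SimPopConfig(n_wild=143, n_hybrid=140, n_markers=125, seed=11)
    wild = simulate_wild_population(cfg)
    hybrid = simulate_f2_population(wild, cfg)
    return cfg, wild, hybrid


@pytest.fixture
def toy_genotypes():
    """Tiny deterministic hybrid matrix for hand-checkable operations."""
    dosage = np.array(
        [
            [0, 0, 2, 1],
            [1, 1, 1, 0],
            [2, 2, 0, 2],
            [0, 1, 2, 1],
            [1, 2, 1, 0],
            [2, 0, 0, 2],
        ]
    )
    return GenotypeMatrix(
        [f"s{i}" for i in range(6)], ["m1", "m2", "m3", "m4"], dosage, "hybrid"
    )


def make_pheno(sample_ids, values, **kw):
    return PhenotypeVector(list(sample_ids), np.asarray(values, float), **kw)
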