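import numpy as np
import pytest

from lcpop import simdata


@pytest.fixture(scope="session")
def two_deme():
    """Moderate two-deme low-coverage simulation shared across tests."""
    cfg = simdata.SimConfig(
        n_demes=2,
        inds_per_deme=20,
        n_sites=2000,
        chrom_length=2_000_000,
        fst_drift=0.1,
        mean_depth=1.3,
        error_rate=0.01,
        seed=42,
    )
    truth, counts, gl = simdata.simulate(cfg)
    return cfg, truth, counts, gl


@pytest.fixture(scope="session")
def two_deme_certain(two_deme):
    """Full-certainty genotype panel for the same two-deme simulation."""
    cfg, truth, _, _ = two_deme
    gl = simdata.glmatrix_from_genotypes(
        truth.true_genotypes, positions=truth.positions, demes=cfg.deme_of()
    )
    return cfg, truth, gl


def certain(genotypes):
    return simdata.certain_gl_from_genotypes(np.asarray(genotypes))
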