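import numpy as np
import pytest

from sexdimorph import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small two-region dataset with planted effects, shared by tests."""
    cfg = SimConfig(
        n_genes=400,
        n_per_cell={"F": 10, "M": 18},
        regions=("a", "b"),
        seed=11,
        rxe_factor=0.8,
        rxe_region="a",
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted effects anywhere; autosomes only."""
    cfg = SimConfig(
        n_genes=300,
        n_per_cell=12,
        regions=("a",),
        chrom_props={"autosome": 1.0, "X": 0.0, "Y": 0.0, "PAR": 0.0},
        sex_frac=0.0,
        dx_frac_female=0.0,
        dx_frac_male=0.0,
        dx_frac_shared=0.0,
        escape_shift=0.0,
        variable_shift=0.0,
        batch_scale=0.0,
        seed=5,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
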