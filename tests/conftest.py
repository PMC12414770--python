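import numpy as np
import pytest

from daisel import BlupTable, Environment, SimConfig, Treatment


@pytest.fixture
def rng():
    return np.random.default_rng(20190401)


def make_environments():
    return [
        Environment(Treatment(t), y)
        for t in ("CV", "UC")
        for y in (2019, 2020, 2021, 2022)
    ]


@pytest.fixture
def random_blups(rng):
    """A complete positive 24 × 8 BLUP-style matrix over CV/UC × 4 years."""
    vals = np.abs(rng.normal(2000.0, 400.0, (24, 8))) + 100.0
    return BlupTable(
        genotypes=[f"g{i:02d}" for i in range(24)],
        environments=make_environments(),
        values=vals,
    )


@pytest.fixture
def small_sim():
    """A down-scaled trial: 24 genotypes, 2 years, 2 blocks, small grids."""
    return SimConfig(
        n_genotypes=24,
        years=(2019, 2020),
        year_effects=(150.0, -150.0),
        blocks=2,
        grid_cv=(5, 6),
        grid_uc=(6, 5),
        Vg=150_000.0,
        Ve=60_000.0,
        spatial_amplitude=100.0,
        missing_rate=0.03,
        seed=11,
    )
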