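from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import genecol as gc

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"
GOLDEN_DIR = Path(__file__).parent / "data" / "golden"

#: bands shipped with (and predictors used by) the pinned fixture
FIXTURE_BANDS = ["TD", "MWMT", "MAP", "MAT"]
FIXTURE_SEED = 20260927


@pytest.fixture(scope="session")
def tiny_study() -> gc.Study:
    """The pinned small study: 12 populations x 2 families x 3 gardens x
    2 blocks, 20x20 grid."""
    return gc.tiny_fixture()


@pytest.fixture(scope="session")
def full_study() -> gc.Study:
    """One full-design synthetic study (98 x 2 x 3 x 6)."""
    return gc.simulate_study(gc.SimConfig(), seed=7)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_study) -> pd.DataFrame:
    gardens = sorted(tiny_study.plants["garden"].unique())
    means = {g: gc.population_means(tiny_study.plants, g)[0] for g in gardens}
    retained = [(t.name, g) for t in gc.DEFAULT_TRAITS for g in gardens]
    return gc.build_trait_matrix(means, retained)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
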