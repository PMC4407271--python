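import numpy as np
import pytest

from ftltools.simulate import ReporterLayout, SimulationModel

CHROM_BP = 1_000_000


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def pollen2_layout():
    return ReporterLayout([("YFP", 1, "G"), ("dsRed", CHROM_BP, "R")], "pollen2")


@pytest.fixture
def tetrad_layout():
    return ReporterLayout([("YFP", 1, "G"), ("dsRed", CHROM_BP, "R")], "tetrad")


@pytest.fixture
def pollen3_layout():
    return ReporterLayout(
        [("CFP", 1, "C"), ("YFP", CHROM_BP // 2, "Y"), ("dsRed", CHROM_BP, "R")],
        "pollen3",
    )


def uniform_model(total_cm, nu=1.0, escape=0.0, seed=0):
    return SimulationModel.uniform(CHROM_BP, total_cm, nu=nu,
                                   escape_fraction=escape, rng_seed=seed)


@pytest.fixture
def make_model():
    return uniform_model
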