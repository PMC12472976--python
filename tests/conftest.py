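import numpy as np
import pytest

from wortpep import (ActivityDatabase, CalibrationCurve, EnzymeRule,
                     load_fixtures)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def fixture_proteins():
    return load_fixtures()


@pytest.fixture(scope="session")
def barley(fixture_proteins):
    return fixture_proteins[:3]


@pytest.fixture(scope="session")
def hemp(fixture_proteins):
    return fixture_proteins[3:]


@pytest.fixture()
def trypsin_like():
    return EnzymeRule("trypsin", "3.4.21.4", frozenset("KR"), frozenset("P"))


@pytest.fixture()
def sec_curve():
    # log10(kDa) = 3.2 - 0.095 * RT over a 45-min run
    return CalibrationCurve(slope=-0.095, intercept=3.2, r_squared=1.0,
                            rt_min=0.0, rt_max=45.0)


@pytest.fixture(scope="session")
def golden_profile():
    from pathlib import Path
    return (Path(__file__).parent / "data" / "golden_profile.tsv").read_text()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def random_rule(rng: np.random.Generator) -> EnzymeRule:
    n_p1 = int(rng.integers(1, 8))
    p1 = frozenset(rng.choice(list(AA), size=n_p1, replace=False))
    n_block = int(rng.integers(0, 4))
    block = frozenset(rng.choice(list(AA), size=n_block, replace=False))
    return EnzymeRule("random", "", p1, block)
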