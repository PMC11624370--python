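import numpy as np
import pandas as pd
import pytest

from mefeval.covariance import holstein_defaults
from mefeval.pedigree import PedigreeTable


@pytest.fixture(scope="session")
def truth():
    return holstein_defaults()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture()
def trio_pedigree():
    """Sire, dam, offspring."""
    return PedigreeTable(pd.DataFrame({
        "animal": [1, 2, 3],
        "sire": [0, 0, 1],
        "dam": [0, 0, 2],
        "birth_year": [2000, 2000, 2002],
        "sex": ["M", "F", "F"],
    }))


def random_pedigree(rng, n_founders=8, n_extra=24, start_year=2000):
    """Random multi-generation pedigree for property tests."""
    animal, sire, dam, year, sex = [], [], [], [], []
    males, females = [], []
    for i in range(n_founders):
        s = "M" if i % 2 == 0 else "F"
        animal.append(i + 1)
        sire.append(0)
        dam.append(0)
        year.append(start_year)
        sex.append(s)
        (males if s == "M" else females).append(i + 1)
    nid = n_founders + 1
    for j in range(n_extra):
        s = int(rng.choice(males))
        d = int(rng.choice(females))
        sx = "M" if rng.random() < 0.5 else "F"
        animal.append(nid)
        sire.append(s)
        dam.append(d)
        year.append(start_year + 1 + j)
        sex.append(sx)
        (males if sx == "M" else females).append(nid)
        nid += 1
    return PedigreeTable(pd.DataFrame({
        "animal": animal, "sire": sire, "dam": dam,
        "birth_year": year, "sex": sex,
    }))
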