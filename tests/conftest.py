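"""Shared fixtures: small synthetic templates and read sets."""

import numpy as np
import pytest

from riboprofiler import simdata
from riboprofiler.seqio import SeqRecord


@pytest.fixture(scope="session")
def template_2kb() -> SeqRecord:
    return simdata.default_unit_template(seed=3, regions={"X": 2000})


@pytest.fixture(scope="session")
def template_45s() -> SeqRecord:
    """A 6.5 kb repeat-unit template with the standard region layout."""
    return simdata.default_unit_template(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
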