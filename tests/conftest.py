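import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mtpopgen import simdata
from mtpopgen.seqio import Alignment, PopulationMap


@pytest.fixture(scope="session")
def study_ds():
    """The seeded study-like synthetic dataset (45 x 473, pops E/S/W)."""
    return simdata.make_study_like_fixture(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_alignment():
    return Alignment.from_pairs(
        [("a", "ACGTACGTAC"), ("b", "ACGTACGTAA"), ("c", "ACGAACGTAC")]
    )


@pytest.fixture()
def toy_popmap():
    return PopulationMap({"a": "X", "b": "X", "c": "Y"})


def make_alignment(seqs, prefix="s"):
    return Alignment.from_pairs(
        [(f"{prefix}{i+1}", s) for i, s in enumerate(seqs)]
    )
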