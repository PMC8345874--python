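import numpy as np
import pytest

from phyloharvest import synth
from phyloharvest.seqio import Alignment, SequenceRecord, read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fast_model():
    """Small, cheap substitution model for simulation-heavy tests."""
    return synth.poisson_model(alpha=1.0, n_categories=2)


@pytest.fixture(scope="session")
def lg():
    return synth.lg_model(alpha=0.8, n_categories=4)


@pytest.fixture
def small_tree():
    return read_newick("((t1:0.1,t2:0.2):0.05,(t3:0.3,t4:0.1):0.05);")


def random_records(rng, n, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return [
        SequenceRecord(
            f"s{i}", "".join(rng.choice(list(alphabet), size=length)), taxon_code=f"s{i}"
        )
        for i in range(n)
    ]


@pytest.fixture
def random_alignment(rng):
    return Alignment(random_records(rng, 6, 40))
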