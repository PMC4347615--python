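import numpy as np
import pytest
from hypothesis import settings

import pssmloc as pl

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_pssm():
    """A 60-row PSSM whose every row is the uniform distribution."""
    return pl.PSSM(
        protein_id="uniform",
        probs=np.full((60, 20), 1 / 20),
        residues="A" * 60,
    )


@pytest.fixture
def random_pssm(rng):
    """An 80-row Dirichlet PSSM."""
    return pl.synth_pssm(80, np.full(20, 0.05), 5.0, rng, protein_id="rand")


@pytest.fixture
def ramp_scale():
    """Scale whose canonical-order values are 0, 1, ..., 19 (min-max -> i/19)."""
    return pl.AttributeScale(
        attribute_id="ramp",
        values={aa: float(i) for i, aa in enumerate(pl.CANONICAL_AA)},
    )


@pytest.fixture
def random_scale(rng):
    return pl.synth_attribute_scale(rng)


def make_attr_seq(values, pid="p", attr="a"):
    return pl.AttributeSequence(protein_id=pid, attribute_id=attr, values=np.asarray(values, float))
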