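import numpy as np
import pytest

from shapereadout.fixtures import TableSpec, make_table
from shapereadout.models import MechanismAgnosticModel
from shapereadout.seq2shape import MONO_DI, fit as fit_seq2shape


@pytest.fixture(scope="session")
def mgw_like_table():
    """Synthetic pentamer table with the real tables' variance structure
    (about two-thirds mono, most of the rest dinucleotide)."""
    return make_table(TableSpec(feature_name="synthetic-MGW"), seed=11)


@pytest.fixture(scope="session")
def mgw_like_model(mgw_like_table):
    return fit_seq2shape(mgw_like_table, MONO_DI)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_agn(k: int, rng, di_scale: float = 1.0) -> MechanismAgnosticModel:
    return MechanismAgnosticModel(
        k,
        float(rng.normal()),
        rng.normal(size=(k, 4)),
        di_scale * rng.normal(size=(k - 1, 16)),
    )
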