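import numpy as np
import pytest

from vdlin.grammar import default_grammar, encode_smiles
from vdlin.synthetic import SyntheticConfig, generate_library


@pytest.fixture(scope="session")
def grammar():
    return default_grammar(max_sequence_length=120)


@pytest.fixture(scope="session")
def small_library():
    """300 compounds with planted actives; shared across read-only tests."""
    return generate_library(
        SyntheticConfig(n_compounds=300, seed=11, active_fraction=0.3)
    )


@pytest.fixture(scope="session")
def small_encodings(small_library, grammar):
    return [encode_smiles(r.smiles, grammar) for r in small_library]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
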