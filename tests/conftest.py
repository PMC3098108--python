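import numpy as np
import pytest

from thermoscore import GeneratorSpec, ProteinSequence, generate_dataset


@pytest.fixture(scope="session")
def biased_pairs():
    """120 HP/MP-like pairs with the default (published-direction) bias."""
    return list(generate_dataset(GeneratorSpec(n_pairs=120, seed=11)).pairs)


@pytest.fixture(scope="session")
def null_pairs():
    """80 pairs generated with zero compositional bias (negative control)."""
    spec = GeneratorSpec(n_pairs=80, bias={}, seed=7)
    return list(generate_dataset(spec).pairs)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_sequence(rng, length=120, seq_id="s"):
    from thermoscore.tables import STANDARD_AA

    return ProteinSequence(
        seq_id, "".join(rng.choice(list(STANDARD_AA), size=length))
    )
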