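import numpy as np
import pytest

from planac import EnergyModel, FamilySpec, Sequence, generate_family


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def toy_pair():
    """The motivating example: a 2-pair helix vs a 1-pair partner."""
    return (
        (Sequence("s1", "AAGGAAAACCAA"), "..((....)).."),
        # the printed partner is 9 nt against a 10-char structure; the
        # structure is authoritative, so the sequence is padded with A
        (Sequence("s2", "AACAAAAGAA"), "..(....).."),
    )


@pytest.fixture(scope="session")
def small_family():
    spec = FamilySpec(
        structure=".(((....))).((((...)))).",
        n_sequences=5,
        sub_rate=0.4,
        comp_rate=0.4,
        indel_rate=0.25,
        seed=7,
    )
    return generate_family(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))
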