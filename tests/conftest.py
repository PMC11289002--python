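import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lwikit.io import LabeledAlignment, ReferenceTopology, SeqMeta
from lwikit.simulate import make_fixture


@pytest.fixture
def toy_alignment():
    """Four gapless 40-residue sequences around a 2-TM reference topology."""
    #            1         2         3         4
    #   1234567890123456789012345678901234567890
    ref = "MKTAYIAKQRFFLLGGAAVVSSDDEEKKRRHHWWYYPPQN"
    alt = "MKTAYIAKQRWFLLGGAAVVSSDDEEKKRRHHWWYYPPQN"  # one substitution at 11
    gap = "MKTAYIAKQR-FLLGGAAVVSSDDEEKKRRHHWWYYPPQN"
    div = "AATAYIAKQRFFLLGGAAVVSSDDEEKKRRHHWWYYPPAA"
    records = [("m1", ref), ("m2", alt), ("b1", gap), ("f1", div)]
    metadata = {
        "m1": SeqMeta("Homo sapiens", "mammal"),
        "m2": SeqMeta("Mus musculus", "mammal"),
        "b1": SeqMeta("Gallus gallus", "bird"),
        "f1": SeqMeta("Danio rerio", "fish"),
    }
    return LabeledAlignment(records=records, metadata=metadata)


@pytest.fixture
def toy_topology():
    """2-TM topology on the toy reference, roomy loop (11..15 and 26..30)."""
    return ReferenceTopology(
        reference_id="m1",
        tm_intervals=((11, 15), (26, 30)),
        n_terminus_side="inner",
        flank_width=5,
    )


@pytest.fixture(scope="session")
def catsper_family():
    """The channel-like fixture family: (alignment, topology, ground truth)."""
    return make_fixture("catsper_like")


@pytest.fixture(scope="session")
def null_family():
    """The no-signal fixture: uniform compositions, equal saturating rates."""
    return make_fixture("null_uniform")
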