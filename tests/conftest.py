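import pytest
from hypothesis import settings

from proteasim.prep import ProteinRecord, assign_groups
from proteasim.proteases import get_protease

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def trypsin():
    return get_protease("trypsin")


@pytest.fixture
def trypsin_p():
    """Trypsin variant without the proline block (pure K/R C-terminal rule)."""
    return get_protease("trypsin/p")


@pytest.fixture
def toy_proteome():
    """Four hand-written proteins with known peptide sharing.

    p1 and p2 share the substring TAYIAK; p4 contains overlapping AA runs.
    """
    records = [
        ProteinRecord("p1", "MKTAYIAKQRLLVDK"),
        ProteinRecord("p2", "GGTAYIAKPPE"),
        ProteinRecord("p3", "MEEPQSDPSV"),
        ProteinRecord("p4", "AAAKWWAAA"),
    ]
    return assign_groups(records)
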