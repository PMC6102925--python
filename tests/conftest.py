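import pytest

from repeatspan import default_locus


@pytest.fixture(scope="session")
def locus():
    """Synthetic G4C2 locus with 100-nt motif-free flanks."""
    return default_locus()


@pytest.fixture()
def perfect_read_seq(locus):
    def _build(units: int) -> str:
        return locus.flank_up + locus.motif * units + locus.flank_down

    return _build
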