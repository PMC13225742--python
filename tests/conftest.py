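import numpy as np
import pytest

from bequant import ProtospacerSite, make_genome

_RNG = np.random.default_rng(20240917)
_FLANK5 = "".join(_RNG.choice(list("ACGT"), 40))
_FLANK3 = "".join(_RNG.choice(list("ACGT"), 40))


@pytest.fixture(scope="session")
def polya_site() -> ProtospacerSite:
    """Protospacer that is A at every position: all 20 positions informative."""
    amp = _FLANK5 + "A" * 20 + "AGG" + _FLANK3
    return ProtospacerSite("polyA", amp, 40, "+", 20, "NGG",
                           intended_positions=(5,))


@pytest.fixture(scope="session")
def mixed_site() -> ProtospacerSite:
    """Protospacer with A at 2,4,5,7,8 and a C at 5' of them, NGG PAM."""
    proto = "GACTAAGAATGCCGTGCTGA"  # A at 2,4?,...
    # positions (1-based): G A C T A A G A A T G C C G T G C T G A
    amp = _FLANK5 + proto + "TGG" + _FLANK3
    return ProtospacerSite("mixed", amp, 40, "+", 20, "NGG",
                           intended_positions=(5,))


@pytest.fixture(scope="session")
def dual_site() -> ProtospacerSite:
    """Two intended positions (A4 and A7), for dual-edit metrics."""
    amp = _FLANK5 + "A" * 20 + "AGG" + _FLANK3
    return ProtospacerSite("dual", amp, 40, "+", 20, "NGG",
                           intended_positions=(4, 7))


@pytest.fixture(scope="session")
def small_genome() -> dict[str, str]:
    return make_genome(50_000, gc=0.42, seed=7)
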