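import numpy as np
import pytest

from poppystr.nomenclature import MarkerReference, RepeatStructure
from poppystr.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def tet_reference(rng):
    """OPTET089b-like marker: repeat region (AAGA)7AG(AAGA)1, flanks
    totaling 152 bp so the reference amplicon is 186 bp, with TC at
    downstream offsets 42-43."""
    up = random_dna(rng, 109)
    down = list(random_dna(rng, 43))
    down[41:43] = list("TC")
    down[40] = "G"  # keep the TC deletion's position unambiguous
    return MarkerReference("TET089b_like", up,
                           RepeatStructure.parse("(AAGA)7AG(AAGA)1"),
                           "".join(down))


@pytest.fixture()
def tri_reference(rng):
    """OPTRI0245b-like marker: repeat region (AGA)3 with TGTTAAAATG at
    upstream offsets 11-20."""
    up = list(random_dna(rng, 60))
    up[40:50] = list("TGTTAAAATG")
    if up[50] == "T":  # a T here would let the deletion slide by one
        up[50] = "C"
    if up[39] == "G":
        up[39] = "A"
    return MarkerReference("TRI0245b_like", "".join(up),
                           RepeatStructure.parse("(AGA)3"),
                           random_dna(rng, 40))
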