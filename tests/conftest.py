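import numpy as np
import pytest

from introgrescan.seqdata import HaplotypeAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_alignment(rng, n=10, length=50, bases="ACGT", locus="toy"):
    mat = rng.choice(list(bases), size=(n, length))
    return HaplotypeAlignment(
        locus, [f"h{i}" for i in range(n)], ["".join(row) for row in mat]
    )


@pytest.fixture
def toy_alignment():
    return HaplotypeAlignment(
        "toy",
        ["a1", "a2", "b1", "b2"],
        ["ACGTACGT", "ACGTACGA", "TCGAACGT", "TCGAACGA"],
    )
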