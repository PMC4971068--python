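import numpy as np
import pytest

from filoplast import AnnotatedGenome

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_928)


@pytest.fixture
def small_genome(rng) -> AnnotatedGenome:
    """A 10 kb single-contig genome with three CDS intervals."""
    seq = random_seq(rng, 10_000)
    return AnnotatedGenome(
        contigs={"c1": seq},
        cds_intervals={"c1": [(1_000, 4_000), (4_500, 7_000), (8_000, 9_500)]},
        name="toy",
    )
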