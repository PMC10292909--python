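import numpy as np
import pytest

from masv import ReferenceGenome


def random_genome(length: int, seed: int, contig: str = "chr") -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length))
    return ReferenceGenome(contig_id=contig, sequence=seq)


@pytest.fixture(scope="session")
def small_genome() -> ReferenceGenome:
    """A 60 kb random genome, enough for a few dozen small SVs."""
    return random_genome(60_000, seed=20230601)


@pytest.fixture(scope="session")
def tiny_genome() -> ReferenceGenome:
    return ReferenceGenome(contig_id="tiny", sequence="ACGTACGTAC")
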