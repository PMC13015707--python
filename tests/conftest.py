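import numpy as np
import pytest

from phagecodon.genetic_code import SENSE_CODONS
from phagecodon.seqio import CodingSequence
from phagecodon.synthetic_data import SyntheticConfig, generate_study


def random_cds(rng: np.random.Generator, n_codons: int = 50, gene_id: str = "g") -> CodingSequence:
    """A random valid coding sequence of uniformly drawn sense codons."""
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    return CodingSequence(gene_id=gene_id, sequence="".join(codons))


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across pipeline-level tests."""
    return generate_study(SyntheticConfig(seed=11, n_host_genes=250))
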