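import numpy as np
import pytest
from hypothesis import settings

from drscan import GenomeRecord, PlantSpec, generate_genome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def plant_exact(
    rng: np.random.Generator,
    genome_len: int,
    unit: str,
    n_copies: int,
    spacer_len: int = 35,
) -> tuple[GenomeRecord, list[int]]:
    """Background with one exact repeat planted at regular spacer gaps."""
    block_parts, starts, pos = [], [], 0
    for i in range(n_copies):
        starts.append(pos)
        block_parts.append(unit)
        pos += len(unit)
        if i < n_copies - 1:
            block_parts.append(random_seq(rng, spacer_len))
            pos += spacer_len
    block = "".join(block_parts)
    lead = (genome_len - len(block)) // 2
    seq = random_seq(rng, lead) + block + random_seq(rng, genome_len - lead - len(block))
    return GenomeRecord("g", seq), [lead + s for s in starts]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_planted():
    """One clean planted array (4 exact copies of a 30-bp DR) in 20 kb."""
    spec = PlantSpec(
        genome_len=20_000, n_arrays=1, dr_len_range=(30, 30),
        dr_copies_range=(4, 4), dr_divergence=0.0, seed=7,
    )
    return generate_genome(spec)
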