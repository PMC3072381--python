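import numpy as np
import pytest

from nucret.seqcomp import Genome, make_windows


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_genome(rng):
    """A 3-kb single-chromosome genome with no N."""
    bases = rng.choice(list("ACGT"), size=3000)
    return Genome({"chr1": "".join(bases)})


@pytest.fixture
def random_grid(random_genome):
    return make_windows(random_genome, 150)


def make_random_genome(seed: int, lengths: dict[str, int], gc: float = 0.5) -> Genome:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return Genome(
        {
            name: "".join(rng.choice(list("ACGT"), size=n, p=p))
            for name, n in lengths.items()
        }
    )
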