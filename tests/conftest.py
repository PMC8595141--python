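import numpy as np
import pytest

from gmpnet.expression import RankedList


@pytest.fixture
def ten_gene_list() -> RankedList:
    """Ten genes with strictly decreasing scores 10..1."""
    genes = tuple(f"g{i}" for i in range(10))
    return RankedList(genes=genes, scores=tuple(float(10 - i) for i in range(10)))


@pytest.fixture
def random_ranked_list():
    """Factory: ranked list of n genes with seeded standard-normal scores."""

    def make(n: int, seed: int) -> RankedList:
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.standard_normal(n))[::-1]
        return RankedList(
            genes=tuple(f"g{i:05d}" for i in range(n)),
            scores=tuple(float(s) for s in scores),
        )

    return make
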