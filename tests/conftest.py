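import numpy as np
import pytest

from ffdcj import Chromosome, Genome, SignedGene


def random_same_content_pair(rng: np.random.Generator, max_genes: int = 8):
    """Two random duplicate-free genomes over the same gene set (for
    family-based adjacency-graph properties)."""
    n = int(rng.integers(1, max_genes + 1))
    names = [f"g{i}" for i in range(1, n + 1)]

    def scramble(tag: str) -> Genome:
        order = rng.permutation(n)
        n_chrom = int(rng.integers(1, min(3, n) + 1))
        cuts = sorted(rng.choice(np.arange(1, n), size=n_chrom - 1, replace=False)) if n_chrom > 1 else []
        chroms = []
        for piece in np.split(order, cuts):
            if not len(piece):
                continue
            genes = tuple(SignedGene(names[i], bool(rng.random() < 0.5)) for i in piece)
            chroms.append(Chromosome(genes, circular=bool(rng.random() < 0.3)))
        return Genome(tag, tuple(chroms))

    return scramble("A"), scramble("B")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
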