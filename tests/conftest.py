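import numpy as np
import pytest

from wavescore.io_formats import GenotypeMatrix, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_genotypes():
    """8 individuals x 6 SNPs on two chromosomes, two genes, mixed annotation."""
    dosages = np.array(
        [
            [0, 1, 0, 2, 0, 1],
            [1, 0, 0, 1, 0, 0],
            [0, 0, 1, 0, 1, 0],
            [2, 1, 0, 1, 0, 0],
            [0, 0, 0, 0, 0, 1],
            [1, 0, 1, 1, 1, 0],
            [0, 1, 0, 0, 0, 0],
            [0, 0, 0, 1, 0, 1],
        ]
    )
    snps = [
        SnpRecord("s1", "1", 100, gene="GENE_A", is_nonsynonymous=True),
        SnpRecord("s2", "1", 200, gene="GENE_A", is_nonsynonymous=True),
        SnpRecord("s3", "1", 300, gene="GENE_A", is_nonsynonymous=False),
        SnpRecord("s4", "1", 400, gene="GENE_B", is_nonsynonymous=True),
        SnpRecord("s5", "2", 150, gene="GENE_C", is_nonsynonymous=True),
        SnpRecord("s6", "2", 250, gene="GENE_C", is_nonsynonymous=True),
    ]
    ids = [f"ind{i}" for i in range(1, 9)]
    return GenotypeMatrix(dosages, ids, snps)
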