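import numpy as np
import pytest

from rcdkit.alignment import CodonAlignment


@pytest.fixture
def toy_alignment() -> CodonAlignment:
    """Ten codons, four haplotypes, a few engineered variable sites."""
    base = "ATGGCTGGTACCTTAGACCGATTCGGAAAA"  # 10 codons, no stops
    seqs = [
        base,
        base[:5] + "G" + base[6:],          # codon 2 GCT->GCG (synonymous 3rd pos? pos5)
        base[:12] + "A" + base[13:],        # codon 5 change
        base,
    ]
    return CodonAlignment("toy", seqs, ["a", "b", "c", "d"], lineage="A", context="sympatric")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
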