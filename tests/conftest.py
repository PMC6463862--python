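import numpy as np
import pytest

from askpoly import HaplotypeAlignment


@pytest.fixture
def four_haplotype_alignment() -> HaplotypeAlignment:
    """4 haplotypes x 3 sites with allele splits (1,3), (2,2), (3,1).

    By hand: pi_locus = (1*3 + 2*2 + 1*3) / C(4,2) = 10/6, S = 3.
    """
    return HaplotypeAlignment.from_sequences("fixture", [
        ("a", "CAA"), ("b", "ACA"), ("c", "ACA"), ("d", "AAC")])


@pytest.fixture
def glycine_pair() -> tuple[str, str]:
    """Three glycine codons with one synonymous third-position difference."""
    return "GGGGGGGGG", "GGAGGGGGG"


def brute_force_pi(matrix: np.ndarray) -> float:
    """Independent double-loop pi with pairwise deletion over N."""
    n = matrix.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            for a, b in zip(matrix[i], matrix[j]):
                if a != "N" and b != "N" and a != b:
                    total += 1
    return total / (n * (n - 1) / 2)
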