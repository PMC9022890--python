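import numpy as np
import pytest

from saltiscan.hfs import HaplotypeMatrix


def random_background(rng: np.random.Generator, K: int) -> np.ndarray:
    """Random valid background spectrum with p_K comfortably above 1/(100K).

    A sorted Dirichlet draw mixed with a touch of the uniform spectrum, so
    the anchor frequency U = p_K always leaves the epsilon interval
    [1/(100K), U] non-degenerate.
    """
    p = np.sort(rng.dirichlet(np.ones(K)))[::-1]
    p = 0.9 * p + 0.1 / K
    return p / p.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_matrix():
    """4 haplotypes x 6 SNPs on one chromosome."""
    alleles = np.array(
        [
            [0, 0, 1, 0, 1, 0],
            [0, 0, 1, 0, 1, 0],
            [0, 1, 0, 0, 1, 1],
            [1, 1, 0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypeMatrix(
        alleles=alleles,
        chrom=np.array(["1"] * 6, dtype=object),
        pos_bp=np.arange(1, 7) * 100,
        phased=True,
        sample_ids=["a_1", "a_2", "b_1", "b_2"],
    )


def make_matrix(n_snps_per_chrom: dict, n_seq: int = 4, seed: int = 0) -> HaplotypeMatrix:
    rng = np.random.default_rng(seed)
    chroms, pos, cols = [], [], []
    for c, n in n_snps_per_chrom.items():
        chroms += [c] * n
        pos += list((np.arange(n) + 1) * 10)
        cols.append(rng.integers(0, 2, size=(n_seq, n), dtype=np.int8))
    return HaplotypeMatrix(
        alleles=np.concatenate(cols, axis=1),
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos),
        phased=True,
    )
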