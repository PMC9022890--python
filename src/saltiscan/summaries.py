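"""Expected-homozygosity summaries of the full (untruncated) window spectrum.

For a descending frequency vector f over all distinct classes in a window:

    H1    = sum_j f_j^2
    H12   = (f_1 + f_2)^2 + sum_{j>=3} f_j^2
    H2/H1 = (H1 - f_1^2) / H1

In unphased (multilocus genotype) mode the pooled statistic combines the top
three classes instead: G123 = (f_1 + f_2 + f_3)^2 + sum_{j>=4} f_j^2, with
G1 and G2/G1 defined analogously.  Truncation is a device of the likelihood
model only; these summaries always use the complete spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SummaryStats", "homozygosity_stats"]


@dataclass
class SummaryStats:
    h1: float
    h12: float  # pooled-top-class homozygosity (H12 or G123)
    h2h1: float
    mode: str


def homozygosity_stats(full_spectrum: np.ndarray, mode: str = "haplotype") -> SummaryStats:
    """H1, H12 (or G123), and H2/H1 (or G2/G1) of an untruncated spectrum.

    ``mode`` selects how many top classes are pooled: two for haplotypes
    (H12), three for multilocus genotypes (G123).  Spectra with fewer classes
    than the pooled count contribute zeros for the missing classes.
    """
    if mode not in ("haplotype", "genotype"):
        raise ValueError("mode must be 'haplotype' or 'genotype'")
    f = np.asarray(full_spectrum, dtype=float)
    if np.any(f < 0) or np.any(np.diff(f) > 1e-12):
        raise ValueError("spectrum must be descending and non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("spectrum must be normalized to sum 1")
    pooled = 2 if mode == "haplotype" else 3
    top = f[:pooled]
    rest = f[pooled:]
    h1 = float(np.sum(f**2))
    h12 = float(top.sum() ** 2 + np.sum(rest**2))
    h2h1 = float((h1 - f[0] ** 2) / h1) if h1 > 0 else 0.0
    return SummaryStats(h1=h1, h12=h12, h2h1=h2h1, mode=mode)
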