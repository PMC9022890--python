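"""Synthetic data with controllable sweep-like spatial structure.

Two generators exercise the scan at different levels:

``sample_model_counts`` draws window count vectors directly from the scan's
own mixture model — window ``i`` is Multinomial(n, g_i(m0, A0, eps0)) — the
exact sampling distribution the likelihood assumes, for parameter-recovery
and null-calibration experiments.

``generate_mosaic_haplotypes`` emits a sequence matrix: each window region
carries K prototype allele strings and every sample copies, per window, the
prototype of a class drawn from g_i(m0, A0, eps0).  Scanning the matrix with
the matching window settings recovers window spectra whose expectations are
the g_i.  The mosaic deliberately omits recombination-driven LD decay within
windows: it targets the model's sufficient statistics (window spectra),
which is all the likelihood consumes.  Realistic sequence evolution is
delegated to external simulators through the VCF interface.

Randomness derives from one root seed; each window owns a deterministic
child stream, so changing the window count never perturbs earlier windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hfs import HaplotypeMatrix
from .lassi import distorted_spectrum, epsilon_grid
from .salti import build_A_grid

__all__ = [
    "default_background",
    "GenerativeModel",
    "sample_model_counts",
    "generate_mosaic_haplotypes",
    "write_vcf",
]


def default_background(K: int = 10) -> np.ndarray:
    """Harmonic-ranked background spectrum p_k proportional to 1/k."""
    p = 1.0 / np.arange(1, K + 1, dtype=float)
    return p / p.sum()


@dataclass
class GenerativeModel:
    """Sampling model for synthetic window spectra.

    Windows sit at coordinates ``spacing * (0..I-1)``; the focal window
    defaults to the center, ``A0`` to the middle of the decay grid implied
    by the spacing, and ``epsilon0`` to the middle of the epsilon grid.
    Defaults (I=201 windows, n=200 sequences, K=10) are the conditions used
    throughout the recovery experiments.
    """

    p: np.ndarray = field(default_factory=default_background)
    m0: int = 2
    A0: float | None = None
    epsilon0: float | None = None
    i_star: int | None = None
    I: int = 201
    spacing: float = 1.0
    n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.I < 2:
            raise ValueError("need at least two windows")
        if not 1 <= self.m0 <= self.K:
            raise ValueError("m0 must be in 1..K")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.i_star is None:
            self.i_star = self.I // 2
        if not 0 <= self.i_star < self.I:
            raise ValueError("focal index out of range")
        grid = self.decay_grid()
        if self.A0 is None:
            self.A0 = float(grid.values[len(grid.values) // 2])
        if not grid.values[0] <= self.A0 <= grid.values[-1]:
            raise ValueError("A0 outside the decay grid implied by the window spacing")
        if self.epsilon0 is None:
            eg = epsilon_grid(self.K, float(self.p[-1]))
            self.epsilon0 = float(eg[len(eg) // 2])

    @property
    def K(self) -> int:
        return self.p.shape[0]

    @property
    def coords(self) -> np.ndarray:
        return np.arange(self.I, dtype=float) * self.spacing

    def decay_grid(self):
        return build_A_grid(coords=self.coords)

    def sweep_spectrum(self) -> np.ndarray:
        """q(m0, epsilon0) at the focal window."""
        return distorted_spectrum(self.p, self.m0, self.epsilon0)

    def window_probs(self) -> np.ndarray:
        """Expected spectra g_i(m0, A0, eps0) for every window, shape (I, K)."""
        q = self.sweep_spectrum()
        alpha = np.exp(-self.A0 * np.abs(self.coords - self.coords[self.i_star]))
        return alpha[:, None] * q + (1.0 - alpha)[:, None] * self.p


def _window_rng(seed: int, stream: int, i: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, i])


def sample_model_counts(model: GenerativeModel) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial window counts from the mixture model.

    Returns (counts, coords): counts is (I, K) with each row drawn as
    Multinomial(n, g_i) then sorted descending (the scan sees ranked
    spectra).  Deterministic given the model seed.
    """
    G = model.window_probs()
    X = np.empty((model.I, model.K), dtype=float)
    for i in range(model.I):
        rng = _window_rng(model.seed, 1, i)
        draw = rng.multinomial(model.n, G[i])
        X[i] = np.sort(draw)[::-1]
    return X, model.coords


def _make_prototypes(
    rng: np.random.Generator, K: int, n_snps: int, maf_floor: int
) -> np.ndarray:
    if maf_floor > K // 2:
        raise ValueError("maf_floor cannot exceed half the class count")
    if n_snps < 2:
        raise ValueError("need at least two SNPs per window")
    for _ in range(1000):
        proto = rng.integers(0, 2, size=(K, n_snps), dtype=np.int8)
        # per-site minor allele count among the prototypes
        ones = proto.sum(axis=0)
        minor = np.minimum(ones, K - ones)
        bad = np.flatnonzero(minor < maf_floor)
        for _ in range(1000):
            if bad.size == 0:
                break
            proto[:, bad] = rng.integers(0, 2, size=(K, bad.size), dtype=np.int8)
            ones = proto.sum(axis=0)
            minor = np.minimum(ones, K - ones)
            bad = np.flatnonzero(minor < maf_floor)
        if len({row.tobytes() for row in proto}) == K:
            return proto
    raise ValueError(
        f"could not draw {K} distinct prototypes of {n_snps} SNPs with "
        f"minor allele count >= {maf_floor}; increase n_snps_per_window"
    )


def generate_mosaic_haplotypes(
    model: GenerativeModel,
    n_snps_per_window: int = 25,
    maf_floor: int = 1,
    pos_spacing_bp: int = 100,
    chrom: str = "1",
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Mosaic sequence matrix whose window spectra have expectation g_i.

    Windows are non-overlapping runs of ``n_snps_per_window`` sites.  Each of
    the ``n`` samples independently draws a class per window from g_i and
    copies that window's prototype string.  Sites that come out monomorphic
    across the sampled matrix are repaired by flipping the allele of one
    sampled class (class counts — the spectra — are unchanged), so a
    polymorphism-filtering reader preserves the window layout.

    Returns the matrix and the (n, I) array of true class labels.
    """
    S = n_snps_per_window
    G = model.window_probs()
    n, I, K = model.n, model.I, model.K
    alleles = np.empty((n, I * S), dtype=np.int8)
    labels = np.empty((n, I), dtype=np.int64)
    for i in range(I):
        proto = _make_prototypes(_window_rng(model.seed, 2, i), K, S, maf_floor)
        lab = _window_rng(model.seed, 3, i).choice(K, size=n, p=G[i])
        labels[:, i] = lab
        block = proto[lab]
        # repair sites monomorphic in the sample without touching class counts
        used, counts = np.unique(lab, return_counts=True)
        for s in np.flatnonzero(np.ptp(block, axis=0) == 0):
            if used.size < 2:
                break  # a single class drawn by every sample: cannot repair
            for c in used[np.argsort(counts, kind="stable")]:
                proto[c, s] ^= 1
                if len({row.tobytes() for row in proto}) == K:
                    block = proto[lab]
                    break
                proto[c, s] ^= 1  # revert: flip collided with another prototype
        alleles[:, i * S : (i + 1) * S] = block
    total = I * S
    pos = (np.arange(total, dtype=np.int64) + 1) * pos_spacing_bp
    matrix = HaplotypeMatrix(
        alleles=alleles,
        chrom=np.full(total, chrom, dtype=object),
        pos_bp=pos,
        phased=True,
        sample_ids=[f"seq{j}" for j in range(n)],
    )
    return matrix, labels


def write_vcf(matrix: HaplotypeMatrix, path) -> None:
    """Write the matrix as a plain-text VCF (REF=A, ALT=T at every site).

    Phased matrices pair consecutive haplotype rows into diploid samples
    (row count must be even); unphased matrices write dosage genotypes.
    """
    if matrix.phased:
        if matrix.n_seq % 2:
            raise ValueError("phased matrix needs an even number of haplotype rows")
        n_samp = matrix.n_seq // 2
        names = [f"ind{j}" for j in range(n_samp)]
    else:
        n_samp = matrix.n_seq
        names = list(matrix.sample_ids) or [f"ind{j}" for j in range(n_samp)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in matrix.chromosomes():
            last = int(matrix.pos_bp[matrix.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={last + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j in range(matrix.n_snp):
            col = matrix.alleles[:, j]
            if matrix.phased:
                gts = [
                    "{}|{}".format(
                        "." if col[2 * s] < 0 else col[2 * s],
                        "." if col[2 * s + 1] < 0 else col[2 * s + 1],
                    )
                    for s in range(n_samp)
                ]
            else:
                dose = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [dose.get(int(c), "./.") for c in col]
            fh.write(
                f"{matrix.chrom[j]}\t{matrix.pos_bp[j]}\t.\tA\tT\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
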