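"""Sliding SNP windows and truncated haplotype/genotype frequency spectra.

Windows are delimited in SNP units (never physical length): a window is a run
of ``winsize`` consecutive polymorphic sites, advanced by ``winstep`` sites,
and never spans a chromosome boundary.  Within a window every sequence (a
haplotype in phased mode, a multilocus genotype in unphased mode) is reduced
to its allele string; the ranked class counts form the window's haplotype
frequency spectrum (HFS).  The likelihood machinery consumes the spectrum
truncated to its ``K`` most frequent classes, rescaled so the truncated
counts still sum to the number of sequences sampled in the window.

The genome-wide background spectrum ``p`` is the unweighted mean of the
normalized truncated spectra over all windows, re-sorted, renormalized, and
floored at ``1/(100K)`` so that ``p_K > 0`` (the floor keeps the lowest
non-sweeping frequency interval well defined downstream).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "WindowSpec",
    "WindowCounts",
    "build_windows",
    "window_class_counts",
    "truncate_and_normalize",
    "genome_background",
    "validate_spectrum",
]


@dataclass
class HaplotypeMatrix:
    """Allele-coded sequence matrix with per-SNP genomic metadata.

    Rows are sequences: the ``2n`` haplotypes of ``n`` diploids in phased
    mode, or ``n`` multilocus genotypes in unphased mode.  Columns are SNPs.
    Codes are 0/1 for haplotypes, 0/1/2 (alt-allele dosage) for genotypes,
    and :data:`MISSING` (-1) for missing calls.
    """

    alleles: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    phased: bool
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix (sequences x SNPs)")
        if self.alleles.shape[1] != self.pos_bp.shape[0]:
            raise ValueError("pos_bp length must match SNP count")
        if self.chrom.shape[0] != self.pos_bp.shape[0]:
            raise ValueError("chrom length must match SNP count")
        hi = 1 if self.phased else 2
        bad = (self.alleles > hi) | (self.alleles < MISSING)
        if bad.any():
            raise ValueError(f"allele codes must be in [{MISSING}, {hi}]")
        for c in self.chromosomes():
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {c!r}")

    @property
    def n_seq(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class WindowSpec:
    """One SNP-delimited analysis window.

    ``first_snp``/``last_snp`` are 0-based inclusive column indices into the
    full SNP matrix.  ``index`` is the 1-based genome-wide window id;
    ``chrom_ordinal`` the 1-based rank within the chromosome (the coordinate
    in the "window number" distance measure).  ``z`` holds the coordinate in
    the active distance measure once assigned.
    """

    index: int
    chrom: object
    first_snp: int
    last_snp: int
    chrom_ordinal: int
    start_bp: int
    end_bp: int
    z: float | None = None

    @property
    def n_snps(self) -> int:
        return self.last_snp - self.first_snp + 1


@dataclass
class WindowCounts:
    """K-truncated, descending class counts for one window.

    ``x`` holds real-valued counts (the top-K counts are proportionally
    rescaled so they sum to ``n``, the number of sequences retained in the
    window); ``n_distinct`` is the number of distinct classes seen before
    truncation.
    """

    x: np.ndarray
    n: float
    n_distinct: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(np.diff(self.x) > 0):
            raise ValueError("truncated counts must be descending")
        if np.any(self.x < 0):
            raise ValueError("counts must be non-negative")
        if self.n > 0 and abs(self.x.sum() - self.n) > 1e-9 * max(1.0, self.n):
            raise ValueError("truncated counts must sum to n")

    @property
    def spectrum(self) -> np.ndarray:
        """Normalized truncated spectrum x / n."""
        return self.x / self.n


def validate_spectrum(freq: np.ndarray, *, atol: float = 1e-12) -> np.ndarray:
    """Check that ``freq`` is a descending probability vector; return it as float array."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 0):
        raise ValueError("spectrum entries must be non-negative")
    if np.any(np.diff(freq) > atol):
        raise ValueError("spectrum must be sorted descending")
    if abs(freq.sum() - 1.0) > 1e-9:
        raise ValueError(f"spectrum must sum to 1 (got {freq.sum()!r})")
    return freq


def build_windows(matrix: HaplotypeMatrix, winsize: int, winstep: int) -> list[WindowSpec]:
    """Enumerate SNP-delimited windows per chromosome.

    Per chromosome, windows start at SNP offsets 0, winstep, 2*winstep, ...
    for as long as a full ``winsize`` window fits; trailing partial windows
    are not emitted, and windows never span chromosomes.
    """
    if winsize < 2:
        raise ValueError("winsize must be >= 2")
    if winstep < 1:
        raise ValueError("winstep must be >= 1")
    chrom_sizes = {c: int(np.sum(matrix.chrom == c)) for c in matrix.chromosomes()}
    if not any(sz >= winsize for sz in chrom_sizes.values()):
        raise ValueError(
            f"no chromosome has >= {winsize} SNPs (chromosome sizes: {chrom_sizes})"
        )
    windows: list[WindowSpec] = []
    idx = 1
    for c in matrix.chromosomes():
        cols = np.flatnonzero(matrix.chrom == c)
        n = len(cols)
        ordinal = 1
        for off in range(0, n - winsize + 1, winstep):
            first = int(cols[off])
            last = int(cols[off + winsize - 1])
            windows.append(
                WindowSpec(
                    index=idx,
                    chrom=c,
                    first_snp=first,
                    last_snp=last,
                    chrom_ordinal=ordinal,
                    start_bp=int(matrix.pos_bp[first]),
                    end_bp=int(matrix.pos_bp[last]),
                )
            )
            idx += 1
            ordinal += 1
    return windows


def window_class_counts(matrix: HaplotypeMatrix, window: WindowSpec) -> dict[str, int]:
    """Tally allele-string classes for the rows of one window.

    Rows containing any missing call within the window are dropped.  The
    returned mapping is ordered by descending count, ties broken by
    lexicographic class string, so iteration order is deterministic.
    """
    block = matrix.alleles[:, window.first_snp : window.last_snp + 1]
    keep = ~np.any(block == MISSING, axis=1)
    if not keep.any():
        raise ValueError(
            f"window {window.index} ({window.chrom}:{window.start_bp}-{window.end_bp}) "
            "has no rows without missing data"
        )
    counts = Counter("".join(map(str, row)) for row in block[keep])
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return dict(ordered)


def truncate_and_normalize(raw_counts: dict[str, int], K: int) -> WindowCounts:
    """Keep the K largest class counts, rescaled to preserve the window total.

    The truncated vector is multiplied by ``n / sum(top-K)`` so it sums
    exactly to ``n`` (the number of sequences tallied); fewer than K distinct
    classes are padded with zeros (no rescale needed since nothing was cut).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not raw_counts:
        raise ValueError("raw_counts must be non-empty")
    vals = sorted(raw_counts.values(), reverse=True)
    n = float(sum(vals))
    top = np.zeros(K, dtype=float)
    kept = vals[:K]
    top[: len(kept)] = kept
    retained = top.sum()
    if retained < n:
        top *= n / retained
    return WindowCounts(x=top, n=n, n_distinct=len(vals))


def genome_background(
    all_window_counts: list[WindowCounts], K: int, *, floor: float | None = None
) -> np.ndarray:
    """Genome-wide background spectrum p.

    The unweighted mean over windows of each normalized truncated spectrum,
    re-sorted descending, renormalized, then floored at ``1/(100K)`` and
    renormalized once more so that ``p_K > 0``.
    """
    if not all_window_counts:
        raise ValueError("need at least one window to form the background spectrum")
    mat = np.stack([wc.spectrum for wc in all_window_counts])
    if mat.shape[1] != K:
        raise ValueError("window counts truncation level does not match K")
    p = mat.mean(axis=0)
    p = np.sort(p)[::-1]
    p = p / p.sum()
    if floor is None:
        floor = 1.0 / (100.0 * K)
    p = np.maximum(p, floor)
    p = p / p.sum()
    return p
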