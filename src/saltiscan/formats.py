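"""File formats: VCF input, BED masks, genetic maps, and the results table.

VCF positions are 1-based; BED mask intervals are 0-based half-open, and a
SNP is dropped when its position falls inside a mask interval.  Genetic maps
are whitespace-delimited tables of (chromosome, position bp, map cM) anchors
— a rate column, if present (the common four-column dialect), is ignored.
Queries between anchors are linearly interpolated; queries beyond the first
or last anchor clamp to the boundary cM value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hfs import MISSING, HaplotypeMatrix, WindowSpec

__all__ = [
    "GeneticMap",
    "read_genetic_map",
    "interpolate_cm",
    "read_bed_mask",
    "read_variants",
    "window_coordinates",
    "SCAN_COLUMNS",
    "write_scan_table",
    "read_scan_table",
]

SCAN_COLUMNS = [
    "chrom",
    "win_id",
    "start_bp",
    "end_bp",
    "mid",
    "n_snps",
    "n_obs",
    "n_distinct",
    "h12_or_g123",
    "h2h1_or_g2g1",
    "T",
    "m_hat_T",
    "lambda",
    "m_hat",
    "log10_A_hat",
    "eps_hat",
]


@dataclass
class GeneticMap:
    """Per-chromosome (pos_bp, cM) anchor tables, cM non-decreasing in pos_bp."""

    anchors: dict = field(default_factory=dict)  # chrom -> (pos array, cm array)

    def add(self, chrom, pos_bp: np.ndarray, cm: np.ndarray) -> None:
        order = np.argsort(pos_bp, kind="stable")
        pos_bp = np.asarray(pos_bp, dtype=float)[order]
        cm = np.asarray(cm, dtype=float)[order]
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"cM not non-decreasing on chromosome {chrom!r}")
        self.anchors[str(chrom)] = (pos_bp, cm)


def read_genetic_map(path) -> GeneticMap:
    """Read a whitespace-delimited genetic map.

    Three columns are read as (chrom, pos_bp, cM); four or more as the
    HapMap-style (chrom, pos_bp, rate, cM) with the rate ignored.  A header
    line (non-numeric position field) is skipped.
    """
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                pos = float(parts[1])
            except (ValueError, IndexError):
                continue  # header
            cm = float(parts[2]) if len(parts) == 3 else float(parts[3])
            rows.setdefault(parts[0], []).append((pos, cm))
    gmap = GeneticMap()
    for chrom, pts in rows.items():
        arr = np.array(pts)
        gmap.add(chrom, arr[:, 0], arr[:, 1])
    return gmap


def interpolate_cm(gmap: GeneticMap, chrom, pos_bp) -> np.ndarray | float:
    """cM position(s) for bp queries: linear between anchors, clamped beyond ends."""
    key = str(chrom)
    if key not in gmap.anchors:
        raise KeyError(
            f"chromosome {key!r} absent from genetic map "
            f"(available: {sorted(gmap.anchors)})"
        )
    pos, cm = gmap.anchors[key]
    if len(pos) < 2:
        raise ValueError(f"genetic map needs >= 2 anchors on chromosome {key!r}")
    out = np.interp(np.asarray(pos_bp, dtype=float), pos, cm)
    return float(out) if np.isscalar(pos_bp) else out


def read_bed_mask(path) -> dict:
    """BED intervals per chromosome as sorted (starts, ends) arrays (0-based half-open)."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] in ("track", "browser") or parts[0].startswith("#"):
                continue
            rows.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    mask = {}
    for chrom, iv in rows.items():
        iv.sort()
        arr = np.array(iv, dtype=np.int64)
        mask[chrom] = (arr[:, 0], arr[:, 1])
    return mask


def _masked(mask: dict, chrom: str, pos_1based: int) -> bool:
    if mask is None or chrom not in mask:
        return False
    starts, ends = mask[chrom]
    i = int(np.searchsorted(starts, pos_1based - 1, side="right")) - 1
    return i >= 0 and pos_1based - 1 < ends[i]


_SNP_ALLELES = frozenset("ACGT")


def read_variants(path, mode: str = "phased", mask: dict | None = None) -> HaplotypeMatrix:
    """Load biallelic, sample-polymorphic SNPs from a VCF into a sequence matrix.

    Phased mode splits each diploid genotype into two haplotype rows and
    requires the phase separator ``|`` on every non-missing call; unphased
    mode encodes each site as the alt-allele dosage 0/1/2 per individual.
    Missing genotypes become the missing sentinel.  Multi-allelic and
    non-SNP records are dropped, as are sites overlapping the mask.
    """
    from cyvcf2 import VCF

    if mode not in ("phased", "unphased"):
        raise ValueError("mode must be 'phased' or 'unphased'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    chroms: list[str] = []
    pos: list[int] = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        if v.REF not in _SNP_ALLELES or v.ALT[0] not in _SNP_ALLELES:
            continue
        if _masked(mask, v.CHROM, v.POS):
            continue
        gts = v.genotypes  # per sample: [allele0, allele1, phased] (diploid)
        if mode == "phased":
            col = np.empty(2 * len(gts), dtype=np.int8)
            for si, g in enumerate(gts):
                a0, a1, phased_flag = g[0], g[1], g[-1]
                missing = a0 < 0 or a1 < 0
                if not missing and not phased_flag:
                    raise ValueError(
                        f"unphased genotype for sample {samples[si]} at "
                        f"{v.CHROM}:{v.POS} in phased mode"
                    )
                col[2 * si] = MISSING if a0 < 0 else a0
                col[2 * si + 1] = MISSING if a1 < 0 else a1
        else:
            col = np.empty(len(gts), dtype=np.int8)
            for si, g in enumerate(gts):
                a0, a1 = g[0], g[1]
                col[si] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        total = int(obs.sum())
        limit = obs.size if mode == "phased" else 2 * obs.size
        if total == 0 or total == limit:
            continue  # monomorphic in the sample
        cols.append(col)
        chroms.append(v.CHROM)
        pos.append(v.POS)
    if not cols:
        raise ValueError(f"no biallelic polymorphic SNPs left after filters in {path}")
    alleles = np.column_stack(cols)
    row_ids = (
        [f"{s}_{h}" for s in samples for h in (1, 2)] if mode == "phased" else samples
    )
    return HaplotypeMatrix(
        alleles=alleles,
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        phased=(mode == "phased"),
        sample_ids=row_ids,
    )


def window_coordinates(
    windows: list[WindowSpec], measure: str = "bp", gmap: GeneticMap | None = None
) -> np.ndarray:
    """Assign the coordinate z_i of each window under the chosen distance measure.

    bp: midpoint of the window's first/last SNP positions; cm: that midpoint
    interpolated through the genetic map; windex: the window's 1-based
    ordinal within its chromosome.  Coordinates are also stored on the
    ``WindowSpec.z`` field.
    """
    if measure == "bp":
        z = np.array([(w.start_bp + w.end_bp) / 2.0 for w in windows])
    elif measure == "cm":
        if gmap is None:
            raise ValueError("cm distance measure requires a genetic map")
        z = np.array(
            [
                interpolate_cm(gmap, w.chrom, (w.start_bp + w.end_bp) / 2.0)
                for w in windows
            ]
        )
    elif measure == "windex":
        z = np.array([float(w.chrom_ordinal) for w in windows])
    else:
        raise ValueError("measure must be 'bp', 'cm', or 'windex'")
    for w, zi in zip(windows, z):
        w.z = float(zi)
    return z


def write_scan_table(rows: pd.DataFrame, path) -> None:
    """Write the 16-column scan results TSV (floats at 6 significant digits)."""
    df = rows.loc[:, SCAN_COLUMNS]
    df = df.sort_values(["chrom", "win_id"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scan_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
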