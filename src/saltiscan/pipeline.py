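"""End-to-end scan orchestration shared by the CLI and the library API."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import formats, hfs, salti, summaries
from .lassi import lassi_T

__all__ = ["scan_matrix"]

log = logging.getLogger("saltiscan")


def scan_matrix(
    matrix: hfs.HaplotypeMatrix,
    winsize: int = 201,
    winstep: int = 100,
    K: int = 20,
    measure: str = "bp",
    gmap: formats.GeneticMap | None = None,
    targets: list[int] | None = None,
) -> pd.DataFrame:
    """Run the full scan on a sequence matrix; one result row per target window.

    Builds SNP-delimited windows, computes each window's truncated spectrum
    and homozygosity summaries, estimates the genome-wide background p,
    fits the non-spatial T statistic and the spatial Lambda scan at every
    target window, and returns the 16-column results table.
    """
    windows = hfs.build_windows(matrix, winsize, winstep)
    z = formats.window_coordinates(windows, measure=measure, gmap=gmap)
    chroms = np.array([w.chrom for w in windows], dtype=object)

    counts = []
    stats = []
    mode = "haplotype" if matrix.phased else "genotype"
    for w in windows:
        raw = hfs.window_class_counts(matrix, w)
        wc = hfs.truncate_and_normalize(raw, K)
        counts.append(wc)
        full = np.array(sorted(raw.values(), reverse=True), dtype=float)
        stats.append(summaries.homozygosity_stats(full / full.sum(), mode))

    p = hfs.genome_background(counts, K)
    grids = salti.make_grids(p, windows=windows)
    log.info(
        "scan: %d windows, K=%d, measure=%s, d_min=%g, A grid [%g, %g]",
        len(windows),
        K,
        measure,
        grids.A.d_min,
        grids.A.A_min,
        grids.A.A_max,
    )

    X = np.stack([wc.x for wc in counts])
    fits = salti.salti_scan(X, z, p, grids, targets=targets, chroms=chroms)

    rows = []
    for fit in fits:
        i = fit.target
        w, wc, st = windows[i], counts[i], stats[i]
        T, m_T, _eps_T = lassi_T(wc.x, p, grids.Q, grids.eps_grid)
        rows.append(
            {
                "chrom": w.chrom,
                "win_id": w.index,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "mid": w.z,
                "n_snps": w.n_snps,
                "n_obs": wc.n,
                "n_distinct": wc.n_distinct,
                "h12_or_g123": st.h12,
                "h2h1_or_g2g1": st.h2h1,
                "T": T,
                "m_hat_T": m_T,
                "lambda": fit.Lambda,
                "m_hat": fit.m_hat,
                "log10_A_hat": float(np.log10(fit.A_hat)),
                "eps_hat": fit.eps_hat,
            }
        )
    return pd.DataFrame(rows, columns=formats.SCAN_COLUMNS)
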