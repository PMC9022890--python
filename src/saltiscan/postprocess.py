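"""Empirical calibration and region calling on scan results.

Significance thresholds are taken from the pooled per-window Lambda values
of neutral replicate scans (the genome-wide maximum and the top 0.1%, 1%,
and 5% quantiles, linear interpolation between order statistics).  Windows
from simulated genomes, whose SNP-delimited windows never align exactly with
the real data's, are projected onto the real windows by a bp-overlap
weighted mean.  Windows exceeding a threshold are concatenated into regions
over maximal runs of consecutive window indices within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "neutral_thresholds",
    "align_sim_windows",
    "call_regions",
    "write_regions",
]

REGION_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "m_hat",
    "log10_A_hat",
    "max_lambda",
    "n_windows",
]


@dataclass
class Region:
    """A run of consecutive significant windows."""

    chrom: object
    start_bp: int
    end_bp: int
    m_hat: int
    log10_A_hat: float
    max_lambda: float
    window_ids: list[int]

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)


def _lambda_values(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table["lambda"].to_numpy(dtype=float)
    return np.asarray(table, dtype=float).ravel()


def neutral_thresholds(replicate_lambda_tables) -> dict[str, float]:
    """Pool per-window Lambda over replicates; return max and upper quantiles.

    Quantiles use linear interpolation between order statistics.
    """
    pools = [_lambda_values(t) for t in replicate_lambda_tables]
    if not pools:
        raise ValueError("no replicate tables provided")
    pool = np.concatenate(pools)
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError("pooled Lambda values are empty")
    q = np.quantile(pool, [0.999, 0.99, 0.95], method="linear")
    return {
        "max": float(pool.max()),
        "top_0.1pct": float(q[0]),
        "top_1pct": float(q[1]),
        "top_5pct": float(q[2]),
    }


def align_sim_windows(sim_rows: pd.DataFrame, real_windows: pd.DataFrame) -> np.ndarray:
    """Project simulated windows onto real windows by bp-overlap weighted mean.

    Both frames need chrom, start_bp, end_bp columns and sim_rows a lambda
    column; intervals are bp-inclusive.  Real windows with no overlapping
    simulated window get NaN.
    """
    out = np.full(len(real_windows), np.nan)
    for chrom, sim_c in sim_rows.groupby("chrom", sort=False):
        ss = sim_c["start_bp"].to_numpy(dtype=float)
        se = sim_c["end_bp"].to_numpy(dtype=float)
        sl = sim_c["lambda"].to_numpy(dtype=float)
        sel = np.flatnonzero(real_windows["chrom"].to_numpy() == chrom)
        for ri in sel:
            rs = float(real_windows["start_bp"].iloc[ri])
            re = float(real_windows["end_bp"].iloc[ri])
            ov = np.minimum(se, re) - np.maximum(ss, rs) + 1.0
            w = np.clip(ov, 0.0, None)
            tot = w.sum()
            if tot > 0:
                out[ri] = float((w * sl).sum() / tot)
    return out


def call_regions(rows: pd.DataFrame, threshold: float) -> list[Region]:
    """Group windows with Lambda > threshold into runs of consecutive indices.

    Consecutive means adjacent window ids within a chromosome.  The region's
    reported m_hat / log10_A_hat come from its maximum-Lambda member window
    (ties resolved toward the smaller window id).
    """
    regions: list[Region] = []
    df = rows.sort_values(["chrom", "win_id"], kind="stable")
    for _, chrom_df in df.groupby("chrom", sort=False):
        sig = chrom_df[chrom_df["lambda"] > threshold]
        if sig.empty:
            continue
        ids = sig["win_id"].to_numpy(dtype=int)
        breaks = np.flatnonzero(np.diff(ids) != 1) + 1
        for run in np.split(np.arange(len(ids)), breaks):
            members = sig.iloc[run]
            best = members.loc[members["lambda"].idxmax()]
            regions.append(
                Region(
                    chrom=members["chrom"].iloc[0],
                    start_bp=int(members["start_bp"].min()),
                    end_bp=int(members["end_bp"].max()),
                    m_hat=int(best["m_hat"]),
                    log10_A_hat=float(best["log10_A_hat"]),
                    max_lambda=float(best["lambda"]),
                    window_ids=[int(i) for i in members["win_id"]],
                )
            )
    return regions


def write_regions(regions: list[Region], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "m_hat": r.m_hat,
                "log10_A_hat": r.log10_A_hat,
                "max_lambda": r.max_lambda,
                "n_windows": r.n_windows,
            }
            for r in regions
        ],
        columns=REGION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
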