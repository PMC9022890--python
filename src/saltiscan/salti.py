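"""Spatial mixture model and the composite likelihood-ratio scan (Lambda).

The sweep's effect on a flanking window ``i`` decays exponentially with
distance from the target window ``i*``:

    alpha_i(A) = exp(-A |z_i - z_i*|)

and the expected truncated spectrum in window ``i`` is the mixture

    g_ik(m, A) = alpha_i(A) q_k(m) + [1 - alpha_i(A)] p_k .

The composite log likelihoods sum over the window set W:

    log L0 = sum_i sum_k x_ik ln p_k
    log L1 = sum_i sum_k x_ik ln g_ik(m, A)

and the scan statistic at target ``i*`` is
``Lambda = 2 [max_{m, eps, A} log L1 - log L0]`` with the argmax reported as
``(m_hat, A_hat, eps_hat)``.  The decay-rate grid runs over 100 log-spaced
values from ``A_min = -ln(0.99999)/d_min`` (effect barely decays between the
two closest windows) to ``A_max = -ln(0.00001)/d_min`` (effect is gone one
window away), where ``d_min`` is the smallest inter-window distance
genome-wide.

Windows on other chromosomes than the target contribute identical terms to
L0 and L1 and cancel in Lambda; the scan therefore sums only over the
target's chromosome.

The scan's vectorized evaluation aggregates counts over windows sharing an
inter-window distance before contracting with the log-mixture table.  This
is an exact regrouping of the naive triple-loop sum over the (m, eps, A)
grid — no window is skipped or approximated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hfs import WindowSpec
from .lassi import epsilon_grid, precompute_q

__all__ = [
    "DecayGrid",
    "ScanGrids",
    "SweepFit",
    "decay_alpha",
    "build_A_grid",
    "mixture_spectrum",
    "loglik_null",
    "loglik_alt",
    "make_grids",
    "salti_scan",
]

# Cap on elements in one log-mixture slab, to bound transient memory.
_SLAB_ELEMS = 8_000_000


@dataclass
class DecayGrid:
    """Log-spaced decay-rate grid anchored at the minimum inter-window distance."""

    d_min: float
    values: np.ndarray

    @property
    def A_min(self) -> float:
        return float(self.values[0])

    @property
    def A_max(self) -> float:
        return float(self.values[-1])


@dataclass
class ScanGrids:
    """Precomputed parameter grids shared by every target window."""

    p: np.ndarray
    eps_grid: np.ndarray
    A: DecayGrid
    Q: np.ndarray  # (K, E, K): Q[m-1, e] = q(m, eps_grid[e])

    @property
    def K(self) -> int:
        return self.p.shape[0]


@dataclass
class SweepFit:
    """Per-target-window scan output."""

    target: int
    Lambda: float
    m_hat: int
    A_hat: float
    eps_hat: float


def decay_alpha(A: float, z_i: float, z_star: float) -> float:
    """Sweep mixture proportion exp(-A |z_i - z_star|)."""
    if A <= 0:
        raise ValueError("decay rate A must be positive")
    return float(np.exp(-A * abs(z_i - z_star)))


def _min_adjacent_distance(coords: np.ndarray, chroms: np.ndarray | None) -> float:
    coords = np.asarray(coords, dtype=float)
    if chroms is None:
        chroms = np.zeros(len(coords), dtype=int)
    chroms = np.asarray(chroms, dtype=object)
    d_min = np.inf
    for c in dict.fromkeys(chroms):
        z = coords[chroms == c]
        if len(z) >= 2:
            d_min = min(d_min, float(np.min(np.diff(z))))
    if not np.isfinite(d_min):
        raise ValueError("need at least two windows on some chromosome to build the A grid")
    if d_min <= 0:
        raise ValueError(
            "duplicate window coordinates (d_min = 0); deduplicate window midpoints "
            "or switch distance measure"
        )
    return d_min


def build_A_grid(
    windows: list[WindowSpec] | None = None,
    *,
    coords: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
    n_steps: int = 100,
) -> DecayGrid:
    """Decay grid from window coordinates: 100 log-spaced values, endpoints included."""
    if windows is not None:
        coords = np.array([w.z for w in windows], dtype=float)
        chroms = np.array([w.chrom for w in windows], dtype=object)
    if coords is None:
        raise ValueError("provide windows or coords")
    d_min = _min_adjacent_distance(coords, chroms)
    a_min = -np.log(0.99999) / d_min
    a_max = -np.log(0.00001) / d_min
    values = np.exp(np.linspace(np.log(a_min), np.log(a_max), n_steps))
    values[0], values[-1] = a_min, a_max
    return DecayGrid(d_min=d_min, values=values)


def mixture_spectrum(p: np.ndarray, q: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination alpha*q + (1-alpha)*p."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * np.asarray(q, float) + (1.0 - alpha) * np.asarray(p, float)


def loglik_null(window_counts: np.ndarray, p: np.ndarray) -> float:
    """log L0 = sum_i sum_k x_ik ln p_k."""
    X = np.atleast_2d(np.asarray(window_counts, dtype=float))
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) & (X.sum(axis=0) > 0)):
        raise ValueError("p has a zero entry with positive observed counts")
    return float(X.sum(axis=0) @ np.log(p))


def loglik_alt(
    window_counts: np.ndarray,
    window_coords: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    A: float,
    i_star: int,
) -> float:
    """log L1 = sum_i sum_k x_ik ln g_ik for one (q, A) parameter point."""
    X = np.atleast_2d(np.asarray(window_counts, dtype=float))
    z = np.asarray(window_coords, dtype=float)
    alpha = np.exp(-A * np.abs(z - z[i_star]))
    g = alpha[:, None] * np.asarray(q, float) + (1.0 - alpha)[:, None] * np.asarray(p, float)
    return float(np.sum(X * np.log(g)))


def make_grids(
    p: np.ndarray,
    *,
    windows: list[WindowSpec] | None = None,
    coords: np.ndarray | None = None,
    chroms: np.ndarray | None = None,
    n_eps: int = 100,
    n_A: int = 100,
) -> ScanGrids:
    """Bundle the epsilon grid, decay grid, and precomputed q table."""
    p = np.asarray(p, dtype=float)
    eps = epsilon_grid(p.shape[0], float(p[-1]), n_eps)
    A = build_A_grid(windows, coords=coords, chroms=chroms, n_steps=n_A)
    Q = precompute_q(p, eps)
    return ScanGrids(p=p, eps_grid=eps, A=A, Q=Q)


def _scan_block(
    Xc: np.ndarray,
    zc: np.ndarray,
    block: np.ndarray,
    grids: ScanGrids,
    logp: np.ndarray,
    L0: float,
) -> list[tuple[int, float, int, float, float]]:
    """Fit every target in ``block`` (local indices into one chromosome)."""
    K = grids.K
    QF = grids.Q.reshape(-1, K)  # (G, K), m-major then epsilon
    G = QF.shape[0]
    E = len(grids.eps_grid)
    A_values = grids.A.values
    nA = len(A_values)
    B = len(block)

    dist = np.abs(zc[block][:, None] - zc[None, :])  # (B, Ic)
    du, inv = np.unique(dist, return_inverse=True)
    inv = inv.reshape(B, -1)
    J = len(du)
    C = np.zeros((B, J, K))
    for b in range(B):
        np.add.at(C[b], inv[b], Xc)

    ll = np.empty((nA, B, G))
    row_chunk = max(1, _SLAB_ELEMS // (G * K))
    for ai, Aval in enumerate(A_values):
        u = np.exp(-Aval * du)
        nz = u > 0.0
        if nz.all():
            base = np.zeros(B)
        else:
            # alpha underflowed to exactly 0: the mixture is exactly p there
            base = C[:, ~nz, :].sum(axis=1) @ logp
        un = u[nz]
        Cn = C[:, nz, :]
        acc = np.zeros((B, G))
        for s in range(0, len(un), row_chunk):
            uc = un[s : s + row_chunk]
            g = uc[:, None, None] * QF[None, :, :] + (1.0 - uc)[:, None, None] * grids.p
            lg = np.log(g).transpose(0, 2, 1).reshape(len(uc) * K, G)
            acc += Cn[:, s : s + row_chunk, :].reshape(B, len(uc) * K) @ lg
        ll[ai] = acc + base[:, None]

    out = []
    for b, t in enumerate(block):
        # (m, A, eps) priority order: first max in C order is the tie-break winner
        arr = ll[:, b, :].reshape(nA, K, E).transpose(1, 0, 2)
        flat = int(np.argmax(arr))
        mi, rem = divmod(flat, nA * E)
        ai, ei = divmod(rem, E)
        lam = 2.0 * (float(arr.flat[flat]) - L0)
        out.append((int(t), lam, mi + 1, float(A_values[ai]), float(grids.eps_grid[ei])))
    return out


def salti_scan(
    window_counts: np.ndarray,
    window_coords: np.ndarray,
    p: np.ndarray,
    grids: ScanGrids,
    targets: np.ndarray | list[int] | None = None,
    chroms: np.ndarray | None = None,
    *,
    block_size: int = 64,
) -> list[SweepFit]:
    """Composite likelihood-ratio scan over target windows.

    Parameters
    ----------
    window_counts
        (I, K) truncated counts, one row per window.
    window_coords
        Window coordinates z_i in the active distance measure.
    targets
        Indices (into the window arrays) to fit; all windows by default.
    chroms
        Optional per-window chromosome labels; the likelihood for a target
        sums only over its own chromosome (terms elsewhere cancel in Lambda).

    Ties in the grid maximum break toward smallest m, then smallest A, then
    smallest epsilon.  Lambda is unfloored.
    """
    X = np.atleast_2d(np.asarray(window_counts, dtype=float))
    z = np.asarray(window_coords, dtype=float)
    I = X.shape[0]
    if z.shape[0] != I:
        raise ValueError("coords and counts disagree on window count")
    if targets is None:
        targets = np.arange(I)
    targets = np.asarray(targets, dtype=int)
    if targets.size and (targets.min() < 0 or targets.max() >= I):
        raise ValueError(f"target index out of range 0..{I - 1}")
    if chroms is None:
        chroms = np.zeros(I, dtype=int)
    chroms = np.asarray(chroms, dtype=object)
    logp = np.log(np.asarray(p, dtype=float))

    results: dict[int, SweepFit] = {}
    for c in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == c)
        tsel = targets[np.isin(targets, sel)]
        if tsel.size == 0:
            continue
        Xc = X[sel]
        zc = z[sel]
        L0 = float(Xc.sum(axis=0) @ logp)
        loc = np.searchsorted(sel, tsel)
        for s in range(0, len(loc), block_size):
            block = loc[s : s + block_size]
            for t_loc, lam, m_hat, A_hat, eps_hat in _scan_block(
                Xc, zc, block, grids, logp, L0
            ):
                gi = int(sel[t_loc])
                results[gi] = SweepFit(
                    target=gi, Lambda=lam, m_hat=m_hat, A_hat=A_hat, eps_hat=eps_hat
                )
    return [results[int(t)] for t in targets]
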