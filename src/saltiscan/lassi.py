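"""Single-window sweep-distortion model and the T statistic.

A sweep with ``m`` sweeping classes distorts the background spectrum ``p``
into ``q(m)``: the non-sweeping classes ``k = m+1..K`` are interpolated
linearly between the anchor frequency ``U = p_K`` and a free parameter
``epsilon`` (the lowest non-sweeping frequency), and the mass they shed is
redistributed to the ``m`` sweeping classes in proportions
``f_k = e^{-k} / sum_{j=1}^{m} e^{-j}``:

    q_k(m) = p_k + f_k * sum_{j=m+1}^{K} (p_j - q_j(m))      k = 1..m
    q_k(m) = U - (k - m - 1) / (K - m - 1) * (U - epsilon)   k = m+1..K

Edge cases: for ``m = K-1`` the single tail class takes ``q_K = epsilon``;
for ``m = K`` there is no tail and ``q = p`` (the grid point is equivalent
to the null, kept for completeness).

The non-spatial T statistic is the likelihood-ratio machinery restricted to
one window: ``T = 2 [max_{m, eps} sum_k x_k ln q_k - sum_k x_k ln p_k]``,
maximized on the same ``m`` and ``epsilon`` grids as the spatial scan.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sweep_mass_weights",
    "distorted_spectrum",
    "epsilon_grid",
    "precompute_q",
    "lassi_T",
]


def sweep_mass_weights(m: int) -> np.ndarray:
    """Exponential mass weights f_k = e^{-k} / sum_{j<=m} e^{-j}, k = 1..m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    w = np.exp(-np.arange(1, m + 1, dtype=float))
    return w / w.sum()


def distorted_spectrum(
    p: np.ndarray, m: int, epsilon: float, U: float | None = None
) -> np.ndarray:
    """Spectrum q(m) distorted by ``m`` sweeping classes.

    ``U`` defaults to ``p_K``; ``epsilon`` must lie in ``(0, U]``.
    """
    p = np.asarray(p, dtype=float)
    K = p.shape[0]
    if not 1 <= m <= K:
        raise ValueError(f"m must be in 1..{K}")
    if U is None:
        U = float(p[-1])
    if U <= 0:
        raise ValueError("anchor frequency U must be positive")
    if not 0 < epsilon <= U * (1 + 1e-12):
        raise ValueError(f"epsilon must be in (0, U={U}]")
    q = p.copy()
    if m < K:
        if K - m == 1:
            tail = np.array([epsilon], dtype=float)
        else:
            k = np.arange(m + 1, K + 1, dtype=float)
            tail = U - (k - m - 1) / (K - m - 1) * (U - epsilon)
        freed = float(np.sum(p[m:] - tail))
        q[m:] = tail
        q[:m] = p[:m] + sweep_mass_weights(m) * freed
    return q


def epsilon_grid(K: int, U: float, n_steps: int = 100) -> np.ndarray:
    """Equally spaced epsilon values on [1/(100K), U].

    If the background floor left ``U`` at or below ``1/(100K)`` the interval
    is empty and the grid collapses to the single point ``{U}``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    lo = 1.0 / (100.0 * K)
    if U <= lo:
        return np.array([U], dtype=float)
    return np.linspace(lo, U, n_steps)


def precompute_q(p: np.ndarray, eps_grid: np.ndarray) -> np.ndarray:
    """Distorted spectra for every grid point, shape (K, E, K).

    ``Q[m-1, e]`` is ``q(m, eps_grid[e])``; computed once and reused across
    target windows.
    """
    p = np.asarray(p, dtype=float)
    K = p.shape[0]
    U = float(p[-1])
    E = len(eps_grid)
    Q = np.empty((K, E, K), dtype=float)
    for mi in range(K):
        for ei, eps in enumerate(eps_grid):
            Q[mi, ei] = distorted_spectrum(p, mi + 1, float(eps), U)
    return Q


def lassi_T(
    x: np.ndarray, p: np.ndarray, Q: np.ndarray, eps_grid: np.ndarray
) -> tuple[float, int, float]:
    """Single-window likelihood-ratio statistic T with its (m, epsilon) argmax.

    Ties in the grid maximum are broken toward the smallest m, then the
    smallest epsilon.  T is reported unfloored.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape[0] != p.shape[0]:
        raise ValueError("x and p must share the truncation level K")
    if np.any((p <= 0) & (x > 0)):
        raise ValueError("p has a zero entry with positive observed count")
    ll = np.einsum("mek,k->me", np.log(Q), x)
    l0 = float(x @ np.log(p))
    flat = int(np.argmax(ll))
    mi, ei = divmod(flat, ll.shape[1])
    T = 2.0 * (float(ll.flat[flat]) - l0)
    return T, mi + 1, float(eps_grid[ei])
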