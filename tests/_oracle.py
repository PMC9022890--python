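"""Literal triple-loop grid evaluation of the spatial scan, for cross-checks.

Loops over the full (m, A, epsilon) grid in tie-break priority order and
keeps the first strict maximum, exactly as the scan's contract requires.
Deliberately naive; independent of the package's vectorized path.
"""

import numpy as np

from saltiscan.lassi import distorted_spectrum


def oracle_fit(X, z, p, eps_grid, A_values, i_star):
    """(Lambda, m_hat, A_index, eps_index) by exhaustive grid evaluation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    K = p.shape[0]
    L0 = float(X.sum(axis=0) @ np.log(p))
    qs = {
        (m, ei): distorted_spectrum(p, m, float(e))
        for m in range(1, K + 1)
        for ei, e in enumerate(eps_grid)
    }
    dist = np.abs(z - z[i_star])
    best = None
    for m in range(1, K + 1):
        for ai, A in enumerate(A_values):
            alpha = np.exp(-A * dist)
            for ei in range(len(eps_grid)):
                q = qs[(m, ei)]
                g = alpha[:, None] * q + (1.0 - alpha)[:, None] * p
                ll = float(np.sum(X * np.log(g)))
                if best is None or ll > best[0]:
                    best = (ll, m, ai, ei)
    return 2.0 * (best[0] - L0), best[1], best[2], best[3]
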