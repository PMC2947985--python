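"""Numba-compiled numerical kernels.

Gillespie (exact stochastic simulation) of the two-state reaction scheme and
a batch tridiagonal solver for the alternating-implicit CME iteration.
Compiled on first use; kept in a separate module so importing the package
does not trigger compilation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_endpoint", "batch_tridiag_solve"]


@njit(cache=True)
def _ssa_many(ka, kr, kt, kp, kpm, t_end, n_cells, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    out_m = np.empty(n_cells, dtype=np.int64)
    out_n = np.empty(n_cells, dtype=np.int64)
    for c in range(n_cells):
        t = 0.0
        g = 0
        m = 0
        n = 0
        while True:
            a_gene = ka if g == 0 else kr
            a_tx = kt if g == 1 else 0.0
            a_tdeg = 1.0 * m
            a_tl = kp * m
            a_pdeg = kpm * n
            a_tot = a_gene + a_tx + a_tdeg + a_tl + a_pdeg
            t += -np.log(np.random.random()) / a_tot
            if t > t_end:
                break
            u = np.random.random() * a_tot
            if u < a_gene:
                g = 1 - g
            elif u < a_gene + a_tx:
                m += 1
            elif u < a_gene + a_tx + a_tdeg:
                m -= 1
            elif u < a_gene + a_tx + a_tdeg + a_tl:
                n += 1
            else:
                n -= 1
        out_m[c] = m
        out_n[c] = n
    return out_m, out_n


def ssa_endpoint(ka, kr, kt, kp, kpm, t_end, n_cells, seed):
    """End-time (transcript, protein) samples from independent trajectories."""
    return _ssa_many(
        float(ka), float(kr), float(kt), float(kp), float(kpm),
        float(t_end), int(n_cells), int(seed) % (2**32 - 1),
    )


@njit(cache=True)
def batch_tridiag_solve(ab, rhs):  # pragma: no cover - jitted
    """Solve (nT) tridiagonal systems for rhs of shape (2, nT, nP) in place.

    ab[i] holds the LAPACK-style bands of system i: ab[i,0,1:] superdiagonal,
    ab[i,1,:] diagonal, ab[i,2,:-1] subdiagonal.
    """
    nb, nT, nP = rhs.shape
    cp = np.empty(nP)
    for i in range(nT):
        sup = ab[i, 0]
        dia = ab[i, 1]
        sub = ab[i, 2]
        denom = dia[0]
        cp[0] = sup[1] / denom
        for g in range(nb):
            rhs[g, i, 0] = rhs[g, i, 0] / denom
        for j in range(1, nP):
            denom = dia[j] - sub[j - 1] * cp[j - 1]
            if j < nP - 1:
                cp[j] = sup[j + 1] / denom
            for g in range(nb):
                rhs[g, i, j] = (rhs[g, i, j] - sub[j - 1] * rhs[g, i, j - 1]) / denom
        for j in range(nP - 2, -1, -1):
            for g in range(nb):
                rhs[g, i, j] -= cp[j] * rhs[g, i, j + 1]
    return rhs
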