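"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def grid_solve(sys, levels=6, n=200):
    """Independent brute-force solve: refine a log-spaced (free L, free T)
    grid by minimizing the squared relative residual of the L and T
    balances.  Log spacing resolves tight-binding roots where free species
    are many orders below the totals."""
    lo_l, hi_l = sys.L0 * 1e-15, sys.L0
    lo_t, hi_t = sys.T0 * 1e-15, sys.T0
    best = None
    for _ in range(levels):
        ls = np.geomspace(lo_l, hi_l, n)
        ts = np.geomspace(lo_t, hi_t, n) if sys.T0 > 0 else np.array([0.0])
        L, T = np.meshgrid(ls, ts, indexing="ij")
        P = sys.P0 / (1 + L / sys.K1_binary
                      + L * T / (sys.K1_binary * sys.K2_ternary))
        PL = P * L / sys.K1_binary
        PLT = PL * T / sys.K2_ternary
        res = ((L + PL + PLT - sys.L0) / max(sys.L0, 1e-300)) ** 2
        if sys.T0 > 0:
            res = res + ((T + PLT - sys.T0) / sys.T0) ** 2
        i, j = np.unravel_index(np.argmin(res), res.shape)
        best = dict(P=P[i, j], L=L[i, j], T=T[i, j], PL=PL[i, j], PLT=PLT[i, j])
        ratio = (hi_l / lo_l) ** (1.0 / (n - 1))
        lo_l = max(sys.L0 * 1e-18, L[i, j] / ratio**4)
        hi_l = min(sys.L0, L[i, j] * ratio**4)
        if sys.T0 > 0:
            ratio_t = (hi_t / lo_t) ** (1.0 / (n - 1))
            lo_t = max(sys.T0 * 1e-18, T[i, j] / ratio_t**4)
            hi_t = min(sys.T0, T[i, j] * ratio_t**4)
    return best
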