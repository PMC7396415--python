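"""Independent oracles used only by the test suite.

These are deliberately written against the formulas and brute-force
strategies, not against the package's own code paths, so that agreement
constitutes an actual cross-check:

* ``adj_r2_oracle``   -- direct evaluation of the goodness-of-fit formulas.
* ``mono_grid_oracle``/``bi_grid_oracle`` -- dense T2 grid search with
  closed-form / linear least-squares amplitudes per grid point.
* ``loglinear_mono``  -- log-domain linear regression, exact for noiseless
  monoexponential data.
"""

import numpy as np


def adj_r2_oracle(y, G, m):
    y = np.asarray(y, float)
    G = np.asarray(G, float)
    K = len(y)
    ybar = sum(y) / K
    rss = sum((yi - gi) ** 2 for yi, gi in zip(y, G))
    tss = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (K - 1) / (K - m - 1)
    return r2, adj


def loglinear_mono(y, tes):
    """Closed-form (A, T2) from linear regression of log(y) on TE."""
    ly = np.log(y)
    slope, intercept = np.polyfit(tes, ly, 1)
    return float(np.exp(intercept)), float(-1.0 / slope)


def mono_grid_oracle(y, tes, t2_lo=27.0, t2_hi=2500.0, n_grid=4000,
                     amp_hi=2000.0):
    """Dense 1-D T2 grid with closed-form amplitude; returns (rss, A, T2)."""
    t2s = np.geomspace(t2_lo, t2_hi, n_grid)
    basis = np.exp(-tes[:, None] / t2s[None, :])  # (K, n_grid)
    num = y @ basis
    den = (basis * basis).sum(axis=0)
    amps = np.clip(num / den, 0.0, amp_hi)
    rss = (y * y).sum() - 2 * amps * num + amps**2 * den
    j = int(np.argmin(rss))
    return float(rss[j]), float(amps[j]), float(t2s[j])


def bi_grid_oracle(y, tes, space=None, n1=80, n2=120):
    """Dense (T2_1, T2_2) grid with per-point linear-LS amplitudes.

    Returns (rss, A1, T2_1, A2, T2_2).
    """
    lo1, hi1 = (27.0, 120.0) if space is None else (space.bi_T2_1_lo, space.bi_T2_1_hi)
    lo2, hi2 = (120.1, 2500.0) if space is None else (space.bi_T2_2_lo, space.bi_T2_2_hi)
    amp_hi = 2000.0 if space is None else space.amp_hi
    g1 = np.geomspace(lo1, hi1, n1)
    g2 = np.geomspace(lo2, hi2, n2)
    best = (np.inf, None)
    for t1 in g1:
        e1 = np.exp(-tes / t1)
        for t2 in g2:
            e2 = np.exp(-tes / t2)
            B = np.column_stack([e1, e2])
            a, *_ = np.linalg.lstsq(B, y, rcond=None)
            a = np.clip(a, 0.0, amp_hi)
            r = y - B @ a
            rss = float(r @ r)
            if rss < best[0]:
                best = (rss, (float(a[0]), float(t1), float(a[1]), float(t2)))
    rss, (a1, t1, a2, t2) = best
    return rss, a1, t1, a2, t2
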