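"""Numba-compiled kernels for EMD sifting and ensemble averaging.

These are internal primitives: plain float64 arrays in, arrays out.  The
public wrappers with validation and the domain containers live in
:mod:`causaldecomp.emd`.

Algorithmic choices (fixed here, surfaced as parameters upstream):

* envelopes are natural cubic splines through the local maxima / minima;
* the two extrema nearest each record end are mirrored across the end
  point before spline fitting, so envelopes are defined on the full record;
* each intrinsic mode function (IMF) is produced by a fixed number of
  sifting iterations (default 10) rather than a Cauchy-type stop rule;
* extraction stops when the working residual has fewer than three local
  extrema, or when the requested number of IMFs is reached.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["emd_kernel", "eemd_kernel"]


@njit(cache=True)
def _local_extrema(x):
    """Indices of strict local maxima and minima of ``x`` (interior points)."""
    n = x.shape[0]
    maxi = np.empty(n, np.int64)
    mini = np.empty(n, np.int64)
    nmax = 0
    nmin = 0
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            maxi[nmax] = i
            nmax += 1
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            mini[nmin] = i
            nmin += 1
    return maxi[:nmax], mini[:nmin]


@njit(cache=True)
def _mirrored_knots(idx, val, n):
    """Extend extrema by mirroring the two nearest each end across the ends.

    Returns strictly increasing knot positions (floats) and values covering
    [0, n-1].
    """
    k = idx.shape[0]
    nl = 2 if k >= 2 else 1
    nr = 2 if k >= 2 else 1
    t = np.empty(k + nl + nr)
    y = np.empty(k + nl + nr)
    # left mirror about position 0
    for j in range(nl):
        src = nl - 1 - j  # farthest mirrored point first to keep order
        t[j] = -float(idx[src])
        y[j] = val[src]
    for j in range(k):
        t[nl + j] = float(idx[j])
        y[nl + j] = val[j]
    # right mirror about position n-1
    for j in range(nr):
        src = k - 1 - j
        t[nl + k + j] = 2.0 * (n - 1) - float(idx[src])
        y[nl + k + j] = val[src]
    return t, y


@njit(cache=True)
def _natural_spline_on_grid(t, y, n):
    """Evaluate the natural cubic spline through (t, y) at 0..n-1.

    ``t`` must be strictly increasing and bracket [0, n-1].  Natural
    boundary conditions: zero second derivative at both end knots.
    """
    m = t.shape[0]
    out = np.empty(n)
    if m == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        for i in range(n):
            out[i] = y[0] + slope * (i - t[0])
        return out

    h = np.empty(m - 1)
    for j in range(m - 1):
        h[j] = t[j + 1] - t[j]

    # Thomas algorithm for interior second derivatives M[1..m-2]; M[0]=M[m-1]=0
    M = np.zeros(m)
    if m > 2:
        a = np.empty(m - 2)  # sub-diagonal
        b = np.empty(m - 2)  # diagonal
        c = np.empty(m - 2)  # super-diagonal
        d = np.empty(m - 2)  # rhs
        for j in range(1, m - 1):
            a[j - 1] = h[j - 1]
            b[j - 1] = 2.0 * (h[j - 1] + h[j])
            c[j - 1] = h[j]
            d[j - 1] = 6.0 * ((y[j + 1] - y[j]) / h[j] - (y[j] - y[j - 1]) / h[j - 1])
        for j in range(1, m - 2):
            w = a[j] / b[j - 1]
            b[j] -= w * c[j - 1]
            d[j] -= w * d[j - 1]
        M[m - 2] = d[m - 3] / b[m - 3]
        for j in range(m - 4, -1, -1):
            M[j + 1] = (d[j] - c[j] * M[j + 2]) / b[j]

    seg = 0
    for i in range(n):
        xq = float(i)
        while seg < m - 2 and t[seg + 1] < xq:
            seg += 1
        hj = h[seg]
        A = (t[seg + 1] - xq) / hj
        B = (xq - t[seg]) / hj
        out[i] = (
            A * y[seg]
            + B * y[seg + 1]
            + ((A ** 3 - A) * M[seg] + (B ** 3 - B) * M[seg + 1]) * hj * hj / 6.0
        )
    return out


@njit(cache=True)
def _mean_envelope(x):
    """Mean of upper and lower spline envelopes; flag False if not siftable."""
    n = x.shape[0]
    maxi, mini = _local_extrema(x)
    if maxi.shape[0] < 1 or mini.shape[0] < 1 or maxi.shape[0] + mini.shape[0] < 3:
        return np.zeros(n), False
    tmax, ymax = _mirrored_knots(maxi, x[maxi], n)
    tmin, ymin = _mirrored_knots(mini, x[mini], n)
    upper = _natural_spline_on_grid(tmax, ymax, n)
    lower = _natural_spline_on_grid(tmin, ymin, n)
    return 0.5 * (upper + lower), True


@njit(cache=True)
def emd_kernel(x, max_imfs, sift_iterations):
    """Sift ``x`` into at most ``max_imfs`` IMFs plus a residual.

    Returns (imfs, residual, count); rows ``count:`` of ``imfs`` are zero
    when extraction terminates early (fewer than 3 extrema left).
    """
    n = x.shape[0]
    imfs = np.zeros((max_imfs, n))
    resid = x.copy()
    count = 0
    for k in range(max_imfs):
        h = resid.copy()
        extracted = False
        for _ in range(sift_iterations):
            env, ok = _mean_envelope(h)
            if not ok:
                break
            h = h - env
            extracted = True
        if not extracted:
            break
        imfs[k] = h
        resid = resid - h
        count += 1
    return imfs, resid, count


@njit(cache=True)
def eemd_kernel(x, noise, amp, max_imfs, sift_iterations):
    """Ensemble EMD: average the IMFs of noise-perturbed copies of ``x``.

    ``noise`` has shape (trials, len(x)); each trial decomposes
    ``x + amp * noise[k]`` forcing ``max_imfs`` rows (zero-padded when a
    trial terminates early, so the ensemble mean stays well defined).
    """
    trials = noise.shape[0]
    n = x.shape[0]
    acc = np.zeros((max_imfs, n))
    racc = np.zeros(n)
    for k in range(trials):
        imfs, resid, _ = emd_kernel(x + amp * noise[k], max_imfs, sift_iterations)
        acc += imfs
        racc += resid
    return acc / trials, racc / trials
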