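"""Rolling-median/MAD (Hampel) kernel.

The identifier uses exact centered windows, truncated at the series edges.
For each sample, the window median m and the median absolute deviation
MAD = median(|window - m|) are computed; a sample with |x - m| beyond
``n_sigma * 1.4826 * MAD`` (1.4826 makes the MAD a consistent Gaussian sigma
estimate) is replaced by m. Windows whose MAD is zero fall back to a small
absolute floor so constant segments are not mass-replaced.

The kernel maintains the current window as a sorted buffer (binary-search
insert/delete) and extracts both the median and the MAD median by selecting
in the merge of the two sorted deviation halves, giving O(N * W) worst-case
with a small constant; it matches a brute-force per-window computation
exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAD_SCALE = 1.4826


@njit(cache=True)
def _hampel_core(x, half, n_sigma, floor):  # pragma: no cover - exercised via hampel()
    n = x.size
    out = x.copy()
    flagged = np.zeros(n, np.bool_)
    cap = 2 * half + 1
    if cap > n:
        cap = n
    buf = np.empty(cap, np.float64)
    k = 0
    end0 = half + 1
    if end0 > n:
        end0 = n
    for j in range(end0):
        v = x[j]
        lo, hi = 0, k
        while lo < hi:
            mid = (lo + hi) >> 1
            if buf[mid] < v:
                lo = mid + 1
            else:
                hi = mid
        for t in range(k, lo, -1):
            buf[t] = buf[t - 1]
        buf[lo] = v
        k += 1
    for i in range(n):
        if i > 0:
            r = i + half
            if r < n:
                v = x[r]
                lo, hi = 0, k
                while lo < hi:
                    mid = (lo + hi) >> 1
                    if buf[mid] < v:
                        lo = mid + 1
                    else:
                        hi = mid
                for t in range(k, lo, -1):
                    buf[t] = buf[t - 1]
                buf[lo] = v
                k += 1
            left = i - half - 1
            if left >= 0:
                v = x[left]
                lo, hi = 0, k
                while lo < hi:
                    mid = (lo + hi) >> 1
                    if buf[mid] < v:
                        lo = mid + 1
                    else:
                        hi = mid
                for t in range(lo, k - 1):
                    buf[t] = buf[t + 1]
                k -= 1
        # window median
        if k & 1:
            m = buf[k >> 1]
        else:
            m = 0.5 * (buf[(k >> 1) - 1] + buf[k >> 1])
        # MAD: median of |buf - m| via merge-selection over the two sorted halves
        lo, hi = 0, k
        while lo < hi:
            mid = (lo + hi) >> 1
            if buf[mid] <= m:
                lo = mid + 1
            else:
                hi = mid
        li = lo - 1
        ri = lo
        target = k >> 1
        d_prev = 0.0
        d_cur = 0.0
        cnt = -1
        while cnt < target:
            if li >= 0:
                dl = m - buf[li]
            else:
                dl = np.inf
            if ri < k:
                dr = buf[ri] - m
            else:
                dr = np.inf
            if dl <= dr:
                d = dl
                li -= 1
            else:
                d = dr
                ri += 1
            cnt += 1
            d_prev = d_cur
            d_cur = d
        if k & 1:
            mad = d_cur
        else:
            mad = 0.5 * (d_prev + d_cur)
        thr = n_sigma * MAD_SCALE * mad
        if thr < floor:
            thr = floor
        if abs(x[i] - m) > thr:
            out[i] = m
            flagged[i] = True
    return out, flagged
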