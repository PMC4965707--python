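"""Numba kernel for the ends-free restriction-map overlap DP.

Two layers make the optimum exact over all monotone matchings with at
least two matched pairs, even when every extension step is penalized:

* ``B[i, j]`` — best score of a chain with >= 1 matched pairs ending at
  ``(i, j)``; a chain may always start fresh at score ``match_base``.
* ``A[i, j]`` — best score of a chain with >= 2 matched pairs ending at
  ``(i, j)``: the best predecessor chain ``B`` plus one extension.

Each extension from ``(i-k, j-l)`` pays ``(k-1 + l-1)`` skip penalties
plus a sizing log-likelihood-ratio term whose variance combines the
per-gap noise of both maps (``c^2 (da^2/k + db^2/l)``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT2PI = 2.5066282746310002
NEG = -1e300


@njit(cache=True)
def overlap_dp(u, v, match_base, skip_cost, c_rel, sd_min, ln_w, max_skip):
    """Fill the DP matrices.

    Returns ``(A, countA, backA_i, backA_j, backB_i, backB_j)``: the >=2
    pair score matrix, its matched-pair counts, the predecessor of the
    final extension, and the predecessor chain (``-1`` marks a fresh
    start).
    """
    m = u.shape[0]
    n = v.shape[0]
    A = np.full((m, n), NEG)
    B = np.full((m, n), NEG)
    countA = np.zeros((m, n), dtype=np.int64)
    countB = np.zeros((m, n), dtype=np.int64)
    backA_i = np.full((m, n), -1, dtype=np.int64)
    backA_j = np.full((m, n), -1, dtype=np.int64)
    backB_i = np.full((m, n), -1, dtype=np.int64)
    backB_j = np.full((m, n), -1, dtype=np.int64)
    span = max_skip + 1
    for i in range(m):
        for j in range(n):
            best = NEG
            bi = -1
            bj = -1
            kmax = i if i < span else span
            lmax = j if j < span else span
            for k in range(1, kmax + 1):
                da = u[i] - u[i - k]
                for l in range(1, lmax + 1):
                    db = v[j] - v[j - l]
                    sd = c_rel * np.sqrt(da * da / k + db * db / l)
                    if sd < sd_min:
                        sd = sd_min
                    z = (db - da) / sd
                    step = (
                        -0.5 * z * z
                        - np.log(sd * _SQRT2PI)
                        + ln_w
                        + (k - 1 + l - 1) * skip_cost
                    )
                    cand = B[i - k, j - l] + step
                    if cand > best + 1e-12:
                        best = cand
                        bi = i - k
                        bj = j - l
            if bi >= 0:
                A[i, j] = best + match_base
                countA[i, j] = countB[bi, bj] + 1
                backA_i[i, j] = bi
                backA_j[i, j] = bj
            # >= 1 pair chain: extend if strictly better than starting fresh
            if A[i, j] > match_base + 1e-12:
                B[i, j] = A[i, j]
                countB[i, j] = countA[i, j]
                backB_i[i, j] = backA_i[i, j]
                backB_j[i, j] = backA_j[i, j]
            else:
                B[i, j] = match_base
                countB[i, j] = 1
    return A, countA, backA_i, backA_j, backB_i, backB_j
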