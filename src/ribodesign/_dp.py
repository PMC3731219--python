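"""Numba kernels for the interval dynamic program behind fold/cofold.

The recurrence is a Nussinov-style energy minimization: position i is either
unpaired, or paired with some k (i < k <= j) splitting the interval into an
inner and an outer part.  Nestedness of the pair set is implied by the
recurrence; pairs between different strands are exempt from the minimum
hairpin-loop distance.  Tie-breaking in the traceback prefers leaving the
leftmost position unpaired, which makes the returned structure deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-6


@njit(cache=True)
def mfe_matrix(enc, strand, pe_intra, pe_inter, minloop):
    n = enc.shape[0]
    E = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            for k in range(i + 1, j + 1):
                if strand[i] == strand[k]:
                    if k - i <= minloop:
                        continue
                    e = pe_intra[enc[i], enc[k]]
                else:
                    e = pe_inter[enc[i], enc[k]]
                if e >= 0.0:
                    continue
                left = E[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                right = E[k + 1, j] if k + 1 <= j else 0.0
                cand = e + left + right
                if cand < best - _EPS:
                    best = cand
            E[i, j] = best
    return E


@njit(cache=True)
def traceback(E, enc, strand, pe_intra, pe_inter, minloop):
    n = enc.shape[0]
    partner = np.full(n, -1, np.int64)
    if n == 0:
        return partner
    si = np.empty(4 * n + 8, np.int64)
    sj = np.empty(4 * n + 8, np.int64)
    top = 0
    si[top] = 0
    sj[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = si[top]
        j = sj[top]
        if i >= j:
            continue
        # prefer the unpaired branch on ties
        if abs(E[i, j] - E[i + 1, j]) < _EPS:
            si[top] = i + 1
            sj[top] = j
            top += 1
            continue
        for k in range(i + 1, j + 1):
            if strand[i] == strand[k]:
                if k - i <= minloop:
                    continue
                e = pe_intra[enc[i], enc[k]]
            else:
                e = pe_inter[enc[i], enc[k]]
            if e >= 0.0:
                continue
            left = E[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
            right = E[k + 1, j] if k + 1 <= j else 0.0
            if abs(E[i, j] - (e + left + right)) < _EPS:
                partner[i] = k
                partner[k] = i
                if k - 1 >= i + 1:
                    si[top] = i + 1
                    sj[top] = k - 1
                    top += 1
                if k + 1 <= j:
                    si[top] = k + 1
                    sj[top] = j
                    top += 1
                break
    return partner
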