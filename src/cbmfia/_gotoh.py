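"""Affine-gap global alignment matrix fill (Gotoh three-state recurrence).

The fill is JIT-compiled with numba so that corpus-scale batches (hundreds of
targets against ~100 templates) run in seconds.  A pure-Python fallback with
identical semantics is used when numba is unavailable.

Conventions: a gap run of length L costs open + (L-1)*extend.  H[i, j] is the
best score of an alignment of the first i target residues against the first j
template residues; Ix ends with the target residue aligned to a gap (gap in
the template row), Iy ends with a gap in the target row.
"""

from __future__ import annotations

import numpy as np

NEG = -1e30


def _fill(S, gap_open, gap_extend, free_end_gaps):
    m, n = S.shape
    H = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)
    Iy = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = 0.0 if free_end_gaps else -(gap_open + (i - 1) * gap_extend)
        H[i, 0] = Ix[i, 0]
    for j in range(1, n + 1):
        Iy[0, j] = 0.0 if free_end_gaps else -(gap_open + (j - 1) * gap_extend)
        H[0, j] = Iy[0, j]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            a = H[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            Ix[i, j] = a if a >= b else b
            a = H[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            Iy[i, j] = a if a >= b else b
            d = H[i - 1, j - 1] + S[i - 1, j - 1]
            best = d
            if Ix[i, j] > best:
                best = Ix[i, j]
            if Iy[i, j] > best:
                best = Iy[i, j]
            H[i, j] = best
    return H, Ix, Iy


try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    fill = njit(cache=True)(_fill)
except ImportError:  # pragma: no cover
    fill = _fill
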