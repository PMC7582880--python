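"""Numba-compiled dynamic-programming alignment kernels.

Shared by the consensus builder (scored Needleman-Wunsch with deterministic
tie-breaking) and the error-profiling analytics (unit-cost edit alignment
with a canonical traceback that prefers substitutions over indel pairs).
Sequences are passed as uint8 code arrays; 4 encodes a gap in the outputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

GAP = np.uint8(4)


@njit(cache=True)
def nw_align_codes(a, b, match, mismatch, gap):
    """Global alignment of code arrays a, b maximizing the linear-gap score.

    Ties in the traceback are broken deterministically: diagonal first, then
    up (gap in b), then left (gap in a).  Returns (a_aln, b_aln, score).
    """
    la, lb = a.size, b.size
    S = np.empty((la + 1, lb + 1), np.int32)
    for i in range(la + 1):
        S[i, 0] = i * gap
    for j in range(lb + 1):
        S[0, j] = j * gap
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            d = S[i - 1, j - 1] + (match if ai == b[j - 1] else mismatch)
            u = S[i - 1, j] + gap
            l = S[i, j - 1] + gap
            best = d
            if u > best:
                best = u
            if l > best:
                best = l
            S[i, j] = best
    # traceback
    out_a = np.empty(la + lb, np.uint8)
    out_b = np.empty(la + lb, np.uint8)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a[k] = a[i - 1]
            out_b[k] = b[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and S[i, j] == S[i - 1, j] + gap:
            out_a[k] = a[i - 1]
            out_b[k] = GAP
            i -= 1
        else:
            out_a[k] = GAP
            out_b[k] = b[j - 1]
            j -= 1
        k += 1
    return out_a[:k][::-1].copy(), out_b[:k][::-1].copy(), S[la, lb]


@njit(cache=True)
def classify_edits(ref, read):
    """Unit-cost edit alignment of read against a reference.

    Returns (positions, types, read_positions, distance) where types are
    0 = substitution, 1 = deletion (reference base absent from the read) and
    2 = insertion (extra read base, reported at the reference position it
    precedes).  ``read_positions`` give the read coordinate of each event.
    The traceback is canonical: matches/substitutions are preferred over
    indel pairs of equal cost, then deletions, then insertions.
    """
    n, m = ref.size, read.size
    D = np.empty((n + 1, m + 1), np.int32)
    for i in range(n + 1):
        D[i, 0] = i
    for j in range(m + 1):
        D[0, j] = j
    for i in range(1, n + 1):
        ri = ref[i - 1]
        for j in range(1, m + 1):
            c = D[i - 1, j - 1] + (0 if ri == read[j - 1] else 1)
            u = D[i - 1, j] + 1
            l = D[i, j - 1] + 1
            best = c
            if u < best:
                best = u
            if l < best:
                best = l
            D[i, j] = best
    pos = np.empty(n + m, np.int32)
    typ = np.empty(n + m, np.int32)
    rdp = np.empty(n + m, np.int32)  # read position of each event
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and D[i, j] == D[i - 1, j - 1] + (0 if ref[i - 1] == read[j - 1] else 1)
        ):
            if ref[i - 1] != read[j - 1]:
                pos[k] = i - 1
                typ[k] = 0
                rdp[k] = j - 1
                k += 1
            i -= 1
            j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            pos[k] = i - 1
            typ[k] = 1
            rdp[k] = j
            k += 1
            i -= 1
        else:
            pos[k] = i
            typ[k] = 2
            rdp[k] = j - 1
            k += 1
            j -= 1
    return pos[:k][::-1].copy(), typ[:k][::-1].copy(), rdp[:k][::-1].copy(), D[n, m]


def encode_seq(s: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3 (anything else raises)."""
    lut = np.full(128, 255, dtype=np.uint8)
    for i, c in enumerate(b"ACGT"):
        lut[c] = i
    arr = lut[np.frombuffer(s.encode("ascii"), np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("sequence contains characters outside ACGT")
    return arr


_DECODE = np.frombuffer(b"ACGT-", dtype=np.uint8)


def decode_codes(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")
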