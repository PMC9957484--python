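"""Low-level numeric kernels: base encoding, k-mer codes, seed extension and
banded edit-distance alignment.

Sequences are encoded as uint8 (A=0, C=1, G=2, T=3, N=4); N never matches
anything, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC_TABLE[ord(_b)] = _i
_DEC_TABLE = np.frombuffer(b"ACGTN", dtype=np.uint8)

BIG = 1 << 29


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(enc: np.ndarray) -> str:
    return _DEC_TABLE[enc].tobytes().decode("ascii")


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """int64 code of every k-mer; -1 where the window contains an N."""
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    x = enc.astype(np.int64)
    weights = 4 ** np.arange(k, dtype=np.int64)  # convolution flips the kernel
    codes = np.convolve(x, weights)[k - 1 : n]
    bad = np.convolve((enc == 4).astype(np.int64), np.ones(k, dtype=np.int64))[k - 1 : n]
    codes[bad > 0] = -1
    return codes


@njit(cache=False)
def extend_seed(a, b, i, j, klen, match_sc, mis_sc, xdrop):  # pragma: no cover
    """Gap-free X-drop extension of an exact seed ``a[i:i+klen] == b[j:j+klen]``.

    Returns ``(left, right, mismatches)``: the extension lengths beyond the
    seed on each side at the maximum-scoring extent, and the total mismatch
    count inside that extent (the seed itself contributes none).
    """
    na = a.shape[0]
    nb = b.shape[0]
    # rightwards
    score = 0
    best = 0
    right = 0
    mm_right = 0
    mm = 0
    step = 1
    while i + klen + step <= na and j + klen + step <= nb:
        x = a[i + klen + step - 1]
        y = b[j + klen + step - 1]
        if x == y and x < 4:
            score += match_sc
        else:
            score += mis_sc
            mm += 1
        if score > best:
            best = score
            right = step
            mm_right = mm
        if best - score > xdrop:
            break
        step += 1
    # leftwards
    score = 0
    best = 0
    left = 0
    mm_left = 0
    mm = 0
    step = 1
    while i - step >= 0 and j - step >= 0:
        x = a[i - step]
        y = b[j - step]
        if x == y and x < 4:
            score += match_sc
        else:
            score += mis_sc
            mm += 1
        if score > best:
            best = score
            left = step
            mm_left = mm
        if best - score > xdrop:
            break
        step += 1
    return left, right, mm_left + mm_right


@njit(cache=False)
def banded_fit(q, t, dlo, dhi):  # pragma: no cover
    """Banded fitting alignment: ``q`` aligned globally inside ``t`` (free
    gaps at both ends of ``t``), unit edit costs.

    The band restricts the offset ``j - i`` to ``[dlo, dhi]``.
    Returns ``(edit_distance, end_position_in_t)``; ``(BIG, -1)`` when no
    path fits in the band.
    """
    m = q.shape[0]
    n = t.shape[0]
    if dhi > n:
        dhi = n
    if dlo < -m:
        dlo = -m
    if dhi < dlo:
        return BIG, -1
    W = dhi - dlo + 1
    prev = np.full(W, BIG, dtype=np.int32)
    cur = np.full(W, BIG, dtype=np.int32)
    for w in range(W):
        j = dlo + w
        if 0 <= j <= n:
            prev[w] = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        for w in range(W):
            j = i + dlo + w
            cur[w] = BIG
            if j < 0 or j > n:
                continue
            c = BIG
            if j >= 1 and prev[w] < BIG:
                sub = prev[w]
                if not (t[j - 1] == qc and qc < 4):
                    sub += 1
                if sub < c:
                    c = sub
            if w + 1 < W and prev[w + 1] < BIG:
                up = prev[w + 1] + 1
                if up < c:
                    c = up
            if w >= 1 and cur[w - 1] < BIG:
                left = cur[w - 1] + 1
                if left < c:
                    c = left
            cur[w] = c
        tmp = prev
        prev = cur
        cur = tmp
    best = BIG
    bestj = -1
    for w in range(W):
        j = m + dlo + w
        if 0 <= j <= n and prev[w] < best:
            best = prev[w]
            bestj = j
    return best, bestj


def fit_align(q: np.ndarray, t: np.ndarray, dlo: int | None = None, dhi: int | None = None):
    """Python wrapper around :func:`banded_fit`; full band by default."""
    if dlo is None:
        dlo = -q.shape[0]
    if dhi is None:
        dhi = t.shape[0]
    err, endj = banded_fit(q, t, np.int64(dlo), np.int64(dhi))
    return int(err), int(endj)


@njit(cache=False)
def rolling_vote(enc, k, codes_sorted, pos_sorted):  # pragma: no cover
    """Diagonal offsets (j - i) of every exact k-mer shared between ``enc``
    and an indexed query whose sorted k-mer codes/positions are given."""
    n = enc.shape[0]
    nc = codes_sorted.shape[0]
    out = np.empty(n, dtype=np.int64)
    cnt = 0
    code = np.int64(0)
    valid = 0
    mask = (np.int64(1) << np.int64(2 * k)) - 1
    for j in range(n):
        b = enc[j]
        if b >= 4:
            valid = 0
            code = np.int64(0)
            continue
        code = ((code << 2) | np.int64(b)) & mask
        valid += 1
        if valid < k:
            continue
        lo = 0
        hi = nc
        while lo < hi:
            mid = (lo + hi) >> 1
            if codes_sorted[mid] < code:
                lo = mid + 1
            else:
                hi = mid
        if lo < nc and codes_sorted[lo] == code:
            out[cnt] = (j - k + 1) - pos_sorted[lo]
            cnt += 1
    return out[:cnt]


@njit(cache=False)
def classify_core(read, rep, u1, u2, d1, d2, dlo, dhi, anchor, pad):  # pragma: no cover
    """Fused per-read scoring: locate the repeat inside the read (banded,
    forward pass for the end, reversed pass for the start) and score the
    four flank anchors adjacent to it.

    Returns ``(err_repeat, js, je, eu1, eu2, ed1, ed2)``; anchor errors are
    -1 when the read lacks ``anchor`` bp of overhang on that side.
    """
    n = read.shape[0]
    m = rep.shape[0]
    err_f, je = banded_fit(rep, read, dlo, dhi)
    if je < 0:
        return BIG, -1, -1, -1, -1, -1, -1
    err_r, je_rev = banded_fit(rep[::-1], read[::-1], n - m - dhi, n - m - dlo)
    if je_rev < 0:
        return BIG, -1, -1, -1, -1, -1, -1
    js = n - je_rev
    err = min(err_f, err_r)
    eu1 = eu2 = ed1 = ed2 = -1
    if js >= anchor:
        lo = js - anchor - pad
        if lo < 0:
            lo = 0
        hi = js + 4
        if hi > n:
            hi = n
        seg = read[lo:hi]
        eu1, _ = banded_fit(u1, seg, -u1.shape[0], seg.shape[0])
        eu2, _ = banded_fit(u2, seg, -u2.shape[0], seg.shape[0])
    if n - je >= anchor:
        lo = je - 4
        if lo < 0:
            lo = 0
        hi = je + anchor + pad
        if hi > n:
            hi = n
        seg = read[lo:hi]
        ed1, _ = banded_fit(d1, seg, -d1.shape[0], seg.shape[0])
        ed2, _ = banded_fit(d2, seg, -d2.shape[0], seg.shape[0])
    return err, js, je, eu1, eu2, ed1, ed2
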