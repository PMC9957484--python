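"""Seed-and-extend enumeration of gap-free local matches between genomes.

Shared by :mod:`mitorecomb.repeat_finder` (genome against itself) and
:mod:`mitorecomb.mtpt_finder` (mitochondrial against chloroplast).  Matches
are exact k-mer seeds grouped per diagonal, extended gap-free with an X-drop
criterion and trimmed to the maximum-scoring extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import encode, extend_seed, kmer_codes

__all__ = ["GapFreeMatch", "gapfree_local_matches"]

# guard against low-complexity k-mer blow-up
_BUCKET_CAP = 200


@dataclass(frozen=True)
class GapFreeMatch:
    """A gap-free local match; ``b_*`` coordinates are forward-strand."""

    orientation: str  # "direct" | "inverted"
    a_chrom: str
    a_start: int
    a_end: int
    b_chrom: str
    b_start: int
    b_end: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def identity(self) -> float:
        return 100.0 * (self.length - self.mismatches) / self.length


def _rc_enc(enc: np.ndarray) -> np.ndarray:
    out = enc[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gapfree_local_matches(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str] | None,
    k: int,
    match_score: int,
    mismatch_score: int,
    xdrop: int,
) -> list[GapFreeMatch]:
    """All maximal-scoring gap-free matches between two genomes.

    ``seqs_b is None`` compares a genome against itself: self-hits, mirror
    duplicates and pairs whose two intervals overlap on the same chromosome
    are removed, and each pair is canonicalised so that
    ``(a_chrom, a_start) <= (b_chrom, b_start)``.
    """
    same = seqs_b is None
    if same:
        seqs_b = seqs_a
    ids_a = list(seqs_a)
    ids_b = list(seqs_b)
    enc_a = {c: encode(s) for c, s in seqs_a.items()}
    enc_b = enc_a if same else {c: encode(s) for c, s in seqs_b.items()}
    rc_b = {c: _rc_enc(e) for c, e in enc_b.items()}

    index: dict[int, list[tuple[int, int]]] = {}
    for ai, ca in enumerate(ids_a):
        for pos, code in enumerate(kmer_codes(enc_a[ca], k)):
            if code < 0:
                continue
            bucket = index.setdefault(int(code), [])
            if len(bucket) < _BUCKET_CAP:
                bucket.append((ai, pos))

    # seed groups keyed by (orientation, a index, b index, diagonal)
    groups: dict[tuple[str, int, int, int], list[tuple[int, int]]] = {}

    def _add(orient: str, ai: int, bi: int, i: int, j: int) -> None:
        groups.setdefault((orient, ai, bi, j - i), []).append((i, j))

    for bi, cb in enumerate(ids_b):
        fwd_codes = kmer_codes(enc_b[cb], k)
        for j, code in enumerate(fwd_codes):
            if code < 0:
                continue
            for ai, i in index.get(int(code), ()):
                if same and (ai > bi or (ai == bi and i >= j)):
                    continue
                _add("direct", ai, bi, i, j)
        rc_codes = kmer_codes(rc_b[cb], k)
        for j, code in enumerate(rc_codes):
            if code < 0:
                continue
            for ai, i in index.get(int(code), ()):
                if same and ai > bi:
                    continue
                _add("inverted", ai, bi, i, j)

    out: list[GapFreeMatch] = []
    seen: set[tuple] = set()
    for (orient, ai, bi, _diag), seeds in groups.items():
        seeds.sort()
        a = enc_a[ids_a[ai]]
        b = rc_b[ids_b[bi]] if orient == "inverted" else enc_b[ids_b[bi]]
        covered_until = -1
        for i, j in seeds:
            if i + k <= covered_until:
                continue
            left, right, mm = extend_seed(
                a, b, np.int64(i), np.int64(j), np.int64(k),
                np.int64(match_score), np.int64(mismatch_score), np.int64(xdrop),
            )
            a_start, a_end = i - left, i + k + right
            b_start, b_end = j - left, j + k + right
            covered_until = a_end
            ca, cb = ids_a[ai], ids_b[bi]
            if orient == "inverted":
                nb = b.shape[0]
                b_start, b_end = nb - b_end, nb - b_start
            if same:
                if ca == cb and not (a_end <= b_start or b_end <= a_start):
                    continue  # self-hit, tandem-overlap or palindromic center
                if (cb, b_start) < (ca, a_start):
                    ca, cb = cb, ca
                    a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
            key = (orient, ca, a_start, a_end, cb, b_start, b_end)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                GapFreeMatch(orient, ca, a_start, a_end, cb, b_start, b_end, int(mm))
            )
    return out
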