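"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package internals: repeat pairs
are found by enumerating all seed-position pairs and extending character by
character; read classification is plain substring containment.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq[::-1].translate(_COMP)


def rotations_equal(a: str, b: str) -> bool:
    return len(a) == len(b) and b in a + a


def maximal_exact_pairs(seqs: dict[str, str], min_length: int) -> set[tuple]:
    """All maximal exact repeat pairs of length >= min_length, both
    orientations, as ``(orientation, chrom1, start1, chrom2, start2, length)``
    with ``(chrom1, start1) <= (chrom2, start2)`` and overlapping same-chrom
    copies excluded."""
    L = min_length
    out: set[tuple] = set()

    index: dict[str, list[tuple[str, int]]] = {}
    for cid, s in seqs.items():
        for i in range(len(s) - L + 1):
            index.setdefault(s[i : i + L], []).append((cid, i))

    def record(orient, c1, a0, c2, b0, length):
        if c1 == c2 and not (a0 + length <= b0 or b0 + length <= a0):
            return
        if (c2, b0) < (c1, a0):
            c1, a0, c2, b0 = c2, b0, c1, a0
        out.add((orient, c1, a0, c2, b0, length))

    # direct: all ordered pairs of occurrences of each L-mer, left-maximal only
    for positions in index.values():
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                (c1, i), (c2, j) = positions[x], positions[y]
                s1, s2 = seqs[c1], seqs[c2]
                if i > 0 and j > 0 and s1[i - 1] == s2[j - 1]:
                    continue  # not left-maximal; a longer pair covers this
                a, b = i + L, j + L
                while a < len(s1) and b < len(s2) and s1[a] == s2[b]:
                    a += 1
                    b += 1
                record("direct", c1, i, c2, j, a - i)

    # inverted: compare every chromosome's reverse complement to the index
    for cid2, s2 in seqs.items():
        r2 = rc(s2)
        for j in range(len(r2) - L + 1):
            for c1, i in index.get(r2[j : j + L], ()):  # noqa: B020
                s1 = seqs[c1]
                if i > 0 and j > 0 and s1[i - 1] == r2[j - 1]:
                    continue
                a, b = i + L, j + L
                while a < len(s1) and b < len(r2) and s1[a] == r2[b]:
                    a += 1
                    b += 1
                length = a - i
                # rc-space [j, b) maps to forward-space [len - b, len - j)
                record("inverted", c1, i, cid2, len(s2) - b, length)
    return out


def containment_classify(read: str, refs, min_anchor: int) -> str:
    """Substring-containment classification of an error-free read."""
    a = min_anchor
    cores = {}
    for label, ref in refs.items():
        lo, hi = ref.repeat_span
        cores[label] = ref.seq[max(0, lo - 1 - a) : hi + a]
    rcread = rc(read)
    qualifying = [
        label for label, core in cores.items() if core in read or core in rcread
    ]
    if len(qualifying) == 1:
        return qualifying[0]
    if len(qualifying) >= 2:
        return "ambiguous"
    repeat = refs["major1"].repeat_seq
    for oriented in (read, rcread):
        pos = oriented.find(repeat)
        if pos >= 0:
            up = pos
            down = len(oriented) - (pos + len(repeat))
            if up < a and down < a:
                return "ambiguous"
            return "unclassified"
    return "unclassified"
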