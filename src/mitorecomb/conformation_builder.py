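"""Flank-swap construction of conformation reference sequences.

For a repeat pair with copies R1 (copy1) and R2 (copy2), let U/D be the
upstream/downstream flanks once copy2 has been rotated into copy1's
orientation (reverse-complemented, flanks swapped-and-complemented, for
inverted pairs).  The four references are::

    major1 = U1 + R1 + D1        alt1 = U1 + R1 + D2
    major2 = U2 + R2 + D2        alt2 = U2 + R2 + D1

so the two major references are exact substrings of the (possibly
reverse-complemented, possibly origin-wrapped) source chromosomes, and the
alternatives model the products of one recombination event.  Flanks wrap the
origin on circular chromosomes and are truncated (and flagged) on linear
ones.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

from .errors import ParameterError
from .genome_model import (
    CircularSequence,
    GenomeSet,
    Interval,
    reverse_complement,
    write_fasta,
)
from .repeat_finder import Orientation, RepeatPair

__all__ = ["LABELS", "ConformationReference", "build_conformation_refs", "write_refs"]

LABELS = ("major1", "major2", "alt1", "alt2")
DEFAULT_FLANK_LEN = 1000


@dataclass(frozen=True)
class ConformationReference:
    pair_id: str
    label: str
    seq: str
    repeat_span: tuple[int, int]  # 1-based inclusive within seq
    flank_len: int  # requested flank length
    flank_up: int  # realised upstream flank length
    flank_down: int
    flags: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return f"{self.pair_id}_{self.label}"

    @property
    def repeat_seq(self) -> str:
        lo, hi = self.repeat_span
        return self.seq[lo - 1 : hi]


def _flank(chrom: CircularSequence, start: int, end: int, flank_len: int):
    """Up/downstream flanks of [start, end) plus truncation/clamp flags."""
    flags: list[str] = []
    n = chrom.length
    span = end - start
    want = flank_len
    if chrom.is_circular and span + 2 * want > n:
        # flanks may not wrap far enough to re-enter the repeat itself
        want = (n - span) // 2
        flags.append("flank_clamped")
    if chrom.is_circular:
        up = chrom.slice0(start - want, want)
        down = chrom.slice0(end, want)
    else:
        up_len = min(want, start)
        down_len = min(want, n - end)
        if up_len < want:
            flags.append("flank_truncated_upstream")
        if down_len < want:
            flags.append("flank_truncated_downstream")
        up = chrom.seq[start - up_len : start]
        down = chrom.seq[end : end + down_len]
    return up, down, flags


def _flank_intervals(chrom: CircularSequence, start: int, length: int) -> list[Interval]:
    """Genome-coordinate footprint of a flank starting at ``start`` (may wrap)."""
    n = chrom.length
    start %= n
    if start + length <= n:
        return [Interval(chrom.id, start, start + length)]
    return [Interval(chrom.id, start, n), Interval(chrom.id, 0, start + length - n)]


def build_conformation_refs(
    genome: GenomeSet,
    pair: RepeatPair,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> dict[str, ConformationReference]:
    """The four flank-swap references for one repeat pair, keyed by label."""
    if flank_len < 1:
        raise ParameterError(f"flank_len must be >= 1, got {flank_len}")
    loc1, loc2 = pair.copy1.location, pair.copy2.location
    chrom1 = genome[loc1.chrom]
    chrom2 = genome[loc2.chrom]
    inverted = pair.orientation is Orientation.INVERTED

    r1 = pair.copy1.seq
    u1, d1, flags1 = _flank(chrom1, loc1.start, loc1.end, flank_len)
    up2_raw, dn2_raw, flags2 = _flank(chrom2, loc2.start, loc2.end, flank_len)
    if inverted:
        # rotate copy2 into copy1's orientation: its genomic downstream flank
        # becomes the upstream flank of the oriented copy, and vice versa
        r2 = reverse_complement(pair.copy2.seq)
        u2, d2 = reverse_complement(dn2_raw), reverse_complement(up2_raw)
    else:
        r2 = pair.copy2.seq
        u2, d2 = up2_raw, dn2_raw

    shared_flags: list[str] = []
    # a flank running into the partner copy's footprint reduces the
    # distinguishing power of the references: record it, do not fail
    partner_of = {1: loc2, 2: loc1}
    for which, (chrom, loc, up_len, dn_len) in {
        1: (chrom1, loc1, len(u1), len(d1)),
        2: (chrom2, loc2, len(up2_raw), len(dn2_raw)),
    }.items():
        partner = partner_of[which]
        footprints = _flank_intervals(chrom, loc.start - up_len, up_len)
        footprints += _flank_intervals(chrom, loc.end, dn_len)
        if any(iv.overlap(partner) > 0 for iv in footprints):
            shared_flags.append(f"flank_overlaps_partner_copy{which}")

    def make(label: str, up: str, repeat: str, down: str, extra: list[str]) -> ConformationReference:
        return ConformationReference(
            pair_id=pair.id,
            label=label,
            seq=up + repeat + down,
            repeat_span=(len(up) + 1, len(up) + len(repeat)),
            flank_len=flank_len,
            flank_up=len(up),
            flank_down=len(down),
            flags=tuple(sorted(set(extra + shared_flags))),
        )

    return {
        "major1": make("major1", u1, r1, d1, flags1),
        "major2": make("major2", u2, r2, d2, flags2),
        "alt1": make("alt1", u1, r1, d2, flags1 + flags2),
        "alt2": make("alt2", u2, r2, d1, flags1 + flags2),
    }


def write_refs(
    refs: dict[str, ConformationReference],
    fasta_path: str | os.PathLike,
    json_path: str | os.PathLike | None = None,
) -> None:
    """Multi-FASTA of the four references plus a JSON sidecar with spans."""
    records = [
        CircularSequence(r.name, r.seq, "linear") for r in refs.values()
    ]
    write_fasta(records, fasta_path)
    if json_path is not None:
        meta = {
            r.name: {
                "pair_id": r.pair_id,
                "label": r.label,
                "length": len(r.seq),
                "repeat_span": list(r.repeat_span),
                "flank_len": r.flank_len,
                "flank_up": r.flank_up,
                "flank_down": r.flank_down,
                "flags": list(r.flags),
            }
            for r in refs.values()
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
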