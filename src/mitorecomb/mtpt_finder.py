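"""Mitochondrial plastid transfer (MTPT) detection.

Local similarity search between a mitochondrial and a chloroplast genome
(seed-and-extend, both strands) scored with a Karlin-Altschul expectation
value ``E = K * m * n * exp(-lambda * S)`` under ungapped nucleotide scoring
(match +2 / mismatch -3); hits above the e-value threshold are discarded and
overlapping or abutting hits on the mitochondrial axis are merged.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

from scipy.optimize import brentq

from ._seedext import gapfree_local_matches
from .errors import InputError, ParameterError
from .genome_model import GenomeSet, Interval, Strand
from .read_classifier import _ratio_round

__all__ = [
    "MtptHit",
    "MtptSummary",
    "find_mtpts",
    "merge_hits",
    "summarize_mtpts",
    "write_mtpt_tsv",
    "write_mtpt_bed",
]

MATCH_SCORE = 2
MISMATCH_SCORE = -3
KA_K = 0.41  # standard ungapped nucleotide approximation
DEFAULT_EVALUE = 1e-5
DEFAULT_MIN_LENGTH = 30
DEFAULT_K = 11


def _karlin_lambda(match: int = MATCH_SCORE, mismatch: int = MISMATCH_SCORE) -> float:
    """Ungapped lambda for uniform base composition: solves
    0.25*exp(lambda*match) + 0.75*exp(lambda*mismatch) = 1."""
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0
    return brentq(f, 1e-6, 5.0)


_LAMBDA = _karlin_lambda()


@dataclass(frozen=True)
class MtptHit:
    """A homologous mt/cp segment; ``cp_interval.strand`` records the strand
    of the chloroplast copy relative to the mitochondrial plus strand."""

    mt_interval: Interval
    cp_interval: Interval
    length: int
    identity: float
    score: int
    e_value: float
    n_merged: int = 1


@dataclass(frozen=True)
class MtptSummary:
    count: int
    total_bp: int
    percent: float  # of the mitochondrial genome length, 2 decimals


def evalue(score: int, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-_LAMBDA * score)


def find_mtpts(
    mt: GenomeSet,
    cp: GenomeSet,
    evalue_threshold: float = DEFAULT_EVALUE,
    min_length: int = DEFAULT_MIN_LENGTH,
    k: int = DEFAULT_K,
    xdrop: int = 30,
    merge: bool = True,
) -> list[MtptHit]:
    """Plastid-derived segments of the mitochondrial genome, sorted by
    mitochondrial coordinate."""
    if len(mt) == 0 or len(cp) == 0:
        raise InputError("both genomes must be non-empty")
    if evalue_threshold <= 0:
        raise ParameterError("evalue_threshold must be > 0")
    m_total = mt.total_length
    n_total = cp.total_length
    mt_seqs = {c.id: c.seq for c in mt}
    cp_seqs = {c.id: c.seq for c in cp}
    matches = gapfree_local_matches(
        mt_seqs, cp_seqs, k, MATCH_SCORE, MISMATCH_SCORE, xdrop
    )
    hits: list[MtptHit] = []
    for mm in matches:
        if mm.length < min_length:
            continue
        score = MATCH_SCORE * (mm.length - mm.mismatches) + MISMATCH_SCORE * mm.mismatches
        e = evalue(score, m_total, n_total)
        if e > evalue_threshold:
            continue
        strand = Strand.MINUS if mm.orientation == "inverted" else Strand.PLUS
        hits.append(
            MtptHit(
                mt_interval=Interval(mm.a_chrom, mm.a_start, mm.a_end),
                cp_interval=Interval(mm.b_chrom, mm.b_start, mm.b_end, strand),
                length=mm.length,
                identity=round(mm.identity, 3),
                score=score,
                e_value=e,
            )
        )
    hits.sort(key=lambda h: (h.mt_interval.chrom, h.mt_interval.start, h.mt_interval.end))
    return merge_hits(hits) if merge else hits


def merge_hits(hits: list[MtptHit]) -> list[MtptHit]:
    """Merge hits overlapping or abutting on the mitochondrial axis.

    The merged hit spans the union interval; identity is the length-weighted
    mean, e-value the minimum, and the chloroplast interval that of the
    highest-scoring constituent.
    """
    merged: list[MtptHit] = []
    for h in sorted(hits, key=lambda h: (h.mt_interval.chrom, h.mt_interval.start)):
        if merged:
            last = merged[-1]
            if (
                h.mt_interval.chrom == last.mt_interval.chrom
                and h.mt_interval.start <= last.mt_interval.end
            ):
                new_iv = Interval(
                    last.mt_interval.chrom,
                    last.mt_interval.start,
                    max(last.mt_interval.end, h.mt_interval.end),
                )
                best = max((last, h), key=lambda x: x.score)
                weight = last.length + h.length
                merged[-1] = MtptHit(
                    mt_interval=new_iv,
                    cp_interval=best.cp_interval,
                    length=new_iv.length,
                    identity=round(
                        (last.identity * last.length + h.identity * h.length) / weight, 3
                    ),
                    score=best.score,
                    e_value=min(last.e_value, h.e_value),
                    n_merged=last.n_merged + h.n_merged,
                )
                continue
        merged.append(h)
    return merged


def summarize_mtpts(hits: list[MtptHit], mt_total_length: int) -> MtptSummary:
    """Hit count, summed mitochondrial-axis length and genome percentage
    (2 decimals).  Hits must be non-overlapping on the mt axis (post-merge)."""
    total = sum(h.length for h in hits)
    if mt_total_length < 1:
        raise ParameterError("mt_total_length must be >= 1")
    return MtptSummary(
        count=len(hits),
        total_bp=total,
        percent=_ratio_round(100 * total, mt_total_length, places=2),
    )


def write_mtpt_tsv(hits: list[MtptHit], path: str | os.PathLike) -> None:
    cols = [
        "mt_chrom", "mt_start", "mt_end", "cp_chrom", "cp_start", "cp_end",
        "cp_strand", "length", "identity", "e_value",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                f"{h.mt_interval.chrom}\t{h.mt_interval.start + 1}\t{h.mt_interval.end}\t"
                f"{h.cp_interval.chrom}\t{h.cp_interval.start + 1}\t{h.cp_interval.end}\t"
                f"{h.cp_interval.strand.value}\t{h.length}\t{h.identity:g}\t{h.e_value:.3g}\n"
            )


def write_mtpt_bed(hits: list[MtptHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, h in enumerate(hits, start=1):
            fh.write(
                f"{h.mt_interval.chrom}\t{h.mt_interval.start}\t{h.mt_interval.end}\t"
                f"MTPT{i}\t{int(round(h.identity * 10))}\t{h.cp_interval.strand.value}\n"
            )
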