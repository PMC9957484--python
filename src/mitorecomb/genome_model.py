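"""Core sequence and coordinate types for circular multipartite genomes.

Conventions
-----------
* Internally every coordinate is 0-based, half-open.  External text
  representations (TSV reports, CLI arguments, position strings such as
  ``"chr1: 48854-48524"``) are 1-based inclusive; conversion happens only in
  :func:`Interval.from_text` / :func:`Interval.to_text` and the report
  writers.
* A position string whose start is larger than its end denotes the
  reverse-complement (minus-strand) copy spanning ``[end, start]``.
* Sequences are normalised to uppercase ``A/C/G/T/N``; anything else is
  rejected loudly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import (
    CoordinateError,
    DegenerateInputError,
    InputError,
    ParseError,
)

__all__ = [
    "Topology",
    "Strand",
    "CircularSequence",
    "GenomeSet",
    "Interval",
    "Read",
    "reverse_complement",
    "circular_slice",
    "gc_content",
    "gc_fraction_of_seq",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "write_fastq",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


def _normalize(seq: str, context: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - _ALPHABET
    if bad:
        raise InputError(
            f"{context} contains non-DNA characters: {sorted(bad)!r} "
            "(allowed: A, C, G, T, N)"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``.

    Raises :class:`InputError` on characters outside ``{A,C,G,T,N}``.
    """
    return _normalize(seq)[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class CircularSequence:
    """A named chromosome with explicit topology.

    ``seq`` is validated and upper-cased on construction; ``length`` is
    derived.
    """

    id: str
    seq: str
    topology: Topology = Topology.CIRCULAR

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("chromosome id must be non-empty")
        object.__setattr__(self, "seq", _normalize(self.seq, f"chromosome {self.id!r}"))
        if len(self.seq) < 1:
            raise InputError(f"chromosome {self.id!r} has empty sequence")
        if not isinstance(self.topology, Topology):
            object.__setattr__(self, "topology", Topology(self.topology))

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR

    def slice0(self, start: int, length: int) -> str:
        """0-based slice of ``length`` bp starting at ``start``; wraps on circles.

        ``start`` may be any integer on a circular molecule (it is reduced
        modulo the length); linear molecules raise :class:`CoordinateError`
        on overrun.
        """
        if length < 0:
            raise CoordinateError("slice length must be >= 0")
        n = self.length
        if self.is_circular:
            start %= n
            if length > n:
                raise CoordinateError(
                    f"slice of {length} bp exceeds circular chromosome "
                    f"{self.id!r} length {n}"
                )
            end = start + length
            if end <= n:
                return self.seq[start:end]
            return self.seq[start:] + self.seq[: end - n]
        if start < 0 or start + length > n:
            raise CoordinateError(
                f"slice [{start}, {start + length}) overruns linear chromosome "
                f"{self.id!r} of length {n}"
            )
        return self.seq[start : start + length]


def circular_slice(chrom: CircularSequence, start: int, length: int) -> str:
    """Extract ``length`` bp starting at 1-based position ``start``.

    On circular chromosomes the slice wraps past the end back to position 1.
    """
    if not 1 <= start <= chrom.length:
        raise CoordinateError(
            f"start {start} outside [1, {chrom.length}] on chromosome {chrom.id!r}"
        )
    return chrom.slice0(start - 1, length)


@dataclass(frozen=True)
class Interval:
    """A located segment: chromosome id, 0-based half-open span, strand."""

    chrom: str
    start: int
    end: int
    strand: Strand = Strand.PLUS

    def __post_init__(self) -> None:
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))
        if self.start < 0 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Overlap in bp, ignoring strand; 0 when on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @classmethod
    def from_text(cls, text: str) -> "Interval":
        """Parse ``"chr1: 48854-48524"`` (1-based inclusive, external form).

        start > end denotes the minus-strand copy spanning [end, start].
        """
        try:
            chrom, span = text.split(":")
            a_s, b_s = span.strip().split("-")
            a, b = int(a_s), int(b_s)
        except ValueError as exc:
            raise ParseError(f"cannot parse position {text!r}") from exc
        chrom = chrom.strip()
        if a <= b:
            return cls(chrom, a - 1, b, Strand.PLUS)
        return cls(chrom, b - 1, a, Strand.MINUS)

    def to_text(self) -> str:
        """External 1-based inclusive form; minus strand prints reversed."""
        lo, hi = self.start + 1, self.end
        if self.strand is Strand.MINUS:
            return f"{self.chrom}: {hi}-{lo}"
        return f"{self.chrom}: {lo}-{hi}"


class GenomeSet:
    """Ordered collection of chromosomes with unique ids."""

    def __init__(self, chromosomes: Iterable[CircularSequence] = ()) -> None:
        self._chroms: list[CircularSequence] = []
        self._index: dict[str, CircularSequence] = {}
        for c in chromosomes:
            self.add(c)

    def add(self, chrom: CircularSequence) -> None:
        if chrom.id in self._index:
            raise InputError(f"duplicate chromosome id {chrom.id!r}")
        self._chroms.append(chrom)
        self._index[chrom.id] = chrom

    def __iter__(self) -> Iterator[CircularSequence]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self._index

    def __getitem__(self, chrom_id: str) -> CircularSequence:
        try:
            return self._index[chrom_id]
        except KeyError:
            raise InputError(f"chromosome {chrom_id!r} not in genome") from None

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._chroms]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self._chroms)

    @property
    def gc_content(self) -> float:
        return gc_content(self)

    def fetch(self, iv: Interval) -> str:
        """Sequence of an interval on its host chromosome's plus strand,
        reverse-complemented for minus-strand intervals."""
        chrom = self[iv.chrom]
        seq = chrom.slice0(iv.start, iv.length)
        return reverse_complement(seq) if iv.strand is Strand.MINUS else seq


def gc_fraction_of_seq(seq: str) -> float:
    """(G + C) / (A + C + G + T); Ns are ignored."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise DegenerateInputError("GC content undefined: no A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / acgt


def gc_content(genome: GenomeSet) -> float:
    if len(genome) == 0:
        raise DegenerateInputError("GC content undefined on an empty genome")
    return gc_fraction_of_seq("".join(c.seq for c in genome))


# ---------------------------------------------------------------------------
# I/O


@dataclass(frozen=True)
class Read:
    """A long read; ``qual`` is a Phred string (may be empty for FASTA input)."""

    id: str
    seq: str
    qual: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalize(self.seq, f"read {self.id!r}"))
        if self.qual and len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


def read_fasta(
    path: str | os.PathLike,
    topology: dict[str, str] | str | None = None,
) -> GenomeSet:
    """Load a FASTA file into a :class:`GenomeSet`.

    ``topology`` is either a per-chromosome mapping (``{"chr1": "circular"}``),
    a single default for all records, or ``None`` (everything circular —
    FASTA cannot express topology, so it is declared in config).
    An empty file yields an empty set.
    """
    genome = GenomeSet()
    default = Topology.CIRCULAR
    per_chrom: dict[str, str] = {}
    if isinstance(topology, str):
        default = Topology(topology)
    elif topology:
        per_chrom = dict(topology)
    try:
        for rec in SeqIO.parse(os.fspath(path), "fasta"):
            topo = Topology(per_chrom.get(rec.id, default))
            try:
                genome.add(CircularSequence(rec.id, str(rec.seq), topo))
            except InputError as exc:
                raise ParseError(f"record {rec.id!r}: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc
    return genome


def write_fasta(genome: GenomeSet | Sequence[CircularSequence], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom.id}\n")
            for i in range(0, chrom.length, width):
                fh.write(chrom.seq[i : i + width] + "\n")


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".fq", ".fastq"}:
        return "fastq"
    if ext in {".fa", ".fasta", ".fna"}:
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_reads(path: str | os.PathLike) -> list[Read]:
    """Load long reads from FASTA or FASTQ (auto-detected)."""
    path = os.fspath(path)
    fmt = _sniff_format(path)
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(path, fmt):
            qual = ""
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, str(rec.seq), qual))
    except ValueError as exc:
        name = reads[-1].id if reads else "<first record>"
        raise ParseError(f"malformed {fmt.upper()} {path} after record {name!r}: {exc}") from exc
    return reads


def write_fastq(reads: Sequence[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
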