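"""Seeded synthetic inputs: multipartite circular genomes with planted
repeat pairs and plastid-derived segments, conformer molecule pools at a
given alternative fraction, and error-bearing long reads with truth labels.

All randomness flows from one integer seed through per-stage sub-streams,
so e.g. changing the read count never perturbs the genome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .genome_model import (
    CircularSequence,
    GenomeSet,
    Interval,
    Read,
    Strand,
    reverse_complement,
)
from .isomer_predictor import Molecule, MoleculeSet, predict_products
from .repeat_finder import Orientation, RepeatCopy, RepeatPair

__all__ = [
    "RepeatSpec",
    "MtptSpec",
    "ReadParams",
    "SimulationConfig",
    "random_dna",
    "generate_genome",
    "truth_repeat_pair",
    "MoleculePool",
    "PoolEntry",
    "simulate_molecule_pool",
    "simulate_reads",
    "apply_errors",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# minimum clearance between planted features, so repeat flanks stay unique
_PLANT_PAD = 1200


@dataclass(frozen=True)
class RepeatSpec:
    length: int
    identity: float = 100.0
    orientation: str = "direct"  # direct | inverted
    placement: str = "intra"  # intra | inter


@dataclass(frozen=True)
class MtptSpec:
    length: int
    identity: float = 100.0


@dataclass(frozen=True)
class ReadParams:
    count: int = 2000
    mean_length: float = 8000.0
    length_sigma_factor: float = 1.6  # log-normal sd factor
    error_rate: float = 0.05
    error_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # sub / ins / del
    min_length: int = 100
    max_length: int | None = None

    def __post_init__(self) -> None:
        if self.count < 0 or self.mean_length <= 0:
            raise ConfigError("read count must be >= 0 and mean_length > 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ConfigError("error_mix must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale defaults mirror the target genome's shape divided by ten:
    a 30 kb + 13 kb two-circle genome at GC 0.452."""

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (30_000, 13_000)
    gc: float = 0.452
    repeat_specs: tuple[RepeatSpec, ...] = (RepeatSpec(length=800),)
    alt_fractions: dict = field(default_factory=dict)  # pair_id -> fraction
    mtpt_specs: tuple[MtptSpec, ...] = ()
    cp_length: int = 16_000
    cp_gc: float = 0.38
    read_params: ReadParams = field(default_factory=ReadParams)

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ConfigError("gc must be in (0, 1)")
        for f in self.alt_fractions.values():
            if not 0 <= f <= 1:
                raise ConfigError("alt fractions must be in [0, 1]")
        for spec in self.repeat_specs:
            if spec.length < 1 or not 0 < spec.identity <= 100:
                raise ConfigError(f"invalid repeat spec {spec}")
            if spec.orientation not in ("direct", "inverted"):
                raise ConfigError(f"unknown orientation {spec.orientation!r}")
            if spec.placement not in ("intra", "inter"):
                raise ConfigError(f"unknown placement {spec.placement!r}")
            if spec.placement == "inter" and len(self.chromosome_lengths) < 2:
                raise ConfigError("inter-chromosomal repeat needs >= 2 chromosomes")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "repeats" in d:
            d["repeat_specs"] = tuple(RepeatSpec(**r) for r in d.pop("repeats"))
        if "mtpts" in d:
            d["mtpt_specs"] = tuple(MtptSpec(**m) for m in d.pop("mtpts"))
        if "reads" in d:
            rp = dict(d.pop("reads"))
            if "error_mix" in rp:
                rp["error_mix"] = tuple(rp["error_mix"])
            d["read_params"] = ReadParams(**rp)
        if "chromosome_lengths" in d:
            d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    n_mut = int(round(len(seq) * (1.0 - identity / 100.0)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = bytearray(seq, "ascii")
    for p in positions:
        choices = [b for b in b"ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return out.decode("ascii")


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    chrom_len: int,
    length: int,
    max_tries: int = 2000,
) -> int:
    """A start position whose padded window avoids all occupied windows."""
    if length > chrom_len - 2 * _PLANT_PAD:
        raise ConfigError(
            f"planted segment of {length} bp does not fit a {chrom_len} bp "
            f"chromosome with {_PLANT_PAD} bp clearance"
        )
    for _ in range(max_tries):
        start = int(rng.integers(_PLANT_PAD, chrom_len - length - _PLANT_PAD))
        lo, hi = start - _PLANT_PAD, start + length + _PLANT_PAD
        if all(hi <= s or e <= lo for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise ConfigError("could not place all planted features; chromosomes too crowded")


def generate_genome(config: SimulationConfig):
    """-> (mt GenomeSet, cp GenomeSet | None, truth dict).

    Chromosomes are random circles at the requested GC; each repeat spec
    copies a source window to a second locus (mutated to the requested
    identity, reverse-complemented when inverted); MTPT segments are copied
    from a jointly generated chloroplast circle.  The truth record stores
    all planted 0-based coordinates.
    """
    rng = np.random.default_rng([int(config.seed), 0x6E0])
    chroms = [
        bytearray(random_dna(rng, ln, config.gc), "ascii")
        for ln in config.chromosome_lengths
    ]
    ids = [f"chr{i + 1}" for i in range(len(chroms))]
    occupied: list[list[tuple[int, int]]] = [[] for _ in chroms]

    truth: dict = {"seed": int(config.seed), "repeats": [], "mtpts": []}
    for idx, spec in enumerate(config.repeat_specs):
        c1 = 0
        c2 = 0 if spec.placement == "intra" else 1
        s1 = _place(rng, occupied[c1], len(chroms[c1]), spec.length)
        s2 = _place(rng, occupied[c2], len(chroms[c2]), spec.length)
        if c1 == c2 and s2 < s1:
            s1, s2 = s2, s1
        source = chroms[c1][s1 : s1 + spec.length].decode("ascii")
        copy = _mutate_to_identity(rng, source, spec.identity)
        if spec.orientation == "inverted":
            copy = reverse_complement(copy)
        chroms[c2][s2 : s2 + spec.length] = copy.encode("ascii")
        truth["repeats"].append(
            {
                "pair_id": f"P{idx + 1}",
                "length": spec.length,
                "identity": spec.identity,
                "orientation": spec.orientation,
                "chrom1": ids[c1],
                "start1": s1,
                "chrom2": ids[c2],
                "start2": s2,
            }
        )

    cp_genome = None
    if config.mtpt_specs:
        cp_rng = np.random.default_rng([int(config.seed), 0xC9])
        cp_seq = random_dna(cp_rng, config.cp_length, config.cp_gc)
        cp_genome = GenomeSet([CircularSequence("cp1", cp_seq)])
        cp_occupied: list[tuple[int, int]] = []
        for idx, spec in enumerate(config.mtpt_specs):
            mt_idx = idx % len(chroms)
            cp_start = _place(cp_rng, cp_occupied, config.cp_length, spec.length)
            mt_start = _place(rng, occupied[mt_idx], len(chroms[mt_idx]), spec.length)
            segment = _mutate_to_identity(
                cp_rng, cp_seq[cp_start : cp_start + spec.length], spec.identity
            )
            chroms[mt_idx][mt_start : mt_start + spec.length] = segment.encode("ascii")
            truth["mtpts"].append(
                {
                    "id": f"M{idx + 1}",
                    "length": spec.length,
                    "identity": spec.identity,
                    "mt_chrom": ids[mt_idx],
                    "mt_start": mt_start,
                    "cp_chrom": "cp1",
                    "cp_start": cp_start,
                }
            )

    genome = GenomeSet(
        CircularSequence(cid, chrom.decode("ascii")) for cid, chrom in zip(ids, chroms)
    )
    return genome, cp_genome, truth


def truth_repeat_pair(genome: GenomeSet, record: dict) -> RepeatPair:
    """A :class:`RepeatPair` built from a planted-repeat truth record."""
    inverted = record["orientation"] == "inverted"
    s1, s2 = record["start1"], record["start2"]
    length = record["length"]
    iv1 = Interval(
        record["chrom1"], s1, s1 + length,
        Strand.MINUS if inverted else Strand.PLUS,
    )
    iv2 = Interval(record["chrom2"], s2, s2 + length)
    return RepeatPair(
        id=record["pair_id"],
        copy1=RepeatCopy(iv1, genome[iv1.chrom].slice0(s1, length)),
        copy2=RepeatCopy(iv2, genome[iv2.chrom].slice0(s2, length)),
        length=length,
        identity=record["identity"],
        orientation=Orientation.INVERTED if inverted else Orientation.DIRECT,
    )


# ---------------------------------------------------------------------------
# conformer pools and read simulation


@dataclass(frozen=True)
class PoolEntry:
    molecule: Molecule
    truth: str  # "major" | "alt"


@dataclass(frozen=True)
class MoleculePool:
    pair_id: str
    alt_fraction: float
    entries: tuple[PoolEntry, ...]

    def by_class(self, truth: str) -> list[Molecule]:
        return [e.molecule for e in self.entries if e.truth == truth]


def simulate_molecule_pool(
    genome: GenomeSet, pair: RepeatPair, alt_fraction: float
) -> MoleculePool:
    """Major host molecules plus the recombined products of one crossover;
    reads are later drawn from the recombined class with probability
    ``alt_fraction``."""
    if not 0 <= alt_fraction <= 1:
        raise ConfigError(f"alt_fraction must be in [0, 1], got {alt_fraction}")
    loc1, loc2 = pair.copy1.location, pair.copy2.location
    host_ids = list(dict.fromkeys([loc1.chrom, loc2.chrom]))
    majors = []
    for hid in host_ids:
        windows = [
            (loc.start, loc.end)
            for loc in (loc1, loc2)
            if loc.chrom == hid
        ]
        majors.append(
            Molecule.from_chromosome(genome[hid], windows=tuple(windows))
        )
    hosts = MoleculeSet(majors, provenance="major conformation")
    products = predict_products(hosts, pair, mode="sequence")
    entries = [PoolEntry(m, "major") for m in majors]
    entries += [PoolEntry(m, "alt") for m in products.molecules]
    return MoleculePool(pair.id, alt_fraction, tuple(entries))


def apply_errors(
    seq: str, rng: np.random.Generator, rate: float, mix: tuple[float, float, float]
) -> str:
    """Uniform per-base errors: substitutions, single-base insertions and
    deletions in the given proportions."""
    if rate <= 0 or not seq:
        return seq
    n = len(seq)
    n_err = rng.binomial(n, rate)
    if n_err == 0:
        return seq
    positions = np.sort(rng.choice(n, size=n_err, replace=False))
    kinds = rng.choice(3, size=n_err, p=list(mix))
    bases = "ACGT"
    parts: list[str] = []
    prev = 0
    for p, kind in zip(positions, kinds):
        parts.append(seq[prev : p])
        base = seq[p]
        if kind == 0:  # substitution
            others = bases.replace(base, "") if base in bases else bases
            parts.append(others[rng.integers(len(others))])
        elif kind == 1:  # insertion after the base
            parts.append(base + bases[rng.integers(4)])
        # kind == 2: deletion -> emit nothing
        prev = p + 1
    parts.append(seq[prev:])
    return "".join(parts)


def _wrap_slice(seq: str, start: int, length: int) -> str:
    n = len(seq)
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def simulate_reads(
    pool: MoleculePool | list[Molecule],
    params: ReadParams,
    seed: int,
    focus: bool = False,
):
    """-> (reads, truth table).

    Reads are drawn from random positions and strands of pool molecules
    (wrapping circles), with log-normal lengths and uniform errors.  With
    ``focus=True``, start positions are constrained so that reads span a
    repeat window of their source molecule with >= 150 bp to spare on both
    sides (desk-scale shortcut to guarantee informative spanning reads).
    """
    rng = np.random.default_rng([int(seed), 0x5EAD])
    if isinstance(pool, MoleculePool):
        majors = pool.by_class("major")
        alts = pool.by_class("alt")
        alt_fraction = pool.alt_fraction
    else:
        majors, alts, alt_fraction = list(pool), [], 0.0

    def weights(mols: list[Molecule]) -> np.ndarray:
        w = np.array([m.length for m in mols], dtype=float)
        return w / w.sum()

    w_major = weights(majors) if majors else None
    w_alt = weights(alts) if alts else None

    sigma = math.log(params.length_sigma_factor)
    mu = math.log(params.mean_length) - 0.5 * sigma * sigma
    pad = 150

    reads: list[Read] = []
    truth: dict[str, dict] = {}
    for i in range(params.count):
        use_alt = bool(alts) and rng.random() < alt_fraction
        mols, w = (alts, w_alt) if use_alt else (majors, w_major)
        mol = mols[int(rng.choice(len(mols), p=w))]
        length = int(round(float(rng.lognormal(mu, sigma))))
        if params.max_length is not None:
            length = min(length, params.max_length)
        length = max(params.min_length, min(length, mol.length))
        if focus and mol.repeat_windows:
            ws, we = mol.repeat_windows[int(rng.integers(len(mol.repeat_windows)))]
            span = we - ws
            if length >= span + 2 * pad:
                lo, hi = we + pad - length, ws - pad
                start = int(rng.integers(lo, hi + 1)) % mol.length
            else:
                start = int(rng.integers(mol.length))
        else:
            start = int(rng.integers(mol.length))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = _wrap_slice(mol.seq, start, length)
        if strand == "-":
            fragment = reverse_complement(fragment)
        observed = apply_errors(fragment, rng, params.error_rate, params.error_mix)
        rid = f"read{i:06d}"
        reads.append(Read(rid, observed, "I" * len(observed)))
        truth[rid] = {
            "molecule": mol.id,
            "class": "alt" if use_alt else "major",
            "start": start,
            "strand": strand,
            "template_length": length,
        }
    return reads, truth
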