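"""Products of one homologous-recombination event at a repeat pair.

Case analysis on circular molecules:

* direct pair, both copies on one circle  -> fission into two circles of
  lengths ``d`` and ``L - d`` (``d`` = start-to-start distance in the +
  direction);
* direct pair, one copy on each of two circles -> fusion into one circle of
  length ``L1 + L2``;
* inverted pair, one circle -> same-length circle with the segment between
  the copies reverse-complemented (an involution);
* inverted pair, two circles -> fused circle of length ``L1 + L2`` with one
  source molecule's contribution reverse-complemented.

Total length is conserved in every case.  In sequence mode the crossover is
placed at the repeat boundary so that each fission product carries one
intact repeat copy and a fusion product carries both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, TopologyError
from .genome_model import CircularSequence, GenomeSet, Topology, reverse_complement
from .repeat_finder import Orientation, RepeatPair

__all__ = ["Molecule", "MoleculeSet", "predict_products"]


@dataclass(frozen=True)
class Molecule:
    """A circular molecule, either with full sequence or as a length stub.

    ``repeat_windows`` records 0-based half-open spans of repeat copies on
    the molecule when known (used by the read simulator for focused
    sampling).
    """

    id: str
    length: int
    seq: str | None = None
    topology: Topology = Topology.CIRCULAR
    repeat_windows: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.seq is not None and len(self.seq) != self.length:
            raise InputError(
                f"molecule {self.id!r}: seq length {len(self.seq)} != {self.length}"
            )
        if not isinstance(self.topology, Topology):
            object.__setattr__(self, "topology", Topology(self.topology))

    @classmethod
    def from_chromosome(cls, chrom: CircularSequence, windows=()) -> "Molecule":
        return cls(chrom.id, chrom.length, chrom.seq, chrom.topology, tuple(windows))

    def to_chromosome(self) -> CircularSequence:
        if self.seq is None:
            raise InputError(f"molecule {self.id!r} is a length stub, has no sequence")
        return CircularSequence(self.id, self.seq, self.topology)


@dataclass
class MoleculeSet:
    molecules: list[Molecule] = field(default_factory=list)
    provenance: str = ""

    @classmethod
    def from_genome(cls, genome: GenomeSet, provenance: str = "input genome") -> "MoleculeSet":
        return cls([Molecule.from_chromosome(c) for c in genome], provenance)

    @classmethod
    def from_lengths(cls, lengths: dict[str, int], provenance: str = "length stubs") -> "MoleculeSet":
        return cls([Molecule(mid, ln) for mid, ln in lengths.items()], provenance)

    @property
    def total_length(self) -> int:
        return sum(m.length for m in self.molecules)

    def __getitem__(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise InputError(f"molecule {mol_id!r} not in set")


def _hosts(molecules: MoleculeSet, pair: RepeatPair) -> tuple[Molecule, Molecule]:
    host1 = molecules[pair.copy1.location.chrom]
    host2 = molecules[pair.copy2.location.chrom]
    for host in {host1.id: host1, host2.id: host2}.values():
        if host.topology is not Topology.CIRCULAR:
            raise TopologyError(
                f"molecule {host.id!r} is linear; recombination products are "
                "defined on circular molecules only"
            )
    for copy, host in ((pair.copy1, host1), (pair.copy2, host2)):
        if copy.location.end > host.length:
            raise InputError(
                f"repeat copy {copy.location.to_text()} outside molecule "
                f"{host.id!r} of length {host.length}"
            )
    return host1, host2


def predict_products(
    molecules: MoleculeSet, pair: RepeatPair, mode: str = "auto"
) -> MoleculeSet:
    """Products of one crossover at ``pair`` applied to ``molecules``.

    ``mode`` is ``"sequence"`` (full product sequences; hosts must carry
    sequence), ``"lengths"`` (length stubs only) or ``"auto"``.
    """
    host1, host2 = _hosts(molecules, pair)
    intra = host1.id == host2.id
    if mode == "auto":
        hosts_have_seq = host1.seq is not None and host2.seq is not None
        mode = "sequence" if hosts_have_seq else "lengths"
    if mode not in ("sequence", "lengths"):
        raise InputError(f"unknown mode {mode!r}")
    seq_mode = mode == "sequence"
    if seq_mode and (host1.seq is None or host2.seq is None):
        raise InputError("sequence mode requires host molecules with sequences")

    loc1, loc2 = pair.copy1.location, pair.copy2.location
    s1, e1 = loc1.start, loc1.end
    s2, e2 = loc2.start, loc2.end
    direct = pair.orientation is Orientation.DIRECT
    R = pair.copy1.seq  # consensus: products carry copy1's repeat sequence
    note = "; crossover at repeat boundary, exchanged region carries copy1 sequence"

    if direct and intra:
        if s1 > s2:
            s1, e1, s2, e2 = s2, e2, s1, e1
        L = host1.length
        d = (s2 - s1) % L
        prov = (
            f"fission of {host1.id} at direct pair {pair.id} "
            f"(d={d}, products {d} + {L - d}){note}"
        )
        if seq_mode:
            seq = host1.seq
            p1 = seq[s1:s2]  # = copy1 repeat + segment up to copy2
            p2 = R + seq[e2:] + seq[:s1]
            mols = [
                Molecule(f"{host1.id}.{pair.id}.fission1", len(p1), p1,
                         repeat_windows=((0, len(R)),)),
                Molecule(f"{host1.id}.{pair.id}.fission2", len(p2), p2,
                         repeat_windows=((0, len(R)),)),
            ]
        else:
            mols = [
                Molecule(f"{host1.id}.{pair.id}.fission1", d),
                Molecule(f"{host1.id}.{pair.id}.fission2", L - d),
            ]
        return MoleculeSet(mols, prov)

    if direct and not intra:
        prov = (
            f"fusion of {host1.id} + {host2.id} at direct pair {pair.id} "
            f"(product {host1.length + host2.length}){note}"
        )
        fused_id = f"{host1.id}+{host2.id}.{pair.id}.fusion"
        if seq_mode:
            a, b = host1.seq, host2.seq
            rest_a = a[e1:] + a[:s1]
            rest_b = b[e2:] + b[:s2]
            seq = R + rest_a + R + rest_b
            win2_start = len(R) + len(rest_a)
            mols = [
                Molecule(fused_id, len(seq), seq,
                         repeat_windows=((0, len(R)), (win2_start, win2_start + len(R))))
            ]
        else:
            mols = [Molecule(fused_id, host1.length + host2.length)]
        return MoleculeSet(mols, prov)

    if not direct and intra:
        if s1 > s2:
            s1, e1, s2, e2 = s2, e2, s1, e1
        prov = (
            f"inversion on {host1.id} at inverted pair {pair.id} "
            f"(segment [{e1}, {s2}) reverse-complemented, length unchanged)"
        )
        inv_id = f"{host1.id}.{pair.id}.inversion"
        if seq_mode:
            seq = host1.seq
            product = seq[:e1] + reverse_complement(seq[e1:s2]) + seq[s2:]
            mols = [
                Molecule(inv_id, len(product), product,
                         repeat_windows=((s1, e1), (s2, e2)))
            ]
        else:
            mols = [Molecule(inv_id, host1.length)]
        return MoleculeSet(mols, prov)

    # inverted, inter-molecular: fuse with host2's contribution flipped
    prov = (
        f"fusion of {host1.id} + reverse-complemented {host2.id} at inverted "
        f"pair {pair.id} (product {host1.length + host2.length}){note}"
    )
    fused_id = f"{host1.id}+{host2.id}rc.{pair.id}.fusion"
    if seq_mode:
        a, b = host1.seq, host2.seq
        rest_a = a[e1:] + a[:s1]
        r2_oriented = reverse_complement(b[s2:e2])
        rest_b = reverse_complement(b[:s2]) + reverse_complement(b[e2:])
        seq = R + rest_a + r2_oriented + rest_b
        win2_start = len(R) + len(rest_a)
        mols = [
            Molecule(fused_id, len(seq), seq,
                     repeat_windows=((0, len(R)), (win2_start, win2_start + (e2 - s2))))
        ]
    else:
        mols = [Molecule(fused_id, host1.length + host2.length)]
    return MoleculeSet(mols, prov)
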