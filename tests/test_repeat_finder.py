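import numpy as np
import pytest

from conftest import random_seq
from oracles import maximal_exact_pairs, rc

from mitorecomb.errors import ParameterError
from mitorecomb.genome_model import CircularSequence, GenomeSet
from mitorecomb.repeat_finder import (
    Orientation,
    SizeClass,
    classify_size,
    find_repeat_pairs,
    read_repeats_tsv,
    write_repeats_tsv,
)


_COMP = {ord("A"): ord("T"), ord("T"): ord("A"), ord("C"): ord("G"), ord("G"): ord("C")}


def plant(seq: str, src: int, dst: int, length: int, inverted=False) -> str:
    """Copy seq[src:src+length] to dst, guarding the boundaries so the exact
    match cannot extend by chance."""
    copy = seq[src : src + length]
    if inverted:
        copy = rc(copy)
    ba = bytearray(seq, "ascii")
    ba[dst : dst + length] = copy.encode()

    def break_match(pos: int, forbidden: int) -> None:
        # change ba[pos] to any base different from both its value and the
        # value that would let the exact match extend
        if 0 <= pos < len(ba) and ba[pos] == forbidden:
            for b in b"ACGT":
                if b != forbidden:
                    ba[pos] = b
                    break

    if not inverted:
        if src - 1 >= 0:
            break_match(dst - 1, ba[src - 1])
        if src + length < len(ba):
            break_match(dst + length, ba[src + length])
    else:
        # copy1 left boundary pairs with copy2 right boundary (complement)
        if src - 1 >= 0:
            break_match(dst + length, _COMP[ba[src - 1]])
        if src + length < len(ba):
            break_match(dst - 1, _COMP[ba[src + length]])
    return ba.decode()


def engine_key(pairs):
    return {
        (
            p.orientation.value,
            p.copy1.location.chrom,
            p.copy1.location.start,
            p.copy2.location.chrom,
            p.copy2.location.start,
            p.length,
        )
        for p in pairs
    }


class TestClassifySize:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (7887, SizeClass.LARGE),  # printed R1 length, grouped with long repeats
            (1235, SizeClass.LARGE),  # printed R2 length
            (331, SizeClass.MEDIUM),  # printed R4 length
            (244, SizeClass.MEDIUM),
            (163, SizeClass.MEDIUM),
            (89, SizeClass.SHORT),  # printed R15 length, a short repeat
            (99, SizeClass.SHORT),
            (100, SizeClass.MEDIUM),
            (1000, SizeClass.MEDIUM),
            (1001, SizeClass.LARGE),
        ],
    )
    def test_classes(self, length, expected):
        assert classify_size(length) is expected

    def test_invalid_length(self):
        with pytest.raises(ParameterError):
            classify_size(0)


class TestFindRepeatPairs:
    def test_planted_direct_pair_matches_oracle(self):
        seq = plant(random_seq(11, 50_000), 12_000, 31_000, 500)
        genome = GenomeSet([CircularSequence("chr1", seq)])
        pairs = find_repeat_pairs(genome, min_length=100, min_identity=100)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.length == 500
        assert p.identity == 100.0
        assert p.orientation is Orientation.DIRECT
        assert (p.copy1.location.start, p.copy2.location.start) == (12_000, 31_000)
        assert engine_key(pairs) == maximal_exact_pairs({"chr1": seq}, 100)

    def test_no_repeat_in_random_sequence(self):
        seq = random_seq(12, 20_000)
        genome = GenomeSet([CircularSequence("chr1", seq)])
        assert find_repeat_pairs(genome, min_length=100, min_identity=100) == []
        assert maximal_exact_pairs({"chr1": seq}, 100) == set()

    def test_planted_inverted_pair(self):
        seq = plant(random_seq(13, 30_000), 5_000, 20_000, 400, inverted=True)
        genome = GenomeSet([CircularSequence("chr1", seq)])
        pairs = find_repeat_pairs(genome, min_length=100, min_identity=100)
        assert len(pairs) == 1
        assert pairs[0].orientation is Orientation.INVERTED
        assert pairs[0].length == 400
        # inverted relation between the stored plus-strand copies
        assert rc(pairs[0].copy1.seq) == pairs[0].copy2.seq
        assert engine_key(pairs) == maximal_exact_pairs({"chr1": seq}, 100)

    def test_inter_chromosomal_pair(self):
        s1 = random_seq(14, 25_000)
        s2 = bytearray(random_seq(15, 12_000), "ascii")
        s2[4_000:4_600] = s1[9_000:9_600].encode()
        s2 = s2.decode()
        genome = GenomeSet(
            [CircularSequence("chr1", s1), CircularSequence("chr2", s2)]
        )
        pairs = find_repeat_pairs(genome, min_length=100, min_identity=100)
        assert len(pairs) == 1
        p = pairs[0]
        assert not p.is_intra
        assert p.copy1.location.chrom == "chr1"
        assert p.length >= 600

    def test_diverged_pair_identity(self):
        # plant at 97% identity via substitutions
        base = random_seq(16, 30_000)
        seg = list(base[8_000:8_800])
        rng = np.random.default_rng(17)
        for pos in rng.choice(800, size=24, replace=False):
            seg[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[pos]]
        ba = bytearray(base, "ascii")
        ba[22_000:22_800] = "".join(seg).encode()
        genome = GenomeSet([CircularSequence("chr1", ba.decode())])
        pairs = find_repeat_pairs(genome, min_length=100, min_identity=90)
        assert len(pairs) == 1
        assert abs(pairs[0].identity - 97.0) <= 1.0
        assert abs(pairs[0].length - 800) <= 5

    def test_symmetry_under_chromosome_swap(self):
        s1 = random_seq(18, 20_000)
        s2 = bytearray(random_seq(19, 15_000), "ascii")
        s2[2_000:2_300] = s1[11_000:11_300].encode()
        s2 = s2.decode()
        a = GenomeSet([CircularSequence("chr1", s1), CircularSequence("chr2", s2)])
        b = GenomeSet([CircularSequence("chr2", s2), CircularSequence("chr1", s1)])
        assert engine_key(find_repeat_pairs(a, 100, 100)) == engine_key(
            find_repeat_pairs(b, 100, 100)
        )

    def test_sorted_by_length_with_sequential_ids(self):
        seq = plant(random_seq(20, 60_000), 2_000, 30_000, 300)
        seq = plant(seq, 10_000, 45_000, 900)
        genome = GenomeSet([CircularSequence("chr1", seq)])
        pairs = find_repeat_pairs(genome, min_length=100, min_identity=100)
        assert [p.id for p in pairs] == ["R1", "R2"]
        assert pairs[0].length >= pairs[1].length
        assert pairs[0].length == 900

    def test_min_length_validation(self):
        genome = GenomeSet([CircularSequence("chr1", "ACGT" * 100)])
        with pytest.raises(ParameterError):
            find_repeat_pairs(genome, min_length=19)

    def test_empty_genome(self):
        assert find_repeat_pairs(GenomeSet()) == []

    def test_planting_recovery_many_random_genomes(self):
        """Recovery of 1-5 planted pairs per genome over 50 seeded genomes,
        both orientations, identities 95-100, boundary error <= 5 bp."""
        master = np.random.default_rng(777)
        for trial in range(50):
            rng = np.random.default_rng([777, trial])
            n_pairs = int(rng.integers(1, 6))
            glen = 60_000
            seq = random_seq(rng, glen)
            planted = []
            cursor = 1_000
            for _ in range(n_pairs):
                length = int(np.exp(rng.uniform(np.log(89), np.log(2_500))))
                identity = float(rng.uniform(95, 100))
                inverted = bool(rng.random() < 0.5)
                src, dst = cursor, cursor + length + 1_500
                cursor = dst + length + 1_500
                if cursor >= glen:
                    break
                seg = list(seq[src : src + length])
                n_mut = int(round(length * (1 - identity / 100)))
                for pos in rng.choice(length, size=n_mut, replace=False):
                    seg[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[pos]]
                copy = "".join(seg)
                if inverted:
                    copy = rc(copy)
                ba = bytearray(seq, "ascii")
                ba[dst : dst + length] = copy.encode()
                seq = ba.decode()
                planted.append((src, dst, length, inverted))
            genome = GenomeSet([CircularSequence("chr1", seq)])
            pairs = find_repeat_pairs(genome, min_length=50, min_identity=90)
            for src, dst, length, inverted in planted:
                match = [
                    p
                    for p in pairs
                    if abs(p.copy1.location.start - src) <= 5
                    and abs(p.copy2.location.start - dst) <= 5
                    and abs(p.length - length) <= 5
                    and (p.orientation is Orientation.INVERTED) == inverted
                ]
                assert match, (
                    f"trial {trial}: planted pair at ({src}, {dst}, {length}, "
                    f"inverted={inverted}) not recovered"
                )


class TestRepeatTsv:
    def test_roundtrip_including_inverted_convention(self, tmp_path):
        seq = plant(random_seq(30, 30_000), 4_000, 18_000, 600, inverted=True)
        seq = plant(seq, 9_000, 25_000, 250)
        genome = GenomeSet([CircularSequence("chr1", seq)])
        pairs = find_repeat_pairs(genome, min_length=100, min_identity=100)
        path = tmp_path / "repeats.tsv"
        write_repeats_tsv(pairs, path)
        text = path.read_text()
        inv = next(p for p in pairs if p.orientation is Orientation.INVERTED)
        # inverted pairs print copy1 with reversed (start > end) coordinates
        lo, hi = inv.copy1.location.start + 1, inv.copy1.location.end
        assert f"chr1: {hi}-{lo}" in text
        back = read_repeats_tsv(path, genome)
        assert engine_key(back) == engine_key(pairs)
        assert [p.identity for p in back] == [p.identity for p in pairs]
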