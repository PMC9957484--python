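import numpy as np
import pytest

from conftest import random_seq
from oracles import rc, rotations_equal

from mitorecomb.errors import InputError, TopologyError
from mitorecomb.genome_model import CircularSequence, GenomeSet, Interval, Strand
from mitorecomb.isomer_predictor import Molecule, MoleculeSet, predict_products
from mitorecomb.repeat_finder import Orientation, RepeatCopy, RepeatPair


def stub_pair(c1, s1, c2, s2, length, inverted=False, pair_id="R"):
    strand1 = Strand.MINUS if inverted else Strand.PLUS
    return RepeatPair(
        id=pair_id,
        copy1=RepeatCopy(Interval(c1, s1, s1 + length, strand1), "A" * length),
        copy2=RepeatCopy(Interval(c2, s2, s2 + length), "A" * length),
        length=length,
        identity=100.0,
        orientation=Orientation.INVERTED if inverted else Orientation.DIRECT,
    )


def seq_pair(genome, c1, s1, c2, s2, length, inverted=False):
    strand1 = Strand.MINUS if inverted else Strand.PLUS
    return RepeatPair(
        id="R",
        copy1=RepeatCopy(
            Interval(c1, s1, s1 + length, strand1), genome[c1].slice0(s1, length)
        ),
        copy2=RepeatCopy(Interval(c2, s2, s2 + length), genome[c2].slice0(s2, length)),
        length=length,
        identity=100.0,
        orientation=Orientation.INVERTED if inverted else Orientation.DIRECT,
    )


def count_occurrences(circle: str, probe: str) -> int:
    doubled = circle + circle[: len(probe) - 1]
    n = start = 0
    while True:
        i = doubled.find(probe, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


class TestLengthArithmetic:
    def test_intra_direct_fission_printed_positions(self):
        # chromosome 1 with the two printed copy start positions of the
        # largest direct pair: d = 299834 - 107714 = 192120
        stubs = MoleculeSet.from_lengths({"chr1": 307_720})
        pair = stub_pair("chr1", 107_713, "chr1", 299_833, 7_887)
        products = predict_products(stubs, pair, mode="lengths")
        assert sorted(m.length for m in products.molecules) == [115_600, 192_120]
        assert products.total_length == 307_720

    def test_inter_direct_fusion_printed_lengths(self):
        stubs = MoleculeSet.from_lengths({"chr1": 307_720, "chr2": 128_744})
        pair = stub_pair("chr1", 63_770, "chr2", 0, 1_235)
        products = predict_products(stubs, pair, mode="lengths")
        assert [m.length for m in products.molecules] == [436_464]

    def test_inverted_intra_preserves_length(self):
        stubs = MoleculeSet.from_lengths({"chr1": 50_000})
        pair = stub_pair("chr1", 5_000, "chr1", 30_000, 400, inverted=True)
        products = predict_products(stubs, pair, mode="lengths")
        assert [m.length for m in products.molecules] == [50_000]

    def test_inverted_inter_fusion_length(self):
        stubs = MoleculeSet.from_lengths({"chr1": 40_000, "chr2": 25_000})
        pair = stub_pair("chr1", 5_000, "chr2", 9_000, 300, inverted=True)
        products = predict_products(stubs, pair, mode="lengths")
        assert [m.length for m in products.molecules] == [65_000]

    def test_length_conservation_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            case = int(rng.integers(4))
            L1 = int(rng.integers(10_000, 100_000))
            L2 = int(rng.integers(10_000, 100_000))
            length = int(rng.integers(60, 2_000))
            if case in (0, 2):  # intra
                s1 = int(rng.integers(0, L1 // 2 - length))
                s2 = int(rng.integers(L1 // 2, L1 - length))
                stubs = MoleculeSet.from_lengths({"c1": L1})
                pair = stub_pair("c1", s1, "c1", s2, length, inverted=case == 2)
                expected = L1
            else:  # inter
                s1 = int(rng.integers(0, L1 - length))
                s2 = int(rng.integers(0, L2 - length))
                stubs = MoleculeSet.from_lengths({"c1": L1, "c2": L2})
                pair = stub_pair("c1", s1, "c2", s2, length, inverted=case == 3)
                expected = L1 + L2
            products = predict_products(stubs, pair, mode="lengths")
            assert products.total_length == expected


class TestSequenceSurgery:
    """Marker-based cut-and-rejoin oracle on small circles."""

    @pytest.fixture
    def fission_setup(self):
        # circle: [R at 500] [marker X in arc1] [R at 4000] [marker Y in arc2]
        rng = np.random.default_rng(5)
        seq = bytearray(random_seq(rng, 8_000), "ascii")
        R = random_seq(rng, 300)
        X = random_seq(rng, 40)
        Y = random_seq(rng, 40)
        seq[500:800] = R.encode()
        seq[2_000:2_040] = X.encode()
        seq[4_000:4_300] = R.encode()
        seq[6_000:6_040] = Y.encode()
        genome = GenomeSet([CircularSequence("c1", seq.decode())])
        return genome, R, X, Y

    def test_fission_products_partition_markers(self, fission_setup):
        genome, R, X, Y = fission_setup
        pair = seq_pair(genome, "c1", 500, "c1", 4_000, 300)
        products = predict_products(MoleculeSet.from_genome(genome), pair, "sequence")
        assert len(products.molecules) == 2
        seqs = [m.seq for m in products.molecules]
        assert sorted(len(s) for s in seqs) == [3_500, 4_500]
        with_x = [s for s in seqs if X in s + s]
        with_y = [s for s in seqs if Y in s + s]
        assert len(with_x) == 1 and len(with_y) == 1 and with_x[0] != with_y[0]
        for s in seqs:
            assert count_occurrences(s, R) == 1  # one repeat copy each

    def test_fission_matches_cut_and_rejoin_strings(self, fission_setup):
        genome, R, X, Y = fission_setup
        pair = seq_pair(genome, "c1", 500, "c1", 4_000, 300)
        products = predict_products(MoleculeSet.from_genome(genome), pair, "sequence")
        src = genome["c1"].seq
        arc1 = src[500:4_000]  # cut at both repeat starts
        arc2 = src[4_000:] + src[:500]
        got = sorted((m.seq for m in products.molecules), key=len)
        expected = sorted((arc1, arc2), key=len)
        for g, e in zip(got, expected):
            assert rotations_equal(g, e)

    def test_fusion_carries_both_markers_and_two_copies(self):
        rng = np.random.default_rng(6)
        a = bytearray(random_seq(rng, 6_000), "ascii")
        b = bytearray(random_seq(rng, 4_000), "ascii")
        R = random_seq(rng, 250)
        X = random_seq(rng, 40)
        Y = random_seq(rng, 40)
        a[1_000:1_250] = R.encode()
        a[3_000:3_040] = X.encode()
        b[500:750] = R.encode()
        b[2_000:2_040] = Y.encode()
        genome = GenomeSet(
            [CircularSequence("c1", a.decode()), CircularSequence("c2", b.decode())]
        )
        pair = seq_pair(genome, "c1", 1_000, "c2", 500, 250)
        products = predict_products(MoleculeSet.from_genome(genome), pair, "sequence")
        assert len(products.molecules) == 1
        fused = products.molecules[0].seq
        assert len(fused) == 10_000
        assert X in fused + fused and Y in fused + fused
        assert count_occurrences(fused, R) == 2

    def test_inversion_is_involution_and_flips_middle(self):
        rng = np.random.default_rng(7)
        seq = bytearray(random_seq(rng, 6_000), "ascii")
        R = random_seq(rng, 200)
        M = random_seq(rng, 40)
        seq[800:1_000] = R.encode()
        seq[2_500:2_540] = M.encode()
        seq[4_200:4_400] = rc(R).encode()
        genome = GenomeSet([CircularSequence("c1", seq.decode())])
        pair = seq_pair(genome, "c1", 800, "c1", 4_200, 200, inverted=True)
        products = predict_products(MoleculeSet.from_genome(genome), pair, "sequence")
        assert len(products.molecules) == 1
        out = products.molecules[0].seq
        assert len(out) == 6_000
        assert M not in out and rc(M) in out  # intervening segment flipped
        # applying the event again restores the original sequence
        genome2 = GenomeSet([CircularSequence("c1", out)])
        pair2 = seq_pair(genome2, "c1", 800, "c1", 4_200, 200, inverted=True)
        back = predict_products(MoleculeSet.from_genome(genome2), pair2, "sequence")
        assert back.molecules[0].seq == genome["c1"].seq

    def test_inverted_inter_fusion_sequence(self):
        rng = np.random.default_rng(8)
        a = bytearray(random_seq(rng, 5_000), "ascii")
        b = bytearray(random_seq(rng, 3_000), "ascii")
        R = random_seq(rng, 220)
        Y = random_seq(rng, 40)
        a[1_000:1_220] = R.encode()
        b[400:620] = rc(R).encode()
        b[1_500:1_540] = Y.encode()
        genome = GenomeSet(
            [CircularSequence("c1", a.decode()), CircularSequence("c2", b.decode())]
        )
        pair = seq_pair(genome, "c1", 1_000, "c2", 400, 220, inverted=True)
        products = predict_products(MoleculeSet.from_genome(genome), pair, "sequence")
        fused = products.molecules[0].seq
        assert len(fused) == 8_000
        assert rc(Y) in fused + fused  # chr2 contribution arrives flipped
        assert count_occurrences(fused, R) == 2


class TestErrors:
    def test_linear_host_rejected(self):
        mols = MoleculeSet([Molecule("c1", 10_000, topology="linear")])
        pair = stub_pair("c1", 100, "c1", 5_000, 200)
        with pytest.raises(TopologyError):
            predict_products(mols, pair)

    def test_missing_molecule(self):
        mols = MoleculeSet.from_lengths({"c1": 10_000})
        pair = stub_pair("c1", 100, "c2", 500, 200)
        with pytest.raises(InputError):
            predict_products(mols, pair)

    def test_copy_outside_molecule(self):
        mols = MoleculeSet.from_lengths({"c1": 1_000})
        pair = stub_pair("c1", 100, "c1", 900, 200)
        with pytest.raises(InputError):
            predict_products(mols, pair)
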