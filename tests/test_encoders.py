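"""Encoder unit tests, including independent brute-force oracles.

The oracles re-derive every descriptor with plain string operations
(str.count, dict lookups) so they share no code with the numpy encoders
they check.
"""

import numpy as np
import pytest

from pseusite.encoders import (
    DESCRIPTORS,
    DINUCLEOTIDES,
    NCP_TABLE,
    NUCLEOTIDES,
    EncoderError,
    FeatureMatrix,
    PropensityTable,
    PseDncConfig,
    descriptor_dimension,
    encode_dataset,
    encode_kd,
    encode_kmer,
    encode_ncp,
    encode_one_hot,
    encode_psednc,
    encode_pskp,
    fit_pskp,
)
from pseusite.sequences import RnaSequence
from pseusite.simulate import FixtureSpec, generate_dataset

from conftest import random_rna


# ---------------------------------------------------------------------------
# independent oracles


def oracle_one_hot(seq: str) -> list[float]:
    out = []
    for nt in seq:
        out.extend(1.0 if nt == x else 0.0 for x in "AUCG")
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        out.extend(1.0 if di == x else 0.0 for x in DINUCLEOTIDES)
    return out


def oracle_kmer(seq: str) -> list[float]:
    mono = [seq.count(x) / len(seq) for x in "AUCG"]
    dis = [seq[i : i + 2] for i in range(len(seq) - 1)]
    di = [dis.count(x) / len(dis) for x in DINUCLEOTIDES]
    return mono + di


def oracle_kd(seq: str) -> list[float]:
    mono = [seq[: i + 1].count(seq[i]) / (i + 1) for i in range(len(seq))]
    dis = [seq[i : i + 2] for i in range(len(seq) - 1)]
    di = [dis[: i + 1].count(dis[i]) / (i + 1) for i in range(len(dis))]
    return mono + di


def oracle_ncp(seq: str) -> list[float]:
    table = {"A": [1, 1, 1], "U": [0, 0, 1], "C": [0, 1, 0], "G": [1, 0, 0]}
    return [float(v) for nt in seq for v in table[nt]]


def oracle_pskp(seq: str, pos: list[str], neg: list[str]) -> list[float]:
    def freq(group, i, sym):
        return sum(s[i : i + len(sym)] == sym for s in group) / len(group)

    mono = [
        freq(pos, i, seq[i]) - freq(neg, i, seq[i]) for i in range(len(seq))
    ]
    di = [
        freq(pos, i, seq[i : i + 2]) - freq(neg, i, seq[i : i + 2])
        for i in range(len(seq) - 1)
    ]
    return mono + di


def oracle_psednc(seq: str, config: PseDncConfig) -> list[float]:
    dis = [seq[i : i + 2] for i in range(len(seq) - 1)]
    freqs = [dis.count(x) / len(dis) for x in DINUCLEOTIDES]
    props = {d: config.property_table[k] for k, d in enumerate(DINUCLEOTIDES)}

    def theta(j):
        pairs = [(dis[i], dis[i + j]) for i in range(len(dis) - j)]
        vals = [
            sum((props[a][u] - props[b][u]) ** 2 for u in range(3)) / 3
            for a, b in pairs
        ]
        return sum(vals) / len(vals)

    thetas = [theta(j) for j in range(1, config.lambda_pse + 1)]
    denom = 1 + config.weight_w * sum(thetas)
    return [f / denom for f in freqs] + [
        config.weight_w * t / denom for t in thetas
    ]


# ---------------------------------------------------------------------------


@pytest.mark.parametrize("lam", [5, 21, 31])
@pytest.mark.parametrize("descriptor", DESCRIPTORS)
def test_dimensionality_contract(rng, lam, descriptor, small_dataset):
    seq = random_rna(rng, lam)
    expected = descriptor_dimension(descriptor, lam)
    if descriptor == "PSKP":
        group = [random_rna(rng, lam, f"g{i}") for i in range(4)]
        vec = encode_pskp(seq, fit_pskp(group[:2], group[2:]))
    elif descriptor == "PSEDNC":
        vec = encode_psednc(seq)
    else:
        encoder = {
            "ONEHOT": encode_one_hot,
            "KMER": encode_kmer,
            "KD": encode_kd,
            "NCP": encode_ncp,
        }[descriptor]
        vec = encoder(seq)
    assert vec.shape == (expected,)


class TestOneHot:
    def test_single_nucleotide_printed_example(self):
        assert encode_one_hot(RnaSequence("s", "A")).tolist() == [1, 0, 0, 0]

    @pytest.mark.parametrize("lam, dim", [(21, 404), (31, 604)])
    def test_formula_values(self, rng, lam, dim):
        assert encode_one_hot(random_rna(rng, lam)).shape == (dim,)

    def test_dinucleotide_block_layout(self):
        vec = encode_one_hot(RnaSequence("s", "AU"))
        assert vec[:8].tolist() == [1, 0, 0, 0, 0, 1, 0, 0]
        di_block = vec[8:]
        assert di_block.sum() == 1
        assert di_block[DINUCLEOTIDES.index("AU")] == 1

    def test_every_block_sums_to_one(self, rng):
        vec = encode_one_hot(random_rna(rng, 21))
        blocks = [vec[4 * i : 4 * (i + 1)] for i in range(21)]
        blocks += [vec[84 + 16 * i : 84 + 16 * (i + 1)] for i in range(20)]
        assert all(b.sum() == 1 for b in blocks)


class TestKmer:
    def test_homopolymer(self):
        vec = encode_kmer(RnaSequence("s", "AAAA"))
        assert vec[0] == 1.0 and vec[1:4].sum() == 0
        assert vec[4 + DINUCLEOTIDES.index("AA")] == 1.0

    def test_auau_frequencies(self):
        vec = encode_kmer(RnaSequence("s", "AUAU"))
        assert vec[0] == vec[1] == 0.5
        assert vec[4 + DINUCLEOTIDES.index("AU")] == pytest.approx(2 / 3)
        assert vec[4 + DINUCLEOTIDES.index("UA")] == pytest.approx(1 / 3)

    def test_groups_sum_to_one(self, rng):
        vec = encode_kmer(random_rna(rng, 21))
        assert vec[:4].sum() == pytest.approx(1)
        assert vec[4:].sum() == pytest.approx(1)

    def test_too_short_rejected(self):
        with pytest.raises(EncoderError):
            encode_kmer(RnaSequence("s", "A"))


class TestKd:
    @pytest.mark.parametrize(
        "seq, mono",
        [
            ("AAAA", [1, 1, 1, 1]),
            ("AUAU", [1, 1 / 2, 2 / 3, 1 / 2]),
            ("GACU", [1, 1 / 2, 1 / 3, 1 / 4]),
        ],
    )
    def test_prefix_density_examples(self, seq, mono):
        vec = encode_kd(RnaSequence("s", seq))
        assert vec[: len(seq)] == pytest.approx(mono)

    def test_values_in_unit_interval_and_homopolymer_all_ones(self, rng):
        vec = encode_kd(random_rna(rng, 31))
        assert np.all(vec > 0) and np.all(vec <= 1)
        homo = encode_kd(RnaSequence("s", "U" * 10))
        assert np.all(homo == 1.0)


class TestNcp:
    @pytest.mark.parametrize(
        "nt, triple",
        [("A", (1, 1, 1)), ("U", (0, 0, 1)), ("C", (0, 1, 0)), ("G", (1, 0, 0))],
    )
    def test_printed_mapping(self, nt, triple):
        assert tuple(encode_ncp(RnaSequence("s", nt))) == triple
        assert NCP_TABLE[nt] == triple

    def test_concatenation(self):
        assert encode_ncp(RnaSequence("s", "AU")).tolist() == [1, 1, 1, 0, 0, 1]


class TestPskp:
    def test_identical_sets_give_zero_table(self, rng):
        group = [random_rna(rng, 9, f"s{i}") for i in range(5)]
        table = fit_pskp(group, group)
        assert np.all(table.mono == 0) and np.all(table.di == 0)
        assert np.all(encode_pskp(group[0], table) == 0)

    def test_two_sequence_worked_example(self):
        pos = [RnaSequence("p1", "AU"), RnaSequence("p2", "AU")]
        neg = [RnaSequence("n1", "AU"), RnaSequence("n2", "GU")]
        table = fit_pskp(pos, neg)
        assert table.mono[0, NUCLEOTIDES.index("A")] == pytest.approx(0.5)
        assert table.mono[0, NUCLEOTIDES.index("G")] == pytest.approx(-0.5)
        assert table.mono[1, NUCLEOTIDES.index("U")] == 0
        vec = encode_pskp(RnaSequence("q", "AU"), table)
        assert vec[:2] == pytest.approx([0.5, 0.0])
        assert vec.shape == (3,)

    def test_position_rows_sum_to_zero(self, rng):
        pos = [random_rna(rng, 21, f"p{i}") for i in range(10)]
        neg = [random_rna(rng, 21, f"n{i}") for i in range(10)]
        table = fit_pskp(pos, neg)
        assert table.mono.sum(axis=1) == pytest.approx(np.zeros(21), abs=1e-12)
        assert table.di.sum(axis=1) == pytest.approx(np.zeros(20), abs=1e-12)
        assert np.abs(table.mono).max() <= 1 and np.abs(table.di).max() <= 1

    def test_heterogeneous_lengths_rejected(self, rng):
        with pytest.raises(EncoderError):
            fit_pskp([random_rna(rng, 9)], [random_rna(rng, 11)])

    def test_length_mismatch_on_encode(self, rng):
        pos = [random_rna(rng, 9, f"p{i}") for i in range(3)]
        neg = [random_rna(rng, 9, f"n{i}") for i in range(3)]
        with pytest.raises(EncoderError):
            encode_pskp(random_rna(rng, 11), fit_pskp(pos, neg))

    def test_tsv_round_trip(self, rng, tmp_path):
        pos = [random_rna(rng, 9, f"p{i}") for i in range(4)]
        neg = [random_rna(rng, 9, f"n{i}") for i in range(4)]
        table = fit_pskp(pos, neg)
        table.to_tsv(tmp_path / "t.tsv")
        loaded = PropensityTable.from_tsv(tmp_path / "t.tsv")
        assert np.allclose(loaded.mono, table.mono)
        assert np.allclose(loaded.di, table.di)


class TestPseDnc:
    def test_property_table_is_standardized(self):
        table = PseDncConfig().property_table
        assert table.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-9)
        assert table.var(axis=0) == pytest.approx(np.ones(3), abs=1e-9)

    def test_zero_tiers_collapse_to_composition(self, rng):
        seq = random_rna(rng, 21)
        vec = encode_psednc(seq, PseDncConfig(lambda_pse=0))
        assert vec.shape == (16,)
        assert vec.sum() == pytest.approx(1)
        assert np.allclose(vec, oracle_kmer(seq.residues)[4:])

    @pytest.mark.parametrize("lambda_pse, w", [(1, 0.05), (2, 0.1), (5, 0.9)])
    def test_components_nonnegative_and_sum_to_one(self, rng, lambda_pse, w):
        vec = encode_psednc(
            random_rna(rng, 21), PseDncConfig(lambda_pse=lambda_pse, weight_w=w)
        )
        assert vec.shape == (16 + lambda_pse,)
        assert np.all(vec >= 0)
        assert vec.sum() == pytest.approx(1)

    def test_homopolymer_thetas_vanish(self):
        seq = RnaSequence("s", "A" * 15)
        vec = encode_psednc(seq, PseDncConfig(lambda_pse=3))
        base = encode_psednc(seq, PseDncConfig(lambda_pse=0))
        assert np.allclose(vec[:16], base)
        assert np.all(vec[16:] == 0)

    def test_lambda_pse_too_large_rejected(self):
        with pytest.raises(EncoderError):
            encode_psednc(RnaSequence("s", "AUGC"), PseDncConfig(lambda_pse=3))
        with pytest.raises(EncoderError):
            PseDncConfig(weight_w=0)


ORACLES = {
    "ONEHOT": lambda s, pos, neg, cfg: oracle_one_hot(s),
    "KMER": lambda s, pos, neg, cfg: oracle_kmer(s),
    "KD": lambda s, pos, neg, cfg: oracle_kd(s),
    "NCP": lambda s, pos, neg, cfg: oracle_ncp(s),
    "PSKP": lambda s, pos, neg, cfg: oracle_pskp(s, pos, neg),
    "PSEDNC": lambda s, pos, neg, cfg: oracle_psednc(s, cfg),
}


@pytest.mark.parametrize("descriptor", DESCRIPTORS)
def test_encoders_match_brute_force_oracle(descriptor):
    """Each encoder agrees with an independent string-based recount on
    100 random length-21 sequences."""
    rng = np.random.default_rng(5)
    sequences = [random_rna(rng, 21, f"s{i}") for i in range(100)]
    pos_raw = [s.residues for s in sequences[:50]]
    neg_raw = [s.residues for s in sequences[50:]]
    config = PseDncConfig()
    table = fit_pskp(sequences[:50], sequences[50:])
    for seq in sequences:
        if descriptor == "PSKP":
            vec = encode_pskp(seq, table)
        elif descriptor == "PSEDNC":
            vec = encode_psednc(seq, config)
        else:
            vec = {
                "ONEHOT": encode_one_hot,
                "KMER": encode_kmer,
                "KD": encode_kd,
                "NCP": encode_ncp,
            }[descriptor](seq)
        expected = ORACLES[descriptor](seq.residues, pos_raw, neg_raw, config)
        assert np.allclose(vec, expected, atol=1e-12), seq.residues


class TestEncodeDataset:
    def test_shapes_and_label_carry_through(self, small_dataset):
        dataset, _ = small_dataset
        kmer = encode_dataset(dataset, "KMER")
        assert kmer.values.shape == (60, 20)
        assert kmer.labels.tolist() == dataset.labels.tolist()
        onehot = encode_dataset(dataset, "ONEHOT")
        assert onehot.values.shape == (60, 404)

    def test_row_order_preserved(self, small_dataset):
        dataset, _ = small_dataset
        matrix = encode_dataset(dataset, "NCP")
        assert np.allclose(matrix.values[7], encode_ncp(dataset.sequences[7]))

    def test_pskp_without_table_rejected(self, small_dataset):
        dataset, _ = small_dataset
        with pytest.raises(EncoderError, match="PropensityTable"):
            encode_dataset(dataset, "PSKP")

    def test_unknown_descriptor_and_empty_dataset(self, small_dataset):
        dataset, _ = small_dataset
        with pytest.raises(EncoderError):
            encode_dataset(dataset, "WAVELET")
        from pseusite.sequences import LabeledDataset

        with pytest.raises(EncoderError):
            encode_dataset(LabeledDataset([], np.array([])), "KMER")

    def test_matrix_tsv_round_trip(self, small_dataset, tmp_path):
        dataset, _ = small_dataset
        matrix = encode_dataset(dataset, "KMER")
        matrix.to_tsv(tmp_path / "m.tsv")
        loaded = FeatureMatrix.from_tsv(tmp_path / "m.tsv", "KMER")
        assert np.allclose(loaded.values, matrix.values)
        assert loaded.feature_names == matrix.feature_names
        assert loaded.labels.tolist() == matrix.labels.tolist()
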