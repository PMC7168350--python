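from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fourmc as fm
from fourmc.encoders import (ALPHA5, EIIP_VALUES, MBE_CHANNELS,
                             PropertyTable, default_property_table)
from fourmc.io import Dataset, SequenceWindow

W = 41
DIMS = {"KMER": 750, "KSNC": 100, "MBE": 205, "DBE": 160, "EIIP": 41,
        "DPC": 375}

ENCODE = {
    "KMER": fm.encode_kmer,
    "KSNC": fm.encode_ksnc,
    "MBE": fm.encode_mbe,
    "DBE": fm.encode_dbe,
    "EIIP": fm.encode_eiip,
    "DPC": fm.encode_dpc,
}


# --------------------------------------------------------------------------
# independent brute-force oracles

def oracle_kmer(seq):
    out = []
    for k in (3, 4):
        for mer in ("".join(m) for m in product(ALPHA5, repeat=k)):
            count = sum(seq[p:p + k] == mer for p in range(len(seq) - k + 1))
            out.append(count / (len(seq) - k + 1))
    return np.array(out)


def oracle_ksnc(seq, dmax=3):
    out = []
    for d in range(dmax + 1):
        for pair in ("".join(p) for p in product(ALPHA5, repeat=2)):
            hits = sum(seq[p] == pair[0] and seq[p + d + 1] == pair[1]
                       for p in range(len(seq) - d - 1))
            out.append(hits / (len(seq) - d - 1))
    return np.array(out)


def oracle_mbe(seq):
    return np.array([1.0 if b == c else 0.0
                     for b in seq for c in MBE_CHANNELS])


def oracle_dbe(seq):
    code = {"A": "00", "T": "01", "C": "10", "G": "11"}
    bits = []
    for p in range(len(seq) - 1):
        pair = seq[p:p + 2]
        if "N" in pair:
            bits.extend("0000")
        else:
            bits.extend(code[pair[0]] + code[pair[1]])
    return np.array([float(b) for b in bits])


def oracle_eiip(seq):
    return np.array([EIIP_VALUES[b] for b in seq])


def oracle_dpc(seq, table=None):
    table = table or default_property_table()
    out = []
    for pair in ("".join(p) for p in product(ALPHA5, repeat=2)):
        freq = sum(seq[p:p + 2] == pair
                   for p in range(len(seq) - 1)) / (len(seq) - 1)
        for prop in table.property_names:
            out.append(freq * table.value(pair, prop))
    return np.array(out)


ORACLE = {"KMER": oracle_kmer, "KSNC": oracle_ksnc, "MBE": oracle_mbe,
          "DBE": oracle_dbe, "EIIP": oracle_eiip, "DPC": oracle_dpc}


# --------------------------------------------------------------------------

@pytest.mark.parametrize("scheme", DIMS)
def test_dimension_invariant(scheme, random_windows):
    fv = ENCODE[scheme](random_windows[0])
    assert len(fv.values) == DIMS[scheme] == len(fv.names)
    assert fm.scheme_dim(scheme) == DIMS[scheme]


@pytest.mark.parametrize("scheme", DIMS)
def test_encoder_matches_bruteforce_oracle_on_100_windows(
        scheme, random_windows):
    """Each encoder reproduces an independent sliding-window oracle."""
    for seq in random_windows:
        np.testing.assert_allclose(ENCODE[scheme](seq).values,
                                   ORACLE[scheme](seq), atol=1e-12)


@pytest.mark.parametrize("scheme", DIMS)
def test_encoder_deterministic_and_finite(scheme, random_windows):
    seq = random_windows[3]
    a, b = ENCODE[scheme](seq).values, ENCODE[scheme](seq).values
    assert np.array_equal(a, b)
    assert np.isfinite(a).all()


class TestKmer:
    def test_homopolymer_saturates_own_kmers(self):
        fv = fm.encode_kmer("A" * 41)
        vals = dict(zip(fv.names, fv.values))
        assert vals["AAA"] == 1.0 and vals["AAAA"] == 1.0
        assert fv.values.sum() == pytest.approx(2.0)  # one per k-block

    def test_kblocks_sum_to_one(self, random_windows):
        for seq in random_windows[:20]:
            fv = fm.encode_kmer(seq)
            assert fv.values[:125].sum() == pytest.approx(1.0)
            assert fv.values[125:].sum() == pytest.approx(1.0)
            assert ((fv.values >= 0) & (fv.values <= 1)).all()


class TestKsnc:
    def test_homopolymer_aa_pair_saturates(self):
        fv = fm.encode_ksnc("A" * 41)
        vals = dict(zip(fv.names, fv.values))
        for d in range(4):
            assert vals[f"AA_d{d}"] == 1.0
        assert fv.values.sum() == pytest.approx(4.0)

    def test_denominator_is_valid_positions(self):
        # one CT adjacency in an otherwise A window
        seq = "CT" + "A" * 39
        vals = dict(zip(*[fm.encode_ksnc(seq).names,
                          fm.encode_ksnc(seq).values]))
        assert vals["CT_d0"] == pytest.approx(1 / 40)

    def test_dmax_out_of_range(self):
        with pytest.raises(ValueError):
            fm.encode_ksnc("A" * 20 + "C" + "A" * 20, dmax=40)


class TestMbe:
    def test_channel_order_is_atgcn(self):
        fv = fm.encode_mbe("A" + "T" * 19 + "C" + "T" * 20)
        assert list(fv.values[:5]) == [1, 0, 0, 0, 0]    # A
        assert list(fv.values[5:10]) == [0, 1, 0, 0, 0]  # T
        center = 20 * 5
        assert list(fv.values[center:center + 5]) == [0, 0, 0, 1, 0]  # C

    def test_all_n_window(self):
        fv = fm.encode_mbe("N" * 41)
        assert fv.values.sum() == 41
        assert all(list(fv.values[i * 5:i * 5 + 5]) == [0, 0, 0, 0, 1]
                   for i in range(41))

    def test_one_hot_property(self, random_windows):
        for seq in random_windows[:20]:
            blocks = fm.encode_mbe(seq).values.reshape(41, 5)
            assert (blocks.sum(axis=1) == 1).all()


class TestDbe:
    @pytest.mark.parametrize("pair,code", [
        ("AT", [0, 0, 0, 1]), ("AA", [0, 0, 0, 0]),
        ("GG", [1, 1, 1, 1]), ("AC", [0, 0, 1, 0])])
    def test_printed_codes(self, pair, code):
        seq = pair + "A" * 18 + "C" + "A" * 20
        assert list(fm.encode_dbe(seq).values[:4]) == code

    def test_all_n_is_zero_vector(self):
        assert not fm.encode_dbe("N" * 41).values.any()

    def test_sixteen_codes_bijective(self):
        codes = {}
        for pair in ("".join(p) for p in product("ACGT", repeat=2)):
            seq = pair + "A" * 18 + "C" + "A" * 20
            codes[pair] = tuple(fm.encode_dbe(seq).values[:4])
        assert len(set(codes.values())) == 16
        base = {"A": (0, 0), "T": (0, 1), "C": (1, 0), "G": (1, 1)}
        for pair, code in codes.items():
            assert code == base[pair[0]] + base[pair[1]]


class TestEiip:
    def test_table_values(self):
        fv = fm.encode_eiip("ACGT" + "N" * 16 + "C" + "N" * 20)
        np.testing.assert_allclose(fv.values[:4],
                                   [0.1260, 0.1340, 0.0806, 0.1335])

    def test_all_n_zero(self):
        assert not fm.encode_eiip("N" * 41).values.any()


class TestDpc:
    def test_homopolymer_closed_form(self):
        table = default_property_table()
        fv = fm.encode_dpc("A" * 41, table=table)
        vals = dict(zip(fv.names, fv.values))
        for prop in table.property_names:
            assert vals[f"AA_{prop}"] == pytest.approx(
                table.value("AA", prop))
        others = [v for n, v in vals.items() if not n.startswith("AA_")]
        assert not any(others)

    def test_all_n_zero_vector(self):
        assert not fm.encode_dpc("N" * 41).values.any()

    def test_table_must_have_15_properties(self):
        import pandas as pd
        bad = pd.DataFrame(np.ones((16, 14)),
                           index=["".join(p) for p in
                                  product("ACGT", repeat=2)])
        with pytest.raises(ValueError, match="15"):
            PropertyTable(bad)

    def test_bundled_table_normalized(self):
        table = default_property_table()
        assert table.frame.min().min() == 0.0
        assert table.frame.max().max() == 1.0
        assert ((table.frame >= 0) & (table.frame <= 1)).all().all()


class TestEncodeDataset:
    def make(self, seqs):
        return Dataset([SequenceWindow(f"w{i}", s, "unknown")
                        for i, s in enumerate(seqs)])

    def test_shape_and_rows_match_per_window(self, random_windows):
        ds = self.make(random_windows[:3])
        matrix = fm.encode_dataset(ds, "EIIP")
        assert matrix.values.shape == (3, 41)
        for r, seq in enumerate(random_windows[:3]):
            np.testing.assert_array_equal(matrix.values[r],
                                          fm.encode_eiip(seq).values)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            fm.encode_dataset(Dataset([]), "EIIP")

    def test_error_names_window(self):
        ds = Dataset([SequenceWindow("badwin", "A" * 41, "unknown")])
        ds.windows[0] = SequenceWindow("badwin", "X" * 41, "unknown")
        with pytest.raises(ValueError, match="badwin"):
            fm.encode_dataset(ds, "EIIP")


@st.composite
def windows(draw):
    left = draw(st.text(alphabet="ACGTN", min_size=20, max_size=20))
    right = draw(st.text(alphabet="ACGTN", min_size=20, max_size=20))
    return left + "C" + right


@settings(max_examples=30, derandomize=True, deadline=None)
@given(windows())
def test_value_range_properties(seq):
    """Bounded-value invariants hold for arbitrary valid windows."""
    kmer = fm.encode_kmer(seq).values
    ksnc = fm.encode_ksnc(seq).values
    assert ((kmer >= 0) & (kmer <= 1)).all()
    assert ((ksnc >= 0) & (ksnc <= 1)).all()
    dbe = fm.encode_dbe(seq).values
    assert set(np.unique(dbe)) <= {0.0, 1.0}
    mbe = fm.encode_mbe(seq).values.reshape(-1, 5)
    assert (mbe.sum(axis=1) == 1).all()


def test_sequence_encoder_transformer_matches_functions(random_windows):
    """The sklearn transformer facade equals the plain encoders row-wise."""
    seqs = random_windows[:5]
    for scheme in DIMS:
        enc = fm.SequenceEncoder(scheme=scheme).fit(seqs)
        X = enc.transform(seqs)
        assert X.shape == (5, DIMS[scheme])
        names = enc.get_feature_names_out()
        assert len(names) == DIMS[scheme]
        for r, seq in enumerate(seqs):
            np.testing.assert_array_equal(X[r], ENCODE[scheme](seq).values)
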