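"""Six numeric encodings of fixed-length DNA windows.

Each encoder maps a window over {A, C, G, T, N} to a fixed-length real
vector. For the default 41-bp window the dimensions are:

========  ====  =========================================================
scheme    dim   construction
========  ====  =========================================================
KMER      750   tri- + tetra-nucleotide frequencies over the 5-letter
                alphabet (5**3 + 5**4 k-mers)
KSNC      100   k-spaced nucleotide pair frequencies, spacings d = 0..3,
                25 ordered pairs, each normalized by w - d - 1
MBE       205   per-position one-hot (5 channels per base)
DBE       160   4-bit code per overlapping dinucleotide from a 2-bit
                base code (A=00, T=01, C=10, G=11); N pairs are zero
EIIP      41    electron-ion interaction pseudopotential per base
DPC       375   25 dinucleotide frequencies x 15 physicochemical
                properties
========  ====  =========================================================

Encoders are exposed both as plain functions (``encode_kmer`` ...) and as
stateless scikit-learn transformers operating on arrays of sequence
strings, so they compose with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ALPHABET, DEFAULT_WINDOW, Dataset

#: canonical sort order for k-mers and ordered pairs (lexicographic)
ALPHA5 = "ACGNT"
#: one-hot channel order for the MBE encoding
MBE_CHANNELS = "ATGCN"

SCHEMES = ("KMER", "KSNC", "MBE", "DBE", "EIIP", "DPC")

EIIP_VALUES = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335,
               "N": 0.0000}

#: 2-bit base code behind the dinucleotide binary encoding
DBE_BASE_CODE = {"A": (0, 0), "T": (0, 1), "C": (1, 0), "G": (1, 1)}

_PAIRS25 = ["".join(p) for p in product(ALPHA5, repeat=2)]
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS25)}


def scheme_dim(scheme: str, w: int = DEFAULT_WINDOW) -> int:
    """Feature-vector length of ``scheme`` for window length ``w``."""
    return {
        "KMER": 5 ** 3 + 5 ** 4,
        "KSNC": 4 * 25,
        "MBE": w * 5,
        "DBE": (w - 1) * 4,
        "EIIP": w,
        "DPC": 25 * 15,
    }[scheme]


@dataclass(frozen=True)
class FeatureVector:
    """A named, ordered feature vector for one encoding scheme."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")


@dataclass
class FeatureMatrix:
    """samples x features for one encoding scheme, with optional labels."""

    scheme: str
    ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        n, p = self.values.shape
        if n != len(self.ids) or p != len(self.names):
            raise ValueError("matrix shape inconsistent with ids/names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _seq_of(window) -> str:
    return window.seq if hasattr(window, "seq") else str(window)


# ---------------------------------------------------------------------------
# plain per-window encoders

def kmer_names() -> list[str]:
    return (["".join(m) for m in product(ALPHA5, repeat=3)]
            + ["".join(m) for m in product(ALPHA5, repeat=4)])


def encode_kmer(window) -> FeatureVector:
    """Tri- and tetra-nucleotide frequency vector (750-D for any w >= 4).

    The feature for k-mer m is count(m) / (w - k + 1), the fraction of
    sliding windows of width k equal to m, so each k-block sums to 1.
    """
    seq = _check_seq(_seq_of(window))
    w = len(seq)
    values = np.zeros(5 ** 3 + 5 ** 4)
    offsets = {3: 0, 4: 5 ** 3}
    for k, off in offsets.items():
        denom = w - k + 1
        idx = {"".join(m): i for i, m in enumerate(product(ALPHA5, repeat=k))}
        for p in range(denom):
            values[off + idx[seq[p:p + k]]] += 1.0
        values[off:off + 5 ** k] /= denom
    return FeatureVector("KMER", tuple(kmer_names()), values)


def ksnc_names(dmax: int = 3) -> list[str]:
    return [f"{p}_d{d}" for d in range(dmax + 1) for p in _PAIRS25]


def encode_ksnc(window, dmax: int = 3) -> FeatureVector:
    """k-spaced nucleotide pair composition.

    For spacing d, the feature for ordered pair (x, y) counts positions p
    with seq[p] == x and seq[p + d + 1] == y, normalized by the number of
    valid positions w - d - 1. Spacings 0..dmax, 25 ordered pairs each.
    """
    seq = _check_seq(_seq_of(window))
    w = len(seq)
    if not 0 <= dmax <= w - 2:
        raise ValueError(f"dmax {dmax} out of range [0, {w - 2}]")
    values = np.zeros((dmax + 1) * 25)
    for d in range(dmax + 1):
        denom = w - d - 1
        off = d * 25
        for p in range(denom):
            values[off + _PAIR_INDEX[seq[p] + seq[p + d + 1]]] += 1.0
        values[off:off + 25] /= denom
    return FeatureVector("KSNC", tuple(ksnc_names(dmax)), values)


def mbe_names(w: int = DEFAULT_WINDOW) -> list[str]:
    return [f"pos{p + 1}_{c}" for p in range(w) for c in MBE_CHANNELS]


def encode_mbe(window) -> FeatureVector:
    """Per-position one-hot encoding, channel order A, T, G, C, N."""
    seq = _check_seq(_seq_of(window))
    w = len(seq)
    values = np.zeros(w * 5)
    channel = {c: i for i, c in enumerate(MBE_CHANNELS)}
    for p, base in enumerate(seq):
        values[p * 5 + channel[base]] = 1.0
    return FeatureVector("MBE", tuple(mbe_names(w)), values)


def dbe_names(w: int = DEFAULT_WINDOW) -> list[str]:
    return [f"dinuc{p + 1}_b{b}" for p in range(w - 1) for b in range(4)]


def encode_dbe(window) -> FeatureVector:
    """4-bit binary code per overlapping dinucleotide.

    Each dinucleotide's code concatenates the 2-bit codes of its bases
    (A=00, T=01, C=10, G=11): e.g. AT -> 0001, GG -> 1111, AC -> 0010.
    Any dinucleotide containing N encodes as 0000.
    """
    seq = _check_seq(_seq_of(window))
    w = len(seq)
    values = np.zeros((w - 1) * 4)
    for p in range(w - 1):
        a, b = seq[p], seq[p + 1]
        if a in DBE_BASE_CODE and b in DBE_BASE_CODE:
            values[p * 4: p * 4 + 4] = DBE_BASE_CODE[a] + DBE_BASE_CODE[b]
    return FeatureVector("DBE", tuple(dbe_names(w)), values)


def eiip_names(w: int = DEFAULT_WINDOW) -> list[str]:
    return [f"pos{p + 1}_eiip" for p in range(w)]


def encode_eiip(window) -> FeatureVector:
    """Electron-ion interaction pseudopotential value per position."""
    seq = _check_seq(_seq_of(window))
    values = np.array([EIIP_VALUES[b] for b in seq])
    return FeatureVector("EIIP", tuple(eiip_names(len(seq))), values)


# ---------------------------------------------------------------------------
# DPC and its property table

class PropertyTable:
    """15 physicochemical property values per dinucleotide.

    Holds values for the 16 standard dinucleotides; any N-containing
    pair implicitly carries 0 for every property. When ``normalize`` is
    set (the default for the bundled table), each property is min-max
    scaled to [0, 1] over the 16 standard pairs.
    """

    N_PROPERTIES = 15

    def __init__(self, frame: pd.DataFrame, normalize: bool = True):
        if frame.shape[1] != self.N_PROPERTIES:
            raise ValueError(
                f"property table must have exactly {self.N_PROPERTIES} "
                f"properties, got {frame.shape[1]}")
        std = ["".join(p) for p in product("ACGT", repeat=2)]
        missing = set(std) - set(frame.index)
        if missing:
            raise ValueError(f"missing dinucleotides: {sorted(missing)}")
        frame = frame.loc[std].astype(float)
        if normalize:
            rng = frame.max() - frame.min()
            rng = rng.replace(0.0, 1.0)
            frame = (frame - frame.min()) / rng
        self.frame = frame
        self.normalized = normalize

    @property
    def property_names(self) -> list[str]:
        return list(self.frame.columns)

    def value(self, pair: str, prop: str) -> float:
        """Property value for an ordered pair; 0 for N-containing pairs."""
        if "N" in pair:
            return 0.0
        return float(self.frame.at[pair, prop])

    @classmethod
    def default(cls) -> "PropertyTable":
        """The bundled curated table, min-max normalized."""
        ref = resources.files("fourmc.data") / "dinucleotide_properties.tsv"
        with resources.as_file(ref) as path:
            frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(frame, normalize=True)


_DEFAULT_TABLE: PropertyTable | None = None


def default_property_table() -> PropertyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = PropertyTable.default()
    return _DEFAULT_TABLE


def dpc_names(table: PropertyTable | None = None) -> list[str]:
    table = table or default_property_table()
    return [f"{p}_{prop}" for p in _PAIRS25 for prop in table.property_names]


def encode_dpc(window, table: PropertyTable | None = None) -> FeatureVector:
    """Dinucleotide physicochemical composition.

    Feature (pair, property) = frequency of the ordered pair among the
    w - 1 overlapping dinucleotides, times the property value for the
    pair. 25 pairs (5-letter alphabet) x 15 properties; N-containing
    pairs contribute 0 through their zero property values.
    """
    table = table or default_property_table()
    seq = _check_seq(_seq_of(window))
    w = len(seq)
    freq = np.zeros(25)
    for p in range(w - 1):
        freq[_PAIR_INDEX[seq[p:p + 2]]] += 1.0
    freq /= w - 1
    prop_matrix = np.zeros((25, PropertyTable.N_PROPERTIES))
    for i, pair in enumerate(_PAIRS25):
        if "N" not in pair:
            prop_matrix[i] = table.frame.loc[pair].to_numpy()
    values = (freq[:, None] * prop_matrix).ravel()
    return FeatureVector("DPC", tuple(dpc_names(table)), values)


_ENCODE_FUNCS = {
    "KMER": encode_kmer,
    "KSNC": encode_ksnc,
    "MBE": encode_mbe,
    "DBE": encode_dbe,
    "EIIP": encode_eiip,
    "DPC": encode_dpc,
}


def encode_window(window, scheme: str, **options) -> FeatureVector:
    if scheme not in _ENCODE_FUNCS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return _ENCODE_FUNCS[scheme](window, **options)


def encode_dataset(dataset: Dataset, scheme: str, **options) -> FeatureMatrix:
    """Encode every window of a dataset; rows follow dataset order."""
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    rows, names = [], None
    for window in dataset:
        try:
            fv = encode_window(window, scheme, **options)
        except ValueError as exc:
            raise ValueError(f"window {window.id!r}: {exc}") from exc
        rows.append(fv.values)
        names = fv.names
    labels = dataset.labels
    if (labels == -1).all():
        labels = None
    return FeatureMatrix(scheme, dataset.ids, list(names),
                         np.vstack(rows), labels)


# ---------------------------------------------------------------------------
# sklearn transformer facade

class SequenceEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer: array of sequence strings -> feature matrix.

    Parameters
    ----------
    scheme : str
        One of KMER, KSNC, MBE, DBE, EIIP, DPC.
    dmax : int
        Maximum spacing for the KSNC scheme (ignored otherwise).
    property_table : PropertyTable, optional
        Table for the DPC scheme; defaults to the bundled one.
    """

    def __init__(self, scheme: str = "KMER", dmax: int = 3,
                 property_table: PropertyTable | None = None):
        self.scheme = scheme
        self.dmax = dmax
        self.property_table = property_table

    def _options(self) -> dict:
        if self.scheme == "KSNC":
            return {"dmax": self.dmax}
        if self.scheme == "DPC":
            return {"table": self.property_table}
        return {}

    def fit(self, X, y=None):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.n_features_out_ = len(
            encode_window(_seq_of(np.asarray(X, dtype=object).ravel()[0]),
                          self.scheme, **self._options()).values)
        return self

    def transform(self, X) -> np.ndarray:
        seqs = np.asarray(X, dtype=object).ravel()
        return np.vstack([
            encode_window(_seq_of(s), self.scheme, **self._options()).values
            for s in seqs])

    def get_feature_names_out(self, input_features=None):
        w = DEFAULT_WINDOW
        names = {
            "KMER": kmer_names(),
            "KSNC": ksnc_names(self.dmax),
            "MBE": mbe_names(w),
            "DBE": dbe_names(w),
            "EIIP": eiip_names(w),
            "DPC": dpc_names(self.property_table),
        }[self.scheme]
        return np.asarray(names, dtype=object)
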