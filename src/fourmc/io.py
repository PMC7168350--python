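"""Reading, validating and writing fixed-window DNA sequence data.

The toolkit operates on fixed-length DNA windows (default 41 bp) with a
cytosine at the center position — the candidate N4-methylcytosine site.
This module parses FASTA input into validated :class:`SequenceWindow`
records, pairs them with binary labels, performs the stratified
train/test split, and writes prediction tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

#: default window length; the center base (1-based position 21) must be C
DEFAULT_WINDOW = 41

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"


class ValidationError(ValueError):
    """A sequence record violates the window invariants."""


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length DNA window centered on a candidate 4mC cytosine.

    Parameters
    ----------
    id : str
        Unique record identifier.
    seq : str
        Upper-case sequence over {A, C, G, T, N} of the expected length.
    label : str
        ``"positive"`` (4mC), ``"negative"`` (non-4mC) or ``"unknown"``.
    """

    id: str
    seq: str
    label: str = UNKNOWN

    def validate(self, expected_length: int = DEFAULT_WINDOW,
                 enforce_center_c: bool = True) -> None:
        if len(self.seq) != expected_length:
            raise ValidationError(
                f"record {self.id!r}: length {len(self.seq)} != "
                f"expected {expected_length}")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}")
        if enforce_center_c:
            center = expected_length // 2  # 0-based; 1-based (w+1)/2
            if self.seq[center] != "C":
                raise ValidationError(
                    f"record {self.id!r}: center base {self.seq[center]!r} "
                    f"at 1-based position {center + 1} is not 'C'")
        if self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise ValidationError(
                f"record {self.id!r}: bad label {self.label!r}")


@dataclass
class Dataset:
    """An ordered collection of validated sequence windows."""

    windows: list[SequenceWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [w.id for w in self.windows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def ids(self) -> list[str]:
        return [w.id for w in self.windows]

    @property
    def sequences(self) -> list[str]:
        return [w.seq for w in self.windows]

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: 1 = positive, 0 = negative, -1 = unknown."""
        mapping = {POSITIVE: 1, NEGATIVE: 0, UNKNOWN: -1}
        return np.array([mapping[w.label] for w in self.windows], dtype=int)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {POSITIVE: 0, NEGATIVE: 0, UNKNOWN: 0}
        for w in self.windows:
            counts[w.label] += 1
        return counts

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset([self.windows[i] for i in indices])


def read_fasta(path, expected_length: int = DEFAULT_WINDOW,
               enforce_center_c: bool = True,
               labels: dict[str, str] | None = None,
               lenient: bool = False) -> Dataset:
    """Read and validate a FASTA file of fixed-length windows.

    Sequences are upper-cased on read. Records failing validation raise
    :class:`ValidationError` naming the offending record, unless
    ``lenient`` is set, in which case they are skipped with a warning.

    Parameters
    ----------
    path : path-like
        FASTA file.
    expected_length : int
        Required window length (default 41).
    enforce_center_c : bool
        Require a C at the center position.
    labels : dict, optional
        Mapping id -> label; unlisted records get ``"unknown"``.
    lenient : bool
        Skip invalid records instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    windows: list[SequenceWindow] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        label = (labels or {}).get(record.id, UNKNOWN)
        window = SequenceWindow(record.id, seq, label)
        try:
            window.validate(expected_length, enforce_center_c)
        except ValidationError as exc:
            if lenient:
                warnings.warn(f"skipping invalid record: {exc}")
                logger.warning("skipping invalid record: %s", exc)
                continue
            raise
        windows.append(window)
    if not windows:
        raise ValidationError(f"no valid records in {path}")
    return Dataset(windows)


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV label file (id, 1/0) into an id->label map."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns")
            rid, lab = parts
            if lab not in ("0", "1"):
                raise ValidationError(
                    f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            labels[rid] = POSITIVE if lab == "1" else NEGATIVE
    return labels


def split_train_test(dataset: Dataset, n_test_per_class: int,
                     seed: int = 0) -> tuple[Dataset, Dataset]:
    """Class-stratified split holding out an exact per-class test count.

    Takes an absolute per-class test count rather than a fraction so
    printed counts (e.g. 746/746 train, 160/160 test from a 906+906
    benchmark) are reproduced exactly. Deterministic under ``seed``.
    """
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in (1, 0):
        members = np.flatnonzero(labels == cls)
        if len(members) < n_test_per_class:
            raise ValidationError(
                f"class {cls} has {len(members)} members, "
                f"need >= {n_test_per_class} for the test set")
        chosen = rng.choice(members, size=n_test_per_class, replace=False)
        test_idx.extend(chosen.tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(dataset)) if i not in test_set]
    return dataset.subset(train_idx), dataset.subset(sorted(test_idx))


def write_predictions(results: Sequence[dict], path,
                      schemes: Sequence[str] | None = None) -> None:
    """Write a per-window prediction table as TSV.

    Each result dict carries ``id``, per-scheme scores under
    ``scores`` (dict scheme -> float), ``combined`` and ``call``.
    Scores are printed with 4 decimals; row order is input order.
    """
    if not results:
        raise ValueError("no results to write")
    if schemes is None:
        schemes = list(results[0]["scores"])
    with open(path, "w") as fh:
        header = ["id"] + [f"score_{s}" for s in schemes] + ["combined", "call"]
        fh.write("\t".join(header) + "\n")
        for res in results:
            row = [str(res["id"])]
            row += [f"{res['scores'][s]:.4f}" for s in schemes]
            row.append(f"{res['combined']:.4f}")
            row.append(str(res["call"]))
            fh.write("\t".join(row) + "\n")


def read_predictions(path) -> list[dict]:
    """Parse a prediction TSV written by :func:`write_predictions`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        schemes = [h[len("score_"):] for h in header if h.startswith("score_")]
        results = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rec = dict(zip(header, parts))
            results.append({
                "id": rec["id"],
                "scores": {s: float(rec[f"score_{s}"]) for s in schemes},
                "combined": float(rec["combined"]),
                "call": rec["call"],
            })
    return results
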