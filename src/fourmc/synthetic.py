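"""Synthetic 41-bp window benchmarks with planted class signal.

Real 4mC benchmarks show position-specific compositional bias around
the methylated cytosine: C is over-represented and A under-represented
at particular flanking positions in true 4mC windows. This generator
reproduces that statistical structure in a controllable way: negatives
draw every non-center base i.i.d. from a background distribution;
positives are identical except at a chosen set of informative
positions, where probability mass ``effect`` is moved onto C and off A
(clipped at zero and renormalized). The center base is always C in both
classes, so the signal lives entirely in the flanks.

The default background is uniform over A,C,G,T with no N substitution —
the simplest exchangeable null. Real-genome features the generator does
not emulate: genome-wide base composition, local sequence dependency
(dinucleotide correlation), redundancy between windows, and SMRT
quality filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NEGATIVE, POSITIVE, Dataset, SequenceWindow

BASES = "ACGT"


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic benchmark.

    Parameters
    ----------
    n_pos, n_neg : int
        Class sizes.
    w : int
        Window length (odd; center is forced to C).
    background : sequence of 4 floats
        Per-position probabilities of A, C, G, T for negatives.
    informative_positions : sequence of int
        0-based positions (excluding the center) where positives are
        enriched for C and depleted of A.
    effect : float
        Probability mass moved onto C and off A at each informative
        position in positives.
    n_rate : float
        Per-base probability of replacement by N (never at the center).
    seed : int
        Generator seed; output is deterministic given the spec.
    """

    n_pos: int = 500
    n_neg: int = 500
    w: int = 41
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    informative_positions: tuple = field(default_factory=tuple)
    effect: float = 0.0
    n_rate: float = 0.0
    seed: int = 0

    @property
    def center(self) -> int:
        return self.w // 2

    def validate(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be 4 non-negative "
                             "probabilities summing to 1")
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError("window length must be odd and >= 3")
        if self.center in self.informative_positions:
            raise ValueError("informative positions must exclude the center")
        if any(not 0 <= p < self.w for p in self.informative_positions):
            raise ValueError("informative position out of window")
        if not 0 <= self.effect <= 1:
            raise ValueError("effect must be in [0, 1]")
        if bg[BASES.index("C")] + self.effect > 1 + 1e-9:
            raise ValueError("effect pushes P(C) above 1")
        if not 0 <= self.n_rate < 1:
            raise ValueError("n_rate must be in [0, 1)")


def _positive_distribution(spec: SyntheticSpec) -> np.ndarray:
    """Shifted per-position distribution at informative positions."""
    bg = np.asarray(spec.background, dtype=float)
    shifted = bg.copy()
    shifted[BASES.index("C")] += spec.effect
    shifted[BASES.index("A")] -= spec.effect
    shifted = np.clip(shifted, 0.0, None)
    total = shifted.sum()
    if total <= 0:
        raise ValueError("effect removes all probability mass")
    return shifted / total


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Draw a labeled synthetic dataset per the spec (seed-deterministic)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    pos_dist = _positive_distribution(spec)
    informative = set(spec.informative_positions)

    base_arr = np.array(list(BASES))

    def draw(n: int, positive: bool, prefix: str) -> list[SequenceWindow]:
        idx = np.empty((n, spec.w), dtype=int)
        for p in range(spec.w):
            dist = pos_dist if (positive and p in informative) else bg
            idx[:, p] = rng.choice(4, size=n, p=dist)
        chars = base_arr[idx]
        if spec.n_rate:
            chars[rng.random((n, spec.w)) < spec.n_rate] = "N"
        chars[:, spec.center] = "C"
        return [SequenceWindow(f"{prefix}{i + 1}", "".join(row),
                               POSITIVE if positive else NEGATIVE)
                for i, row in enumerate(chars)]

    return Dataset(draw(spec.n_pos, True, "pos") +
                   draw(spec.n_neg, False, "neg"))


def composition_report(dataset: Dataset) -> dict:
    """Per-position nucleotide frequencies by class + C/A enrichment z.

    Returns ``{"positive": DataFrame, "negative": DataFrame,
    "z_C": array, "z_A": array}`` where each DataFrame is w x 5
    (columns A,C,G,T,N, rows summing to 1) and z_C / z_A are
    per-position two-proportion z statistics for C enrichment and A
    enrichment of positives over negatives (positive z = higher
    frequency in the positive class).
    """
    labels = dataset.labels
    if (labels == -1).any():
        raise ValueError("composition report requires labeled data")
    seqs = np.array([list(w.seq) for w in dataset.windows])
    out = {}
    freqs = {}
    for name, mask in (("positive", labels == 1), ("negative", labels == 0)):
        if mask.sum() == 0:
            raise ValueError(f"no {name} samples")
        sub = seqs[mask]
        table = np.stack([(sub == b).mean(axis=0) for b in "ACGTN"], axis=1)
        freqs[name] = table
        out[name] = pd.DataFrame(table, columns=list("ACGTN"),
                                 index=np.arange(seqs.shape[1]) + 1)
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    for base in "CA":
        j = "ACGTN".index(base)
        p1, p0 = freqs["positive"][:, j], freqs["negative"][:, j]
        pooled = (p1 * n1 + p0 * n0) / (n1 + n0)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(se > 0, (p1 - p0) / se, 0.0)
        out[f"z_{base}"] = z
    return out
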