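import random

import numpy as np
import pytest

import fourmc as fm

ALPHABET = "ACGTN"


def random_window(rng: random.Random, w: int = 41, with_n: bool = True) -> str:
    letters = ALPHABET if with_n else "ACGT"
    chars = [rng.choice(letters) for _ in range(w)]
    chars[w // 2] = "C"
    return "".join(chars)


@pytest.fixture(scope="session")
def random_windows():
    """100 random valid 41-mers (center C, N allowed), fixed seed."""
    rng = random.Random(2024)
    return [random_window(rng) for _ in range(100)]


@pytest.fixture(scope="session")
def small_planted_dataset():
    """Small planted-signal dataset for fast pipeline tests."""
    spec = fm.SyntheticSpec(n_pos=60, n_neg=60, effect=0.35,
                            informative_positions=tuple(range(5, 15)),
                            seed=7)
    return fm.generate_dataset(spec)


@pytest.fixture(scope="session")
def planted_run():
    """Fused model fit on planted-signal data (effect 0.3, 10 positions,
    500 windows per class) — shared across the heavier statistical tests."""
    spec = fm.SyntheticSpec(n_pos=500, n_neg=500, effect=0.3,
                            informative_positions=tuple(range(5, 15)),
                            seed=11)
    ds = fm.generate_dataset(spec)
    model = fm.FusionClassifier(n_estimators=150, seed=11)
    model.fit(ds.sequences, ds.labels)
    return ds, model


@pytest.fixture(scope="session")
def null_run():
    """Fused model fit on exchangeable (effect=0) data, 500 per class."""
    spec = fm.SyntheticSpec(n_pos=500, n_neg=500, effect=0.0, seed=12)
    ds = fm.generate_dataset(spec)
    model = fm.FusionClassifier(n_estimators=150, seed=12)
    model.fit(ds.sequences, ds.labels)
    return ds, model


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
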