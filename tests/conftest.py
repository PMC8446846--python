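import numpy as np
import pytest

import fescom


@pytest.fixture(scope="session")
def protocol_dataset():
    """One full synthetic protocol dataset (315 windows) plus its feature table."""
    spec = fescom.default_protocol_spec(seed=20240)
    windows, spec = fescom.generate_dataset(spec)
    table = fescom.build_feature_table(windows)
    return spec, windows, table


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset (5 classes x 7 subjects x 3 reps) for wrapper-heavy tests."""
    spec = fescom.default_protocol_spec(seed=77)
    from dataclasses import replace

    spec = replace(spec, n_subjects=7)
    windows, spec = fescom.generate_dataset(spec)
    table = fescom.build_feature_table(windows)
    return spec, windows, table


def planted_table(
    n_per_class: int = 20,
    n_classes: int = 3,
    n_informative: int = 2,
    n_noise: int = 3,
    separation: float = 5.0,
    seed: int = 0,
) -> fescom.FeatureTable:
    """A feature table with planted class-separated columns plus pure-noise columns.

    Informative column j has class means ``separation * class_index`` (unit
    within-class SD); noise columns are N(0, 1) regardless of class.
    """
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    labels = [f"c{c}" for c in range(n_classes) for _ in range(n_per_class)]
    cols = []
    names = []
    for j in range(n_informative):
        mu = np.repeat(separation * np.arange(n_classes), n_per_class)
        cols.append(mu + rng.standard_normal(n))
        names.append(f"informative_{j}")
    for j in range(n_noise):
        cols.append(rng.standard_normal(n))
        names.append(f"noise_{j}")
    return fescom.FeatureTable(
        matrix=np.column_stack(cols), names=tuple(names), labels=tuple(labels)
    )


@pytest.fixture
def two_class_table():
    return planted_table(n_per_class=15, n_classes=2, seed=3)
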