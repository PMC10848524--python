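import numpy as np
import pytest

from mlocpred.encoders import FeatureMatrix
from mlocpred.fixtures import (
    ClassProfile,
    benchmark_profiles,
    generate_dataset,
)
from mlocpred.seqio import LOCALES


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_separable_dataset():
    """Separable five-class dataset, small enough for fast pipeline tests."""
    profiles = benchmark_profiles(separable=True)
    return generate_dataset(profiles, {p.label: 20 for p in profiles}, seed=7)


@pytest.fixture(scope="session")
def heterogeneous_dataset():
    """Five classes with distinct GC so normalizer statistics vary by subset."""
    profiles = [
        ClassProfile(label=label, background_gc=0.3 + 0.1 * i)
        for i, label in enumerate(LOCALES)
    ]
    return generate_dataset(profiles, {label: 15 for label in LOCALES}, seed=3)


def make_matrix(values: np.ndarray, prefix: str = "f") -> FeatureMatrix:
    n, p = values.shape
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=[f"{prefix}{j:02d}" for j in range(p)],
        feature_groups=["TEST"] * p,
        values=values,
    )
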