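import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microbiomegsm.profile_io import AbundanceMatrix
from microbiomegsm.synthetic import SynthConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    """12 samples x 4 species; species 0 separates the classes perfectly."""
    rng = np.random.default_rng(7)
    labels = np.array([1] * 6 + [0] * 6)
    values = rng.dirichlet(np.ones(4), size=12)
    values[labels == 1, 0] += 0.5
    values /= values.sum(axis=1, keepdims=True)
    clades = [
        "k__Bacteria|p__P1|c__C1|o__O1|f__F1|g__Alistipes|s__alistipes_shahii",
        "k__Bacteria|p__P1|c__C1|o__O1|f__F1|g__Alistipes|s__alistipes_inops",
        "k__Bacteria|p__P1|c__C1|o__O2|f__F2|g__Bacteroides|s__bacteroides_dorei",
        "k__Bacteria|p__P1|c__C1|o__O2|f__F2|g__Prevotella|s__prevotella_copri",
    ]
    return AbundanceMatrix(
        sample_ids=[f"S{i:02d}" for i in range(12)],
        species_ids=clades,
        values=values,
        labels=labels,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort reused by modeling-level tests."""
    cfg = SynthConfig(n_samples=60, n_positive=30, n_genera=8,
                      species_per_genus=(1, 4), n_informative_groups=2,
                      effect=2.0, seed=11)
    matrix, truth = generate_dataset(cfg)
    return cfg, matrix, truth
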