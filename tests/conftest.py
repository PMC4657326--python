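import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crystprop.aaindex import parse_aaindex1_text
from crystprop.sequences import ProteinRecord
from crystprop.synthetic import (
    NoiseLabels,
    PlantedLogistic,
    SyntheticSpec,
    generate_dataset,
    toy_aaindex,
)


@pytest.fixture(scope="session")
def toy_tables():
    """Ten parsed synthetic AAIndex characteristics."""
    return parse_aaindex1_text(toy_aaindex(10, seed=3))


@pytest.fixture(scope="session")
def small_planted_dataset():
    """301 proteins with labels planted on the distribution encoding."""
    rng = np.random.default_rng(11)
    spec = SyntheticSpec(
        n_proteins=301, length_range=(50, 300),
        label_model=PlantedLogistic(coef=rng.normal(0, 4, 20),
                                    encoding="distribution"),
        seed=2,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def noise_dataset():
    """60 proteins with labels independent of sequence."""
    spec = SyntheticSpec(n_proteins=60, length_range=(40, 120),
                         label_model=NoiseLabels(prevalence=85 / 301), seed=4)
    return generate_dataset(spec)


@pytest.fixture
def simple_record():
    return ProteinRecord("p1", "ACDAC")
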