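import pytest
from hypothesis import settings

settings.register_profile("fast", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("fast")

from acidmap.simulate import ChipModel, ReporterModel, build_database


@pytest.fixture(scope="session")
def reporter():
    return ReporterModel()


@pytest.fixture()
def ideal_chip():
    """Unit-gain chip with no baseline, fingerprint, offset or noise."""
    return ChipModel("ideal", baseline_params=(0.0, 0.0, 0.0), noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_db():
    """A small simulated database (5 chips x 13 pH x 4 reps = 260 spectra)."""
    dataset, chips = build_database(n_chips=5, reps=4, seed=11)
    return dataset, chips
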