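import numpy as np
import pytest

from flimpipe.instrument import InstrumentModel
from flimpipe.synthetic import CohortConfig, generate_cohort, _background_template


@pytest.fixture(scope="session")
def instrument() -> InstrumentModel:
    return InstrumentModel()


@pytest.fixture(scope="session")
def small_cohort(instrument):
    """A 3-patient in vivo cohort with waveforms, small enough for unit tests."""
    cfg = CohortConfig(
        phase="in_vivo",
        n_patients=3,
        n_mixed=2,
        n_healthy_only=1,
        points_per_class=240,
        rng_seed=7,
    )
    return generate_cohort(cfg, instrument)


@pytest.fixture(scope="session")
def background_template(small_cohort, instrument):
    return _background_template(instrument, small_cohort.config)


@pytest.fixture(scope="session")
def truth_cohorts():
    """Ground-truth-only calibrated cohorts (both phases) at screening scale."""
    out = {}
    for phase in ("in_vivo", "ex_vivo"):
        cfg = CohortConfig(phase=phase, points_per_class=20_000, synthesize_waveforms=False, rng_seed=1)
        out[phase] = generate_cohort(cfg).truth
    return out


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
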