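import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capsense.benchmark import BenchmarkConfig, run_benchmark
from capsense.simulate import (CloneProfile, CultureParams, DisturbanceSpec,
                               SamplingSpec, simulate_run)

settings.register_profile(
    "capsense",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("capsense")


NOISELESS = DisturbanceSpec(noise_cv=0.0)
EXACT_SAMPLING = SamplingSpec(offline_noise_cv=0.0)


def clean_clone(**kw) -> CloneProfile:
    """Debris-free clone profile (measurement noise handled separately)."""
    return CloneProfile(debris_amplitude=0.0, **kw)


def short_culture(**kw) -> CultureParams:
    """5-day fed-batch for fast unit tests (peak around 60 h)."""
    defaults = dict(duration=120.0, death_onset=60.0, mu_max=0.06)
    defaults.update(kw)
    return CultureParams(**defaults)


@pytest.fixture(scope="session")
def benchmark_result():
    """Default transfer benchmark, shared by acceptance and invariant tests."""
    return run_benchmark(BenchmarkConfig(), seed=1)


@pytest.fixture()
def noiseless_run():
    """Debris-free, disturbance-free, noise-free short run (exact signals)."""
    return simulate_run(clean_clone(), short_culture(), NOISELESS, EXACT_SAMPLING, seed=3)


@pytest.fixture()
def debris_heavy_run():
    """Full-length debris-heavy run with default noise levels."""
    return simulate_run(CloneProfile(), CultureParams(), DisturbanceSpec(), SamplingSpec(),
                        seed=5)
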