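import numpy as np
import pytest

from parcelmeg import CohortConfig, EffectSpec, NoiseParams, make_parcellation


@pytest.fixture
def parc4():
    """Minimal parcellation: 2 homologue pairs, 4 parcels."""
    return make_parcellation(2)


@pytest.fixture
def parc6():
    return make_parcellation(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_cohort_config(n_als=5, n_control=6, n_pairs=2, duration_s=12.0, **kw):
    """Cohort config scaled for unit tests; accounting fields consistent."""
    return CohortConfig(
        n_als=n_als,
        n_control=n_control,
        n_recruited=n_als + n_control,
        n_excluded_missing_scan=0,
        n_excluded_noisy=0,
        n_pairs=n_pairs,
        duration_range_s=(duration_s, duration_s),
        **kw,
    )


@pytest.fixture
def null_effects():
    return EffectSpec()


@pytest.fixture
def quiet_noise():
    """No between-subject jitter: deterministic effect sizes."""
    return NoiseParams(amp_jitter_sd=0.0, chi_jitter_sd=0.0)
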