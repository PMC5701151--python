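import numpy as np
import pytest

from ebnt import (AnalysisConfig, BandCoupling, CohortConfig, Recording,
                  analyze_cohort, band_by_name, generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sinusoid(freq, fs=250.0, duration=5.0, phase=0.0):
    t = np.arange(0, duration, 1.0 / fs)
    return np.cos(2 * np.pi * freq * t - phase)


@pytest.fixture
def small_cohort_config():
    """A small but fully coupled two-group cohort: alpha coupling halved
    in group 2, gamma coupled identically in both groups."""
    return CohortConfig(
        n_subjects_per_group=4,
        duration=30.0,
        n_channels=16,
        band_coupling={
            "alpha": BandCoupling(0.9, np.pi / 4, 0.2),
            "gamma": BandCoupling(0.9, np.pi / 4, 0.2),
        },
        group_effect={"alpha": 0.5},
        seed=1,
    )


@pytest.fixture(scope="session")
def analyzed_small_cohort():
    """Session-cached small cohort analysis (alpha band only) for tests
    that need realistic per-subject metrics."""
    config = CohortConfig(
        n_subjects_per_group=4,
        duration=30.0,
        n_channels=16,
        band_coupling={"alpha": BandCoupling(0.9, np.pi / 4, 0.2)},
        group_effect={"alpha": 0.5},
        seed=1,
    )
    recordings = generate_cohort(config)
    acfg = AnalysisConfig(bands=(band_by_name("alpha"),), n_surrogates=20)
    metrics, matrices = analyze_cohort(recordings, acfg)
    return config, recordings, metrics, matrices


def random_symmetric_matrix(n, rng, low=0.05, high=1.0):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture
def toy_recording():
    """3-channel hand-set recording for arithmetic oracles."""
    data = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [10.0, 20.0, 30.0, 40.0],
        [5.0, 5.0, 5.0, 5.0],
    ])
    return Recording("toy", data, sample_rate=4.0,
                     channel_labels=["a", "b", "c"])
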