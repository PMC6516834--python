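import numpy as np
import pytest

from ndcfret import (
    CalibrationConstants,
    KineticsConfig,
    PhotophysicsConfig,
    default_schedule,
)


@pytest.fixture
def schedule():
    return default_schedule()


@pytest.fixture
def short_schedule():
    return default_schedule(
        n_fret_frames=25, n_direct_frames=20, n_bleach_frames=30, n_donor_alone_frames=20
    )


@pytest.fixture
def photo():
    """Default (noisy) photophysics — the study conditions."""
    return PhotophysicsConfig()


@pytest.fixture
def clean_photo():
    """Noiseless, bleach-free photophysics for exact oracles."""
    return PhotophysicsConfig(
        shot_noise=False,
        read_noise_sd=0.0,
        background_per_channel=(0.0, 0.0, 0.0),
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
    )


@pytest.fixture
def paper_kinetics():
    return KineticsConfig(k_closing=0.23, k_opening=0.96)


@pytest.fixture
def true_constants():
    return CalibrationConstants(S=0.13, S_sd=0.0, n_S=1, X=0.37, X_sd=0.0, n_X=1)


def markov_occupancy_se(p: float, n_frames: int, rate_sum: float, frame_interval: float) -> float:
    """Standard error of the time-average occupancy of a two-state Markov
    chain sampled at ``n_frames`` frames: the binomial SE inflated by the
    integrated autocorrelation of the chain (frames are not independent)."""
    rho = np.exp(-rate_sum * frame_interval)
    k = np.arange(1, min(n_frames, 2000))
    kappa = 1.0 + 2.0 * np.sum((1 - k / n_frames) * rho**k)
    return float(np.sqrt(p * (1 - p) * kappa / n_frames))
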