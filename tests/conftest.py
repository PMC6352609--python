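import numpy as np
import pytest

from mibci.preprocess import bandpass, extract_epochs
from mibci.synthgen import SimConfig, SubjectProfile, generate_session

#: Reduced motor-strip montage used by simulation-heavy statistical tests;
#: protocol-count tests use the full default 32-channel montage instead.
REDUCED_CHANNELS = ["FC3", "C5", "C3", "C1", "Cz", "CP3", "CP1", "C4", "EMG"]


def make_profile(
    depth_mu: float,
    depth_beta: float | None = None,
    rebound: float = 0.3,
    freq_manual: int = 3,
) -> SubjectProfile:
    """A subject profile with fixed covariates and chosen ERD parameters."""
    return SubjectProfile(
        erd_mu_depth=depth_mu,
        erd_beta_depth=depth_mu * 0.8 if depth_beta is None else depth_beta,
        rebound_gain=rebound,
        miq_answers=[4] * 14,
        age=25.0,
        gender="M",
        education_years=3.0,
        freq_manual=freq_manual,
        freq_sport=3,
        freq_music=3,
        freq_craft=3,
        freq_gaming=3,
    )


def reduced_config(**kwargs) -> SimConfig:
    """Small, fast simulation config for statistical property tests."""
    defaults = dict(
        n_subjects=1,
        n_trials=16,
        fs=128.0,
        channel_labels=list(REDUCED_CHANNELS),
        seed=0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def session_accuracy(depth: float, seed: int, method: str = "tslr", **cfg_kwargs) -> float:
    """Simulate one reduced-montage subject and return mean CV accuracy."""
    from mibci.classify import crossval_accuracy

    cfg = reduced_config(**cfg_kwargs)
    sess = generate_session(make_profile(depth), cfg, np.random.default_rng(seed))
    epochs = extract_epochs(bandpass(sess))
    _, mean, _, _ = crossval_accuracy(epochs, method, seed=seed)
    return mean


def random_spd(rng: np.random.Generator, c: int, scale: float = 1.0) -> np.ndarray:
    a = rng.standard_normal((c, 2 * c))
    return scale * (a @ a.T) / (2 * c)


@pytest.fixture(scope="session")
def full_session():
    """One full-scale (32 ch, 40 trials, 256 Hz) simulated session."""
    cfg = SimConfig()
    rng = np.random.default_rng(12345)
    return generate_session(make_profile(0.6), cfg, rng), cfg


@pytest.fixture(scope="session")
def full_epochs(full_session):
    session, _ = full_session
    return extract_epochs(bandpass(session))
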