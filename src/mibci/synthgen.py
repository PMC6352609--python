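"""Synthetic motor-imagery BCI cohorts with known ground truth.

The simulator emulates a single-session right-hand kinesthetic motor
imagery (KMI) protocol: each trial shows 6 s of rest (RED cue), a 2 s
warning (ORANGE), 4 s of imagery (GREEN), then a jittered inter-trial
interval of ~2 s. During the GREEN interval the mu (default 10 Hz) and
beta (default 20 Hz) rhythms over the contralateral motor cortex are
attenuated by a subject-specific event-related desynchronization (ERD)
depth; after imagery offset the beta rhythm briefly rebounds
(event-related synchronization). Signals are the sum of

* per-channel 1/f background noise plus a shared common-mode component
  (20 % amplitude) so spatial covariances are full-rank but correlated,
* coherent narrow-band mu and beta oscillator sources whose per-channel
  amplitude and ERD modulation follow a fixed Gaussian spatial gain map
  centred on C3,
* a near-silent white-noise EMG channel mirroring the movement-control
  electrode of the acquisition setup.

Questionnaire answers and personal factors are drawn through a Gaussian
copula whose latent variable can be correlated with the subject's ERD
depth, so both a null scenario (imagery questionnaire unrelated to
decodability) and a positive scenario (e.g. manual-activity frequency
predicts performance) can be generated on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .containers import EEGSession, SubjectRecord
from .errors import ValidationError
from .montage import DEFAULT_CHANNELS, EMG_CHANNEL, load_spatial_gains

logger = logging.getLogger(__name__)

#: Factor names the covariate copula knows about. ``miq_kinesthetic`` /
#: ``miq_visual`` control the latent correlation of the questionnaire
#: item blocks with ERD depth (default 0: the null scenario).
FACTOR_NAMES = (
    "age",
    "gender",
    "education_years",
    "freq_manual",
    "freq_sport",
    "freq_music",
    "freq_craft",
    "freq_gaming",
    "miq_kinesthetic",
    "miq_visual",
)

# Cohort demographics used for the marginals of age / education / gender.
_AGE_MEAN, _AGE_SD = 25.83, 10.42
_EDU_MEAN, _EDU_SD = 3.29, 3.06
_P_FEMALE = 13 / 35

# Likert marginals for questionnaire items (kinesthetic items rate lower
# on average than visual ones), expressed as mean/sd of the rounded
# latent; chosen to give cohort mean scores in the high-60s / low-80s.
_MIQ_K_MEAN, _MIQ_K_SD = 5.05, 1.3
_MIQ_V_MEAN, _MIQ_V_SD = 5.9, 1.1

# Latent coupling between a subject's mu and beta ERD depths: a single
# "imagery ability" latent drives both, with some independent variation.
_MU_BETA_LATENT_CORR = 0.8


def sample_from_dist(dist: dict[str, Any], u: np.ndarray | float):
    """Inverse-CDF transform of uniform draws ``u`` under a distribution spec.

    ``dist`` is ``{"kind": "beta", "a": .., "b": ..}``,
    ``{"kind": "uniform", "lo": .., "hi": ..}`` or
    ``{"kind": "fixed", "value": ..}``.
    """
    kind = dist.get("kind")
    if kind == "beta":
        return spst.beta.ppf(u, dist["a"], dist["b"])
    if kind == "uniform":
        lo, hi = dist["lo"], dist["hi"]
        return lo + (hi - lo) * np.asarray(u)
    if kind == "fixed":
        return np.full_like(np.asarray(u, dtype=float), dist["value"]) if np.ndim(u) else dist["value"]
    raise ValidationError(f"unknown distribution kind {kind!r}")


@dataclass
class SimConfig:
    """Simulation parameters; defaults reproduce the study protocol."""

    n_subjects: int = 35
    n_trials: int = 40
    fs: float = 256.0
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    t_rest: float = 6.0
    t_warn: float = 2.0
    t_kmi: float = 4.0
    iti_jitter: tuple[float, float] = (1.5, 2.5)
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    erd_depth_dist: dict = field(default_factory=lambda: {"kind": "beta", "a": 2.0, "b": 2.0})
    rebound_gain_dist: dict = field(default_factory=lambda: {"kind": "beta", "a": 2.0, "b": 4.0})
    noise_scale: float = 10.0      # broadband background RMS, µV
    mu_amp: float = 3.0            # mu source RMS at full spatial gain, µV
    beta_amp: float = 2.0          # beta source RMS at full spatial gain, µV
    envelope_jitter: float = 0.10  # trial-to-trial multiplicative SD of ERD depth
    rebound_duration: float = 1.0  # s of beta rebound after imagery offset
    covariate_corr: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 4:
            raise ValidationError("n_trials must be >= 4 for 4-fold cross-validation")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        top = max(self.mu_freq, self.beta_freq)
        if self.fs <= 2 * top:
            raise ValidationError(
                f"fs = {self.fs} must exceed twice the highest simulated frequency ({top} Hz)"
            )
        lo, hi = self.iti_jitter
        if lo > hi:
            raise ValidationError("iti_jitter lower bound exceeds upper bound")
        for name, c in self.covariate_corr.items():
            if name not in FACTOR_NAMES:
                raise ValidationError(
                    f"unknown covariate {name!r}; known factors: {list(FACTOR_NAMES)}"
                )
            if not -1.0 <= c <= 1.0:
                raise ValidationError(f"covariate correlation for {name!r} = {c} outside [-1, 1]")
        if EMG_CHANNEL not in self.channel_labels:
            raise ValidationError("channel_labels must include the EMG channel")

    @property
    def trial_period(self) -> float:
        """Nominal seconds per trial at the midpoint of the ITI jitter."""
        return self.t_rest + self.t_warn + self.t_kmi + sum(self.iti_jitter) / 2

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "iti_jitter" in raw:
            raw["iti_jitter"] = tuple(raw["iti_jitter"])
        return cls(**raw)


@dataclass
class SubjectProfile:
    """Ground-truth generative parameters of one simulated subject."""

    erd_mu_depth: float
    erd_beta_depth: float
    rebound_gain: float
    miq_answers: list[int]
    age: float
    gender: str
    education_years: float
    freq_manual: int
    freq_sport: int
    freq_music: int
    freq_craft: int
    freq_gaming: int

    def __post_init__(self):
        for name in ("erd_mu_depth", "erd_beta_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.rebound_gain < 0:
            raise ValidationError("rebound_gain must be >= 0")


def _discretize_likert(latent: np.ndarray, n_levels: int, lowest: int = 0) -> np.ndarray:
    """Map standard-normal latents to equal-probability ordinal levels."""
    u = spst.norm.cdf(latent)
    return np.minimum((u * n_levels).astype(int), n_levels - 1) + lowest


def _miq_item(latent: float, mean: float, sd: float) -> int:
    return int(np.clip(round(mean + sd * latent), 1, 7))


def generate_profile(config: SimConfig, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject: ERD parameters plus copula-linked covariates.

    A single standard-normal "imagery ability" latent ``z`` determines the
    mu ERD depth (via the inverse CDF of ``erd_depth_dist``); the beta
    depth shares that latent with correlation 0.8. Every covariate with a
    declared correlation ``c`` gets its own latent ``c·z + sqrt(1-c²)·ε``
    before discretization to its Likert/ordinal range, so covariates with
    no declared correlation are exactly independent of ERD depth.
    """
    z = rng.standard_normal()
    erd_mu = float(sample_from_dist(config.erd_depth_dist, spst.norm.cdf(z)))
    zb = _MU_BETA_LATENT_CORR * z + np.sqrt(1 - _MU_BETA_LATENT_CORR**2) * rng.standard_normal()
    erd_beta = float(sample_from_dist(config.erd_depth_dist, spst.norm.cdf(zb)))
    rebound = float(sample_from_dist(config.rebound_gain_dist, rng.uniform()))

    def latent_for(name: str) -> float:
        c = float(config.covariate_corr.get(name, 0.0))
        return c * z + np.sqrt(1 - c * c) * rng.standard_normal()

    answers = [_miq_item(latent_for("miq_kinesthetic"), _MIQ_K_MEAN, _MIQ_K_SD) for _ in range(7)]
    answers += [_miq_item(latent_for("miq_visual"), _MIQ_V_MEAN, _MIQ_V_SD) for _ in range(7)]

    age = float(np.clip(_AGE_MEAN + _AGE_SD * latent_for("age"), 18, 65))
    gender = "F" if spst.norm.cdf(latent_for("gender")) < _P_FEMALE else "M"
    edu = float(np.clip(_EDU_MEAN + _EDU_SD * latent_for("education_years"), 0, 12))
    freqs = {
        name: int(_discretize_likert(np.array([latent_for(name)]), 6)[0])
        for name in ("freq_manual", "freq_sport", "freq_music", "freq_craft", "freq_gaming")
    }
    return SubjectProfile(
        erd_mu_depth=erd_mu,
        erd_beta_depth=erd_beta,
        rebound_gain=rebound,
        miq_answers=answers,
        age=age,
        gender=gender,
        education_years=edu,
        **freqs,
    )


def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f power spectrum (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _narrowband_source(n: int, fs: float, freq: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise centred on ``freq`` (±1.5 Hz)."""
    sos = sps.butter(4, [freq - 1.5, freq + 1.5], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _smooth_steps(track: np.ndarray, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    """Soften step transitions with a short Hann-window moving average."""
    w = int(round(ramp_s * fs))
    if w < 3:
        return track
    win = np.hanning(w)
    win /= win.sum()
    return np.convolve(track, win, mode="same")


def build_events(config: SimConfig, rng: np.random.Generator, lead_in: float = 2.0):
    """Event table for one session: per trial RED, ORANGE, GREEN in order."""
    events = []
    t = lead_in
    for _ in range(config.n_trials):
        events.append((round(t, 6), "RED"))
        events.append((round(t + config.t_rest, 6), "ORANGE"))
        events.append((round(t + config.t_rest + config.t_warn, 6), "GREEN"))
        iti = rng.uniform(*config.iti_jitter)
        t += config.t_rest + config.t_warn + config.t_kmi + iti
    return events, t


def generate_session(
    profile: SubjectProfile,
    config: SimConfig,
    rng: np.random.Generator,
    return_parts: bool = False,
):
    """Simulate one EEG session for a subject.

    With ``return_parts=True`` additionally returns the noiseless
    per-channel oscillator tracks (``{"mu": .., "beta": ..}``, channels x
    samples) so tests can verify band-power attenuation against the
    generative components directly.
    """
    fs = config.fs
    events, t_end = build_events(config, rng)
    n = int(np.ceil((t_end + 3.0) * fs))
    tgrid = np.arange(n) / fs

    greens = np.array([o for o, c in events if c == "GREEN"])
    # Per-trial jittered ERD depths (clipped to the physical range).
    jit = np.clip(rng.normal(1.0, config.envelope_jitter, size=len(greens)), 0.0, 2.0)
    d_mu = np.clip(profile.erd_mu_depth * jit, 0.0, 1.0)
    d_beta = np.clip(profile.erd_beta_depth * jit, 0.0, 1.0)

    # Modulation tracks in [0,1]: 0 outside imagery, per-trial depth inside.
    mu_mod = np.zeros(n)
    beta_mod = np.zeros(n)
    rebound_mod = np.zeros(n)
    for g, dm, db in zip(greens, d_mu, d_beta):
        a, b = int(g * fs), int((g + config.t_kmi) * fs)
        mu_mod[a:b] = dm
        beta_mod[a:b] = db
        rb = int((g + config.t_kmi + config.rebound_duration) * fs)
        rebound_mod[b:rb] = profile.rebound_gain
    mu_mod = _smooth_steps(mu_mod, fs)
    beta_mod = _smooth_steps(beta_mod, fs)
    rebound_mod = _smooth_steps(rebound_mod, fs)

    mu_src = _narrowband_source(n, fs, config.mu_freq, rng)
    beta_src = _narrowband_source(n, fs, config.beta_freq, rng)
    common = _one_over_f_noise(n, fs, rng)

    gains = load_spatial_gains()
    labels = list(config.channel_labels)
    signal = np.empty((len(labels), n))
    mu_parts = np.zeros_like(signal)
    beta_parts = np.zeros_like(signal)
    for i, ch in enumerate(labels):
        if ch == EMG_CHANNEL:
            signal[i] = 0.05 * config.noise_scale * rng.standard_normal(n)
            continue
        w = gains.get(ch, 0.0)
        g_osc = 0.3 + 0.7 * w  # oscillators present everywhere, strongest near C3
        mu_parts[i] = config.mu_amp * g_osc * (1.0 - w * mu_mod) * mu_src
        beta_parts[i] = (
            config.beta_amp * g_osc * (1.0 - w * beta_mod) * (1.0 + w * rebound_mod) * beta_src
        )
        bg = _one_over_f_noise(n, fs, rng)
        signal[i] = (
            config.noise_scale * bg
            + 0.2 * config.noise_scale * common
            + mu_parts[i]
            + beta_parts[i]
        )

    session = EEGSession(signal=signal, fs=fs, channel_labels=labels, events=events)
    if return_parts:
        return session, {"mu": mu_parts, "beta": beta_parts, "times": tgrid}
    return session


@dataclass
class Cohort:
    """A simulated cohort: sessions, subject records, and hidden ground truth.

    ``ground_truth`` (one dict per subject: ERD depths, rebound gain) is
    kept separate from the records so analysis stages can never read it;
    it exists for tests and calibration studies only.
    """

    sessions: list[EEGSession]
    records: list[SubjectRecord]
    ground_truth: list[dict]

    def __iter__(self):
        return iter(zip(self.sessions, self.records))


def profile_to_record(profile: SubjectProfile, subject_id: str) -> SubjectRecord:
    return SubjectRecord(
        subject_id=subject_id,
        miq_answers=list(profile.miq_answers),
        age=profile.age,
        gender=profile.gender,
        education_years=profile.education_years,
        freq_manual=profile.freq_manual,
        freq_sport=profile.freq_sport,
        freq_music=profile.freq_music,
        freq_craft=profile.freq_craft,
        freq_gaming=profile.freq_gaming,
    )


def generate_profiles(config: SimConfig, rng=None) -> list[SubjectProfile]:
    """Draw the cohort's subject profiles only (no EEG synthesis)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [generate_profile(config, rng) for _ in range(config.n_subjects)]


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full cohort, deterministic given ``config.seed``."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    sessions, records, truth = [], [], []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        profile = generate_profile(config, rng)
        session = generate_session(profile, config, rng)
        sid = f"S{i + 1:02d}"
        sessions.append(session)
        records.append(profile_to_record(profile, sid))
        truth.append(
            {
                "subject_id": sid,
                "erd_mu_depth": profile.erd_mu_depth,
                "erd_beta_depth": profile.erd_beta_depth,
                "rebound_gain": profile.rebound_gain,
            }
        )
    return Cohort(sessions=sessions, records=records, ground_truth=truth)


def surrogate_accuracies(
    profiles: list[SubjectProfile],
    rng: np.random.Generator,
    slope: float = 0.4,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Cheap stand-in for per-subject decoding accuracy in cohort-level studies.

    Maps ground-truth mu-ERD depth monotonically to an accuracy in
    [0.5, 0.9] plus measurement noise, emulating the (separately
    verified) monotone relation between simulated ERD depth and
    cross-validated classifier accuracy. Intended for statistical
    calibration experiments that need hundreds of cohorts, where running
    the full EEG classification chain per subject would add nothing to
    the quantity under test.
    """
    d = np.array([p.erd_mu_depth for p in profiles])
    acc = 0.5 + slope * d + rng.normal(0.0, noise_sd, size=len(d))
    return np.clip(acc, 0.0, 1.0)
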