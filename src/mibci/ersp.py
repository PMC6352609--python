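"""Event-related spectral perturbation (ERSP) maps and group comparison.

An ERSP map is the trial-averaged time-frequency power around the
imagery onset expressed in dB relative to a pre-trial baseline:

    ERSP(f, t) = 10 * log10( P(f, t) / P_baseline(f) ) ,

with power from a sliding 256-point Hanning-windowed FFT (hop 32
samples) and the baseline taken as the mean power over the 2-s window
ending 2 s before the imagery (GREEN) cue — i.e. inside the preceding
rest period. Maps are restricted to the 8-30 Hz analysis band; the time
axis spans -1000 .. +4000 ms around imagery onset by default. Being a
power *ratio*, the map is invariant to global signal rescaling.

Group differences are assessed cell-wise with a subject-level
permutation test (two-sided) and Benjamini-Hochberg FDR across the full
time-frequency grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EEGSession
from .errors import ValidationError
from .stats import bh_adjust

logger = logging.getLogger(__name__)

NFFT = 256
HOP = 32
FREQ_BAND = (8.0, 30.0)
BASELINE_OFFSET_S = 2.0  # baseline window ends this long before imagery onset
BASELINE_LENGTH_S = 2.0


@dataclass
class ERSPMap:
    """dB power change vs baseline for one channel.

    ``values`` has shape (n_freqs, n_times); ``times_ms`` is relative to
    the imagery (GREEN) onset.
    """

    values: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    channel: str

    def __post_init__(self):
        if self.values.shape != (len(self.freqs), len(self.times_ms)):
            raise ValidationError("ERSP values shape does not match axes")


def _sliding_power(x: np.ndarray, fs: float, freq_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed sliding-FFT power of a 1-D signal.

    Returns (power[f, frame], frame_centers_in_samples).
    """
    win = np.hanning(NFFT)
    n_frames = (len(x) - NFFT) // HOP + 1
    if n_frames < 1:
        raise ValidationError("segment shorter than one FFT window")
    starts = np.arange(n_frames) * HOP
    frames = np.lib.stride_tricks.sliding_window_view(x, NFFT)[starts]
    spec = np.fft.rfft(frames * win, axis=1)
    power = (np.abs(spec) ** 2).T[freq_mask]
    centers = starts + NFFT // 2
    return power, centers


def compute_ersp(
    session: EEGSession,
    channel: str,
    t_range: tuple[float, float] = (-1.0, 4.0),
) -> ERSPMap:
    """Trial-averaged ERSP map of one channel around the imagery cue.

    Trials whose analysis or baseline window falls outside the recording
    are dropped (with a logged warning); an error is raised if none
    remain.
    """
    fs = session.fs
    ch = session.channel_index(channel)
    x = session.signal[ch]
    freqs_all = np.fft.rfftfreq(NFFT, d=1.0 / fs)
    fmask = (freqs_all >= FREQ_BAND[0]) & (freqs_all <= FREQ_BAND[1])
    freqs = freqs_all[fmask]

    t0, t1 = t_range
    greens = session.event_onsets("GREEN")
    if len(greens) == 0:
        raise ValidationError("session has no GREEN events")

    half = NFFT / 2 / fs
    powers, base_powers, dropped = [], [], 0
    for g in greens:
        seg_a = int(round((g + t0 - half) * fs))
        seg_b = int(round((g + t1 + half) * fs))
        base_a = int(round((g - BASELINE_OFFSET_S - BASELINE_LENGTH_S) * fs))
        base_b = int(round((g - BASELINE_OFFSET_S) * fs))
        if seg_a < 0 or seg_b > session.n_samples or base_a < 0:
            dropped += 1
            continue
        p, centers = _sliding_power(x[seg_a:seg_b], fs, fmask)
        t_ms = ((seg_a + centers) / fs - g) * 1000.0
        keep = (t_ms >= t0 * 1000.0 - 1e-6) & (t_ms <= t1 * 1000.0 + 1e-6)
        powers.append(p[:, keep])
        times_ms = t_ms[keep]
        bp, _ = _sliding_power(x[base_a:base_b], fs, fmask)
        base_powers.append(bp.mean(axis=1))
    if dropped:
        logger.warning("ERSP: dropped %d trial(s) with out-of-range windows", dropped)
    if not powers:
        raise ValidationError("ERSP: no usable trials")

    n_t = min(p.shape[1] for p in powers)
    mean_power = np.mean([p[:, :n_t] for p in powers], axis=0)
    baseline = np.mean(base_powers, axis=0)
    values = 10.0 * np.log10(mean_power / baseline[:, None])
    return ERSPMap(values=values, freqs=freqs, times_ms=times_ms[:n_t], channel=channel)


def group_compare_ersp(
    maps_group1: list[ERSPMap],
    maps_group2: list[ERSPMap],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Cell-wise permutation test of the between-group mean ERSP difference.

    Subject labels are permuted ``n_perm`` times; two-sided p-values per
    (frequency, time) cell use the add-one permutation estimator and are
    FDR-corrected (Benjamini-Hochberg) at ``alpha`` over the whole grid.

    Returns ``(mask, diff, p_values)``: boolean significance mask, the
    observed group-1 minus group-2 difference map, and the p-value grid.
    """
    if len(maps_group1) < 2 or len(maps_group2) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    a = np.stack([m.values for m in maps_group1])
    b = np.stack([m.values for m in maps_group2])
    if a.shape[1:] != b.shape[1:]:
        raise ValidationError("ERSP maps of the two groups have different grids")
    n1 = len(a)
    pooled = np.concatenate([a, b], axis=0)
    # canonical subject order: the permutation null (and hence the mask)
    # is exactly invariant under swapping the two groups when sizes match
    pooled = pooled[np.argsort([m.tobytes() for m in pooled], kind="stable")]
    obs = a.mean(axis=0) - b.mean(axis=0)

    rng = np.random.default_rng(seed)
    count = np.zeros(obs.shape)
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))
        d = pooled[idx[:n1]].mean(axis=0) - pooled[idx[n1:]].mean(axis=0)
        count += np.abs(d) >= np.abs(obs)
    pvals = (count + 1.0) / (n_perm + 1.0)
    rejected, _ = bh_adjust(pvals.ravel(), q=alpha)
    mask = rejected.reshape(obs.shape)
    return mask, obs, pvals
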