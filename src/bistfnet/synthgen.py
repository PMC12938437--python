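"""Synthetic paired EEG-fNIRS session generator.

The generator produces recordings with a *known* class structure and a
*known* neurovascular lag, so that every downstream stage (preprocessing,
alignment, fusion, training) can be tested without access to real data.

Generative model
----------------
* Trials follow a cue / task / jittered-rest structure (defaults: 2 s cue,
  10 s task, 15-17 s rest).
* During each task period a class-specific subset of EEG channels carries
  band-limited (8-30 Hz) oscillatory activity gated by a smooth task
  envelope; everything is embedded in white noise at a configurable SNR.
* The oscillation envelope of the active channels, downsampled to the fNIRS
  rate and convolved with a canonical double-gamma hemodynamic response
  function (HRF), drives HbO on spatially corresponding fNIRS channels.
  The HRF kernel is applied peak-aligned (the convolution output is shifted
  back by the kernel's own peak latency), so ``lag_s`` is the *net*
  envelope-to-HbO peak latency — the quantity a cross-correlation estimator
  recovers.
* HbR is the anti-correlated mirror of HbO (coupling -0.4) plus independent
  noise; slow sinusoidal drift is added to both chromophores.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

__all__ = [
    "Montage",
    "SimulationConfig",
    "RecordingPair",
    "make_montage",
    "canonical_hrf",
    "hrf_kernel",
    "simulate_session",
    "estimate_lag",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """2-D sensor layout on the unit disk."""

    names: tuple
    xy: np.ndarray  # (n, 2) in [-1, 1]
    modality: str  # "EEG" | "fNIRS"

    def __post_init__(self):
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        if len(self.names) != len(xy):
            raise ValueError("names and coordinates differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if np.any(np.hypot(xy[:, 0], xy[:, 1]) > 1.0 + 1e-9):
            raise ValueError("all coordinates must lie inside the unit disk")
        if len(xy) < 3:
            raise ValueError("at least 3 channels required (interpolation impossible)")
        # non-collinearity: rank of centered coordinates must be 2
        c = xy - xy.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-9) < 2:
            raise ValueError("channel positions are collinear")

    def __len__(self):
        return len(self.names)


@dataclass
class SimulationConfig:
    n_trials_per_class: int = 10
    class_labels: tuple = (0, 1)
    fs_eeg: float = 200.0
    fs_fnirs: float = 10.0
    lag_s: float = 5.0
    snr_db: float = 20.0
    cue_s: float = 2.0
    task_s: float = 10.0
    rest_s_range: tuple = (15.0, 17.0)
    seed: int = 0
    osc_band: tuple = (8.0, 30.0)
    # infra-slow waxing/waning of task band power (depth, Hz range); this is
    # what makes the hemodynamic lag identifiable at the single-window scale,
    # since only sub-0.1 Hz envelope structure survives the HRF low-pass
    slow_mod_depth: float = 0.5
    slow_mod_band: tuple = (0.05, 0.12)

    def __post_init__(self):
        if self.fs_eeg <= 2 * self.osc_band[1]:
            raise ValueError("fs_eeg must exceed twice the highest simulated frequency")
        if self.lag_s < 0:
            raise ValueError("lag_s must be non-negative")
        lo, hi = self.rest_s_range
        if hi < lo:
            raise ValueError("rest_s_range must be a non-degenerate or point interval")


@dataclass
class RecordingPair:
    """Synchronized raw EEG + fNIRS recording with events and montages."""

    eeg: np.ndarray        # (n_eeg, n_samples) in µV
    fs_eeg: float
    fnirs_hbo: np.ndarray  # (n_fnirs, n_samples') molar concentration change
    fnirs_hbr: np.ndarray
    fs_fnirs: float
    events: list           # [(onset_s, class_label), ...]
    montage_eeg: Montage
    montage_fnirs: Montage

    def validate(self) -> None:
        if self.fnirs_hbo.shape != self.fnirs_hbr.shape:
            raise ValueError("HbO and HbR matrices must share shape")
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        dur = self.fnirs_hbo.shape[1] / self.fs_fnirs
        for t, _ in self.events:
            if t - 5.0 < 0 or t + 22.0 > dur:
                raise ValueError(f"event at {t} s: fNIRS window (-5, +22) s leaves the recording")

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.fs_eeg


# ---------------------------------------------------------------------------
# montage construction
# ---------------------------------------------------------------------------

def make_montage(n_eeg: int, n_fnirs: int, seed: int = 0) -> tuple:
    """Quasi-uniform sensor layouts on the unit disk for both modalities.

    Uses a sunflower (golden-angle) spiral with a small seeded jitter, which
    covers the disk quasi-uniformly and is never collinear for n >= 3.
    """
    if n_eeg < 3 or n_fnirs < 3:
        raise ValueError("need at least 3 channels per modality")
    rng = np.random.default_rng(seed)

    def disk_points(n: int, prefix: str) -> Montage:
        k = np.arange(1, n + 1)
        golden = math.pi * (3.0 - math.sqrt(5.0))
        r = 0.9 * np.sqrt((k - 0.5) / n)
        th = k * golden + rng.uniform(-0.05, 0.05, size=n)
        xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
        names = tuple(f"{prefix}{i:02d}" for i in range(n))
        return Montage(names, xy, "EEG" if prefix == "E" else "fNIRS")

    return disk_points(n_eeg, "E"), disk_points(n_fnirs, "F")


# ---------------------------------------------------------------------------
# hemodynamic response function
# ---------------------------------------------------------------------------

def canonical_hrf(t, peak_shape: float = 6.0, undershoot_shape: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0):
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Difference of two gamma densities (unit scale): the positive lobe peaks
    at ``peak_shape - 1`` = 5 s and the undershoot at 15 s by default.
    h(0) = 0 and h decays toward 0 for large t.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_shape) - undershoot_ratio * gamma_dist.pdf(t, undershoot_shape)
    return h if h.ndim else float(h)


def hrf_kernel(fs: float, duration_s: float = 30.0, **kwargs) -> np.ndarray:
    """Discretized HRF kernel, normalized so the positive lobe sums to 1."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    h = canonical_hrf(t, **kwargs)
    pos = h[h > 0].sum()
    return h / pos


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

_PRE_ROLL_S = 10.0
_POST_ROLL_S = 30.0


def _band_noise(rng, n, fs, band):
    """Gaussian noise band-limited to `band` (Hz), unit RMS."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / (y.std() + 1e-12)


def _task_gate(t, onset, dur, ramp=0.25):
    """Smooth 0->1->0 gate with raised-cosine edges."""
    g = np.zeros_like(t)
    rise = (t >= onset) & (t < onset + ramp)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / ramp))
    g[(t >= onset + ramp) & (t < onset + dur - ramp)] = 1.0
    fall = (t >= onset + dur - ramp) & (t < onset + dur)
    g[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (onset + dur - ramp)) / ramp))
    return g


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k samples (left for negative k), zero-filled."""
    out = np.zeros_like(x)
    if k >= 0:
        if k < len(x):
            out[k:] = x[:len(x) - k]
    else:
        out[:k] = x[-k:]
    return out


def class_channel_assignment(config: SimulationConfig, montage_eeg: Montage,
                             montage_fnirs: Montage):
    """Deterministic class -> (EEG channels, fNIRS weights) assignment.

    EEG channels are split into disjoint per-class groups; each fNIRS
    channel receives a weight from a Gaussian spatial kernel centred on the
    class's active EEG channels (spatial correspondence of the two layouts).
    """
    rng = np.random.default_rng(config.seed + 1)
    n_eeg = len(montage_eeg)
    n_cls = len(config.class_labels)
    perm = rng.permutation(n_eeg)
    per = max(1, n_eeg // n_cls)
    groups, weights = {}, {}
    for i, lab in enumerate(config.class_labels):
        idx = perm[i * per:(i + 1) * per]
        if idx.size == 0:  # more classes than channels: reuse (degenerate)
            idx = perm[:1]
        groups[lab] = np.sort(idx)
        d2 = ((montage_fnirs.xy[:, None, :] - montage_eeg.xy[None, idx, :]) ** 2).sum(-1)
        w = np.exp(-d2 / (2 * 0.3 ** 2)).sum(axis=1)
        weights[lab] = w / (w.max() + 1e-12)
    return groups, weights


def simulate_session(config: SimulationConfig, montages) -> RecordingPair:
    """Simulate one paired EEG-fNIRS session.  Deterministic under seed."""
    montage_eeg, montage_fnirs = montages
    rng = np.random.default_rng(config.seed)
    n_eeg, n_fnirs = len(montage_eeg), len(montage_fnirs)
    n_cls = len(config.class_labels)

    # --- trial timeline ----------------------------------------------------
    order = np.repeat(np.arange(n_cls), config.n_trials_per_class)
    rng.shuffle(order)
    events, t = [], _PRE_ROLL_S
    for ci in order:
        onset = t + config.cue_s
        events.append((onset, config.class_labels[ci]))
        rest = rng.uniform(*config.rest_s_range)
        t = onset + config.task_s + rest
    duration = t + _POST_ROLL_S
    n_samp_e = int(round(duration * config.fs_eeg))
    n_samp_f = int(round(duration * config.fs_fnirs))
    te = np.arange(n_samp_e) / config.fs_eeg

    groups, fnirs_w = class_channel_assignment(config, montage_eeg, montage_fnirs)

    # --- EEG oscillations and their envelopes ------------------------------
    eeg = np.zeros((n_eeg, n_samp_e))
    env_cls = {}
    for lab in config.class_labels:
        gate = np.zeros(n_samp_e)
        for onset, elab in events:
            if elab == lab:
                amp = rng.uniform(0.7, 1.3)  # per-trial excitability
                f_m = rng.uniform(*config.slow_mod_band)
                phi = rng.uniform(0, 2 * np.pi)
                mod = 1.0 + config.slow_mod_depth * np.sin(
                    2 * np.pi * f_m * (te - onset) + phi)
                gate += amp * mod * _task_gate(te, onset, config.task_s)
        env_sum = np.zeros(n_samp_e)
        for ch in groups[lab]:
            osc = _band_noise(rng, n_samp_e, config.fs_eeg, config.osc_band)
            eeg[ch] += osc * gate
            env_sum += np.abs(signal.hilbert(osc)) * gate
        env_cls[lab] = env_sum / len(groups[lab])

    # --- hemodynamics: HRF-convolved, lagged envelope drives HbO -----------
    dec = int(round(config.fs_eeg / config.fs_fnirs))
    kern = hrf_kernel(config.fs_fnirs)
    pk = int(np.argmax(kern))
    lag_samp = int(round(config.lag_s * config.fs_fnirs))
    hbo = np.zeros((n_fnirs, n_samp_f))
    for lab in config.class_labels:
        env_ds = signal.resample_poly(env_cls[lab], 1, dec)[:n_samp_f]
        drive = np.convolve(env_ds, kern)[:n_samp_f]
        drive = _shift(drive, lag_samp - pk)  # peak-aligned kernel + net lag
        hbo += fnirs_w[lab][:, None] * drive[None, :]
    hbo *= 1e-6 / (np.abs(hbo).max() + 1e-30)  # ~1 µM peak response

    # --- noise -------------------------------------------------------------
    task_mask = np.zeros(n_samp_e, dtype=bool)
    for onset, _ in events:
        task_mask |= (te >= onset) & (te < onset + config.task_s)
    sig_rms = np.sqrt(np.mean(eeg[:, task_mask] ** 2) + 1e-30)
    noise_sd = sig_rms * 10 ** (-config.snr_db / 20.0)
    eeg = eeg + noise_sd * rng.standard_normal(eeg.shape)

    hbo_rms = np.sqrt(np.mean(hbo ** 2) + 1e-60)
    f_noise_sd = hbo_rms * 10 ** (-config.snr_db / 20.0)
    tf = np.arange(n_samp_f) / config.fs_fnirs
    drift = np.zeros((n_fnirs, n_samp_f))
    for j in range(n_fnirs):
        freq = rng.uniform(0.005, 0.02)
        drift[j] = 0.2 * hbo_rms * np.sin(2 * np.pi * freq * tf + rng.uniform(0, 2 * np.pi))
    hbr = -0.4 * hbo + f_noise_sd * rng.standard_normal(hbo.shape) + drift
    hbo = hbo + f_noise_sd * rng.standard_normal(hbo.shape) + drift

    pair = RecordingPair(eeg, config.fs_eeg, hbo, hbr, config.fs_fnirs,
                         events, montage_eeg, montage_fnirs)
    pair.validate()
    return pair


# ---------------------------------------------------------------------------
# lag estimation (matched-filter cross-correlation)
# ---------------------------------------------------------------------------

def estimate_lag(pair: RecordingPair, config: SimulationConfig,
                 max_lag_s: float = 12.0) -> float:
    """Estimate the envelope-to-HbO lag of a session, in seconds.

    Cross-correlates the HRF-convolved task-channel EEG envelope (the
    hemodynamic prediction at zero lag) against mean HbO of the responsive
    channels; the argmax of the normalized cross-correlation is the lag.
    """
    groups, fnirs_w = class_channel_assignment(config, pair.montage_eeg, pair.montage_fnirs)
    fs_f = pair.fs_fnirs
    dec = int(round(pair.fs_eeg / fs_f))
    kern = hrf_kernel(fs_f)
    pk = int(np.argmax(kern))
    best, best_lag = -np.inf, 0.0
    lags = np.arange(0, int(max_lag_s * fs_f) + 1)
    for lab in groups:
        env = np.zeros(pair.eeg.shape[1])
        sos = signal.butter(4, (8.0, 30.0), btype="bandpass", fs=pair.fs_eeg, output="sos")
        for ch in groups[lab]:
            env += np.abs(signal.hilbert(signal.sosfiltfilt(sos, pair.eeg[ch])))
        env_ds = signal.resample_poly(env, 1, dec)[:pair.fnirs_hbo.shape[1]]
        pred = _shift(np.convolve(env_ds, kern)[:len(env_ds)], -pk)
        pred = pred - pred.mean()
        w = fnirs_w[lab]
        hbo = (w[:, None] * pair.fnirs_hbo).sum(axis=0) / w.sum()
        hbo = hbo - hbo.mean()
        for k in lags:
            a, b = pred[:len(pred) - k], hbo[k:]
            r = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-30))
            if r > best:
                best, best_lag = r, k / fs_f
    return best_lag
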