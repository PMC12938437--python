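"""Preprocessing: raw paired recordings -> model-input tensors.

Pipeline (per recording):

1. band filtering per modality (EEG: 50 Hz notch, 0.5-50 Hz Butterworth
   order 6, common-average reference; fNIRS: 0.01-0.1 Hz Butterworth
   order 6), all zero-phase,
2. trial segmentation (EEG 15-s windows = 5 s pre + 10 s post task onset at
   200 Hz; fNIRS 27-s windows = 5 s pre + 22 s post at 10 Hz),
3. per-trial baseline correction against the [0, +3] s reference interval,
4. 3-s / 1-s-step sliding-window augmentation of each EEG trial
   (13 anchors per 15-s trial),
5. for each EEG anchor, 11 overlapping 3-s fNIRS candidate windows at
   offsets 0..10 s (the 10-s hemodynamic search space),
6. topographic mapping of each time point onto a 16x16 grid (cubic
   interpolation inside the sensor hull, nearest-neighbour fill outside),
7. tensor assembly: EEG [1 x 600 x 16 x 16]; fNIRS 5-D
   [11 x G x G x 30 x 2] reshaped to 4-D [22 x 30 x 16 x 16]
   (window-major, chromophore-minor channel order).

The topographic map is a fixed linear operator per montage, so it is
precomputed once as a (G*G x n_channels) matrix and applied by matrix
multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree

from .synthgen import Montage, RecordingPair

__all__ = [
    "TrialWindow", "GridMap", "EEGSample", "FNIRSSample", "SampleSet",
    "resample", "filter_eeg", "filter_fnirs", "mbll", "baseline_correct",
    "segment_trials", "slide_eeg_windows", "candidate_fnirs_windows",
    "grid_map", "interpolation_matrix", "assemble_eeg_tensor",
    "assemble_fnirs_tensor", "fnirs_5d_to_4d", "fnirs_4d_to_5d",
    "standardize", "build_samples",
]

EEG_PRE_S, EEG_POST_S = 5.0, 10.0     # 15-s EEG trial window
FNIRS_PRE_S, FNIRS_POST_S = 5.0, 22.0  # 27-s fNIRS trial window
BASELINE_INTERVAL_S = (0.0, 3.0)       # reference interval, relative to onset
N_CANDIDATE_WINDOWS = 11               # 3-s windows at offsets 0..10 s
WINDOW_S = 3.0
GRID_SIZE = 16


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrialWindow:
    modality: str
    data: np.ndarray          # channels x samples (HbO/HbR stacked for fNIRS)
    fs: float
    onset_s: float            # window start relative to the trial event
    label: object
    subject_id: str = "S1"
    trial_id: int = 0


@dataclass
class GridMap:
    values: np.ndarray        # G x G
    modality: str
    time_index: int = 0


@dataclass
class EEGSample:
    tensor: np.ndarray        # 1 x D x G x G
    label: object
    subject_id: str
    trial_id: int
    anchor_offset_s: float


@dataclass
class FNIRSSample:
    tensor5d: np.ndarray      # 11 x G x G x 30 x 2
    label: object
    subject_id: str
    trial_id: int
    anchor_offset_s: float

    @property
    def tensor4d(self) -> np.ndarray:
        return fnirs_5d_to_4d(self.tensor5d)


@dataclass
class SampleSet:
    """Stacked model inputs for one subject/session."""

    eeg: np.ndarray           # N x 1 x D x G x G
    fnirs: np.ndarray         # N x 22 x 30 x G x G
    labels: np.ndarray        # N
    trial_ids: np.ndarray     # N
    anchor_offsets: np.ndarray  # N, seconds relative to trial event
    subject_id: str = "S1"

    def __len__(self):
        return len(self.labels)


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase downsampling (no upsampling path)."""
    if fs_out > fs_in:
        raise ValueError("upsampling is not supported")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                frac.denominator, axis=-1)


def filter_eeg(x: np.ndarray, fs: float) -> np.ndarray:
    """50 Hz notch -> 0.5-50 Hz Butterworth(6) bandpass (zero-phase) -> CAR."""
    if fs < 120:
        raise ValueError("fs must be >= 120 Hz to represent the 50 Hz band edge")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in EEG input")
    b, a = signal.iirnotch(50.0, Q=30.0, fs=fs)
    y = signal.filtfilt(b, a, x, axis=-1)
    sos = signal.butter(6, (0.5, 50.0), btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, y, axis=-1)
    return y - y.mean(axis=0, keepdims=True)  # common average reference


def filter_fnirs(x: np.ndarray, fs: float) -> np.ndarray:
    """0.01-0.1 Hz Butterworth(6) bandpass, zero-phase, no re-referencing."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in fNIRS input")
    sos = signal.butter(6, (0.01, 0.1), btype="bandpass", fs=fs, output="sos")
    # the 0.01 Hz edge gives very long impulse responses; extend the
    # reflect-padding well beyond filtfilt's default to tame edge transients
    padlen = min(x.shape[-1] - 1, int(100 * fs))
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


# extinction coefficients [1/(mM*cm)] at the two operating wavelengths,
# rows = wavelength (760, 850 nm), cols = (HbO, HbR)
EXTINCTION = np.array([[0.586, 1.548],
                       [1.058, 0.691]])
WAVELENGTHS_NM = (760.0, 850.0)


def mbll(intensity: np.ndarray, channel_distances_cm, dpf,
         extinction: np.ndarray = EXTINCTION,
         baseline: np.ndarray | None = None) -> tuple:
    """Modified Beer-Lambert law: dual-wavelength intensity -> (HbO, HbR).

    Parameters
    ----------
    intensity : (n_channels, 2, n_samples) raw optical intensity, axis 1 =
        wavelength.  Must be strictly positive.
    channel_distances_cm : per-channel source-detector separation.
    dpf : differential pathlength factor, scalar or per-wavelength pair.
    baseline : reference intensity per (channel, wavelength); defaults to the
        temporal mean.

    ΔOD_λ = -log10(I / I0);  ΔOD_λ = L * DPF_λ * (ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR)
    solved per channel as a 2x2 linear system.
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I <= 0):
        raise ValueError("intensities must be strictly positive")
    if I.ndim != 3 or I.shape[1] != 2:
        raise ValueError("intensity must have shape (channels, 2 wavelengths, samples)")
    if abs(np.linalg.det(extinction)) < 1e-12:
        raise ValueError("singular extinction-coefficient matrix")
    if baseline is None:
        baseline = I.mean(axis=-1)
    dod = -np.log10(I / baseline[:, :, None])  # (ch, 2, T)
    L = np.atleast_1d(np.asarray(channel_distances_cm, dtype=float))
    dpf = np.broadcast_to(np.asarray(dpf, dtype=float), (2,))
    n_ch = I.shape[0]
    if L.size == 1:
        L = np.full(n_ch, L[0])
    hbo = np.empty((n_ch, I.shape[-1]))
    hbr = np.empty_like(hbo)
    for c in range(n_ch):
        A = extinction * (L[c] * dpf)[:, None]  # (2 wl, 2 chromophores)
        conc = np.linalg.solve(A, dod[c])
        hbo[c], hbr[c] = conc[0], conc[1]
    return hbo, hbr


def mbll_forward(hbo: np.ndarray, hbr: np.ndarray, channel_distances_cm, dpf,
                 extinction: np.ndarray = EXTINCTION,
                 baseline_intensity: float = 1.0) -> np.ndarray:
    """Forward Beer-Lambert map (concentrations -> intensities); inverse of
    :func:`mbll`, used to synthesize optical data with known ground truth."""
    n_ch = hbo.shape[0]
    L = np.broadcast_to(np.asarray(channel_distances_cm, dtype=float), (n_ch,))
    dpf = np.broadcast_to(np.asarray(dpf, dtype=float), (2,))
    I = np.empty((n_ch, 2, hbo.shape[-1]))
    for c in range(n_ch):
        A = extinction * (L[c] * dpf)[:, None]
        dod = A @ np.vstack([hbo[c], hbr[c]])
        I[c] = baseline_intensity * 10.0 ** (-dod)
    return I


# ---------------------------------------------------------------------------
# segmentation and windowing
# ---------------------------------------------------------------------------

def baseline_correct(trial: TrialWindow,
                     interval_s: tuple = BASELINE_INTERVAL_S) -> TrialWindow:
    """Subtract the per-channel mean of the reference interval (relative to
    the trial event) from the whole trial window."""
    lo, hi = interval_s
    i0 = int(round((lo - trial.onset_s) * trial.fs))
    i1 = int(round((hi - trial.onset_s) * trial.fs))
    if i0 < 0 or i1 > trial.data.shape[-1] or i1 <= i0:
        raise ValueError("trial window does not contain the baseline interval")
    ref = trial.data[:, i0:i1].mean(axis=-1, keepdims=True)
    out = TrialWindow(trial.modality, trial.data - ref, trial.fs,
                      trial.onset_s, trial.label, trial.subject_id, trial.trial_id)
    return out


def segment_trials(pair: RecordingPair, subject_id: str = "S1",
                   apply_baseline: bool = True) -> list:
    """Cut one (EEG, fNIRS) trial-window pair per event.

    Events too close to a recording edge are skipped with a warning.
    fNIRS HbO and HbR are stacked along the channel axis (HbO first).
    """
    import warnings

    out = []
    n_e, n_f = pair.eeg.shape[1], pair.fnirs_hbo.shape[1]
    for tid, (onset, label) in enumerate(pair.events):
        e0 = int(round((onset - EEG_PRE_S) * pair.fs_eeg))
        e1 = e0 + int(round((EEG_PRE_S + EEG_POST_S) * pair.fs_eeg))
        f0 = int(round((onset - FNIRS_PRE_S) * pair.fs_fnirs))
        f1 = f0 + int(round((FNIRS_PRE_S + FNIRS_POST_S) * pair.fs_fnirs))
        if e0 < 0 or e1 > n_e or f0 < 0 or f1 > n_f:
            warnings.warn(f"event {tid} at {onset:.1f} s too close to a recording "
                          "edge; skipped")
            continue
        etw = TrialWindow("EEG", pair.eeg[:, e0:e1].copy(), pair.fs_eeg,
                          -EEG_PRE_S, label, subject_id, tid)
        fdata = np.concatenate([pair.fnirs_hbo[:, f0:f1], pair.fnirs_hbr[:, f0:f1]])
        ftw = TrialWindow("fNIRS", fdata, pair.fs_fnirs, -FNIRS_PRE_S,
                          label, subject_id, tid)
        if apply_baseline:
            etw = baseline_correct(etw)
            ftw = baseline_correct(ftw)
        out.append((etw, ftw))
    return out


def slide_eeg_windows(trial: TrialWindow, win_s: float = WINDOW_S,
                      step_s: float = 1.0) -> list:
    """3-s / 1-s-step sliding anchors over an EEG trial window.

    Returns a list of TrialWindow anchors; a 15-s trial yields 13.
    """
    n = trial.data.shape[-1]
    total_s = n / trial.fs
    if win_s > total_s:
        raise ValueError("window longer than trial")
    wn = int(round(win_s * trial.fs))
    anchors = []
    k = 0
    while True:
        start = k * step_s
        i0 = int(round(start * trial.fs))
        if i0 + wn > n:
            break
        anchors.append(TrialWindow(trial.modality, trial.data[:, i0:i0 + wn],
                                   trial.fs, trial.onset_s + start, trial.label,
                                   trial.subject_id, trial.trial_id))
        k += 1
    return anchors


def candidate_fnirs_windows(anchor: TrialWindow, fnirs_trial: TrialWindow,
                            n_windows: int = N_CANDIDATE_WINDOWS,
                            win_s: float = WINDOW_S) -> np.ndarray:
    """The hemodynamic search space: `n_windows` 3-s fNIRS windows starting
    0, 1, ..., n_windows-1 seconds after the EEG anchor onset.

    Returns (n_windows, 2, n_fnirs_channels, 30): axis 1 = (HbO, HbR).
    """
    fs = fnirs_trial.fs
    wn = int(round(win_s * fs))
    n_ch = fnirs_trial.data.shape[0] // 2
    hbo, hbr = fnirs_trial.data[:n_ch], fnirs_trial.data[n_ch:]
    out = np.empty((n_windows, 2, n_ch, wn))
    for k in range(n_windows):
        start_s = (anchor.onset_s - fnirs_trial.onset_s) + k
        i0 = int(round(start_s * fs))
        if i0 < 0 or i0 + wn > fnirs_trial.data.shape[-1]:
            raise ValueError("candidate window leaves the fNIRS trial span")
        out[k, 0] = hbo[:, i0:i0 + wn]
        out[k, 1] = hbr[:, i0:i0 + wn]
    return out


# ---------------------------------------------------------------------------
# topographic grid mapping
# ---------------------------------------------------------------------------

_INTERP_CACHE: dict = {}


def interpolation_matrix(montage: Montage, grid_size: int = GRID_SIZE) -> np.ndarray:
    """Fixed (grid_size**2 x n_channels) linear operator of the topographic
    map: cubic (Clough-Tocher) interpolation inside the sensor convex hull,
    nearest-neighbour fill outside.  Cached per montage."""
    key = (montage.names, montage.xy.tobytes(), grid_size)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    pts = montage.xy
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError("montage has fewer than 3 non-collinear channels") from e
    g = np.linspace(-1.0, 1.0, grid_size)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    n = len(pts)
    M = np.empty((grid_size * grid_size, n))
    for i in range(n):
        basis = np.zeros(n)
        basis[i] = 1.0
        M[:, i] = CloughTocher2DInterpolator(tri, basis)(nodes)
    outside = np.isnan(M[:, 0])
    nearest = cKDTree(pts).query(nodes[outside])[1]
    M[outside] = 0.0
    M[np.nonzero(outside)[0], nearest] = 1.0
    _INTERP_CACHE[key] = M
    return M


def raster_matrix(n_channels: int, grid_size: int = GRID_SIZE) -> np.ndarray:
    """Spatial-mapping ablation operator: channel i is written to grid cell i
    (row-major), all other cells stay zero — no topographic interpolation."""
    if n_channels > grid_size * grid_size:
        raise ValueError("more channels than grid cells")
    M = np.zeros((grid_size * grid_size, n_channels))
    M[np.arange(n_channels), np.arange(n_channels)] = 1.0
    return M


def grid_map(channel_values: np.ndarray, montage: Montage,
             grid_size: int = GRID_SIZE) -> GridMap:
    """Project one per-channel value vector onto the topographic grid."""
    v = np.asarray(channel_values, dtype=float)
    if v.shape != (len(montage),):
        raise ValueError("one value per montage channel required")
    M = interpolation_matrix(montage, grid_size)
    return GridMap((M @ v).reshape(grid_size, grid_size), montage.modality)


# ---------------------------------------------------------------------------
# tensor assembly
# ---------------------------------------------------------------------------

def assemble_eeg_tensor(anchor: TrialWindow, montage: Montage,
                        grid_size: int = GRID_SIZE,
                        mapping_matrix: np.ndarray | None = None) -> EEGSample:
    """Stack one topographic map per time point: [1 x D x G x G]."""
    M = mapping_matrix if mapping_matrix is not None else \
        interpolation_matrix(montage, grid_size)
    maps = (M @ anchor.data)                   # (G*G, D)
    d = anchor.data.shape[-1]
    tensor = maps.T.reshape(1, d, grid_size, grid_size)
    return EEGSample(tensor, anchor.label, anchor.subject_id,
                     anchor.trial_id, anchor.onset_s)


def assemble_fnirs_tensor(candidates: np.ndarray, montage: Montage,
                          anchor: TrialWindow,
                          grid_size: int = GRID_SIZE,
                          mapping_matrix: np.ndarray | None = None) -> FNIRSSample:
    """Map the (11, 2, ch, 30) candidate windows to the 5-D tensor
    [11 x G x G x 30 x 2]; the 4-D network input is its reshape."""
    M = mapping_matrix if mapping_matrix is not None else \
        interpolation_matrix(montage, grid_size)
    n_w, _, n_ch, n_t = candidates.shape
    # (11, 2, ch, 30) -> grid: (11, 2, G*G, 30)
    mapped = np.einsum("gc,wxct->wxgt", M, candidates, optimize=True)
    t5 = mapped.reshape(n_w, 2, grid_size, grid_size, n_t).transpose(0, 2, 3, 4, 1)
    return FNIRSSample(t5, anchor.label, anchor.subject_id,
                       anchor.trial_id, anchor.onset_s)


def fnirs_5d_to_4d(t5: np.ndarray) -> np.ndarray:
    """[11 x G x G x 30 x 2] -> [22 x 30 x G x G], window-major
    chromophore-minor channel order (w0*HbO, w0*HbR, w1*HbO, ...)."""
    n_w, g, _, n_t, _ = t5.shape
    return t5.transpose(0, 4, 3, 1, 2).reshape(n_w * 2, n_t, g, g)


def fnirs_4d_to_5d(t4: np.ndarray) -> np.ndarray:
    """Lossless inverse of :func:`fnirs_5d_to_4d`."""
    n_c, n_t, g, _ = t4.shape
    return t4.reshape(n_c // 2, 2, n_t, g, g).transpose(0, 3, 4, 2, 1)


def standardize(tensor: np.ndarray) -> np.ndarray:
    """Per-sample z-scoring over the whole tensor (mean 0, sd 1)."""
    mu = tensor.mean()
    sd = tensor.std()
    return (tensor - mu) / (sd + 1e-12)


# ---------------------------------------------------------------------------
# end-to-end sample construction
# ---------------------------------------------------------------------------

def build_samples(pair: RecordingPair, subject_id: str = "S1",
                  grid_size: int = GRID_SIZE, zscore: bool = True,
                  apply_filters: bool = True,
                  mapping: str = "topographic",
                  eeg_fs_out: float | None = None) -> SampleSet:
    """Full pipeline for one session: filtering -> segmentation -> windows ->
    grids -> stacked (EEG, fNIRS) sample tensors.

    A session with E usable events yields exactly 13*E sample pairs.
    ``mapping="raster"`` skips topographic interpolation (ablation);
    ``eeg_fs_out`` additionally downsamples the filtered EEG (reduced-scale
    experiments trading temporal depth for speed).
    """
    if mapping == "topographic":
        m_eeg = interpolation_matrix(pair.montage_eeg, grid_size)
        m_fnirs = interpolation_matrix(pair.montage_fnirs, grid_size)
    elif mapping == "raster":
        m_eeg = raster_matrix(len(pair.montage_eeg), grid_size)
        m_fnirs = raster_matrix(len(pair.montage_fnirs), grid_size)
    else:
        raise ValueError("mapping must be 'topographic' or 'raster'")
    if apply_filters:
        pair = RecordingPair(filter_eeg(pair.eeg, pair.fs_eeg), pair.fs_eeg,
                             filter_fnirs(pair.fnirs_hbo, pair.fs_fnirs),
                             filter_fnirs(pair.fnirs_hbr, pair.fs_fnirs),
                             pair.fs_fnirs, pair.events,
                             pair.montage_eeg, pair.montage_fnirs)
    if eeg_fs_out is not None and eeg_fs_out != pair.fs_eeg:
        eeg = pair.eeg
        if eeg_fs_out < 2 * 50.0:
            # below the analysis band's Nyquist rate plain decimation would
            # alias the oscillations away; keep their amplitude envelope
            eeg = np.abs(signal.hilbert(eeg, axis=-1))
        pair = RecordingPair(resample(eeg, pair.fs_eeg, eeg_fs_out),
                             eeg_fs_out, pair.fnirs_hbo, pair.fnirs_hbr,
                             pair.fs_fnirs, pair.events,
                             pair.montage_eeg, pair.montage_fnirs)
    eeg_list, fnirs_list, labels, tids, offs = [], [], [], [], []
    for etw, ftw in segment_trials(pair, subject_id):
        for anchor in slide_eeg_windows(etw):
            cand = candidate_fnirs_windows(anchor, ftw)
            es = assemble_eeg_tensor(anchor, pair.montage_eeg, grid_size, m_eeg)
            fsamp = assemble_fnirs_tensor(cand, pair.montage_fnirs, anchor,
                                          grid_size, m_fnirs)
            et, ft = es.tensor, fsamp.tensor4d
            if zscore:
                et, ft = standardize(et), standardize(ft)
            eeg_list.append(et)
            fnirs_list.append(ft)
            labels.append(anchor.label)
            tids.append(anchor.trial_id)
            offs.append(anchor.onset_s)
    return SampleSet(np.stack(eeg_list), np.stack(fnirs_list),
                     np.asarray(labels), np.asarray(tids),
                     np.asarray(offs, dtype=float), subject_id)
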