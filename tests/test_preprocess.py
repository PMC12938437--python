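"""Preprocessing pipeline: filters, MBLL, segmentation, grids, tensors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import Delaunay

from bistfnet import preprocess as pp
from bistfnet.preprocess import (TrialWindow, assemble_eeg_tensor,
                                 assemble_fnirs_tensor, baseline_correct,
                                 build_samples, candidate_fnirs_windows,
                                 filter_eeg, filter_fnirs, fnirs_4d_to_5d,
                                 fnirs_5d_to_4d, grid_map, mbll, resample,
                                 segment_trials, slide_eeg_windows,
                                 standardize)
from bistfnet.preprocess import mbll_forward
from bistfnet.synthgen import Montage


# ---------------------------------------------------------------------------
# resampling and filtering
# ---------------------------------------------------------------------------

def test_resample_identity_and_length():
    x = np.random.default_rng(0).standard_normal((3, 10_000))
    np.testing.assert_array_equal(resample(x, 1000, 1000), x)
    assert resample(x, 1000, 200).shape == (3, 2000)
    with pytest.raises(ValueError):
        resample(x, 200, 1000)


def test_resample_preserves_sine_amplitude():
    t = np.arange(10_000) / 1000.0
    x = np.sin(2 * np.pi * 7.0 * t)[None]
    y = resample(x, 1000, 200)[0]
    assert np.abs(y[100:-100]).max() == pytest.approx(1.0, rel=0.01)


def _butter_bandpass_mag2(f, lo, hi, order):
    """Closed-form squared magnitude of an analog Butterworth bandpass:
    |H|^2 = 1 / (1 + W(f)^(2n)) with W = (f^2 - lo*hi) / (f * (hi - lo))."""
    W = (f * f - lo * hi) / (f * (hi - lo))
    return 1.0 / (1.0 + W ** (2 * order))


def test_filter_eeg_dc_and_passband():
    fs = 200.0
    t = np.arange(int(20 * fs)) / fs
    dc = np.full((2, t.size), 5.0)
    out = filter_eeg(dc, fs)
    assert np.abs(out[:, 200:-200]).max() < 0.05  # <1% of the DC input

    x = np.stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)])
    y = filter_eeg(x, fs)
    # zero-phase filtering applies |H|^2; compare to the analytic response
    meas = np.abs(y[0, 400:-400]).max()
    # CAR couples the two channels; measure against the CAR'd input amplitude
    x_car = x - x.mean(axis=0, keepdims=True)
    ref_amp = np.abs(x_car[0]).max()
    expected = _butter_bandpass_mag2(10.0, 0.5, 50.0, 6)  # |H|^2 for filtfilt
    att_db = 20 * np.log10(meas / ref_amp)
    exp_db = 10 * np.log10(expected) * 2
    assert abs(att_db) < 1.0 and abs(att_db - exp_db) < 1.0


def test_filter_eeg_common_average_is_zero_mean():
    rng = np.random.default_rng(1)
    y = filter_eeg(rng.standard_normal((5, 4000)), 200.0)
    np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-9)


def test_filter_eeg_rejects_bad_input():
    with pytest.raises(ValueError):
        filter_eeg(np.full((2, 1000), np.nan), 200.0)
    with pytest.raises(ValueError):
        filter_eeg(np.zeros((2, 1000)), 100.0)


def test_filter_fnirs_band():
    # steady-state (interior) attenuation; the 0.01 Hz edge implies onset
    # transients that take hundreds of seconds to decay, so edges are cut
    fs = 10.0
    t = np.arange(int(3000 * fs)) / fs
    inband = np.sin(2 * np.pi * 0.05 * t)[None]
    y = filter_fnirs(inband, fs)[0]
    att = 20 * np.log10(np.abs(y[5000:-5000]).max())
    assert att > -1.0  # < 1 dB attenuation at 0.05 Hz

    fast = np.sin(2 * np.pi * 1.0 * t)[None]
    y2 = filter_fnirs(fast, fs)[0]
    assert 20 * np.log10(np.abs(y2[10000:-10000]).max() + 1e-300) < -20.0

    dc = np.ones((1, t.size))
    assert np.abs(filter_fnirs(dc, fs)[:, 500:-500]).max() < 1e-2


# ---------------------------------------------------------------------------
# modified Beer-Lambert law
# ---------------------------------------------------------------------------

def test_mbll_constant_intensity_gives_zero():
    I = np.ones((4, 2, 100))
    hbo, hbr = mbll(I, channel_distances_cm=3.0, dpf=6.0)
    np.testing.assert_allclose(hbo, 0.0, atol=1e-12)
    np.testing.assert_allclose(hbr, 0.0, atol=1e-12)


def test_mbll_roundtrip_recovers_concentrations(rng):
    hbo = 1e-3 * rng.standard_normal((3, 50))
    hbr = 1e-3 * rng.standard_normal((3, 50))
    I = mbll_forward(hbo, hbr, channel_distances_cm=3.0, dpf=6.0)
    hbo2, hbr2 = mbll(I, channel_distances_cm=3.0, dpf=6.0,
                      baseline=np.ones((3, 2)))
    np.testing.assert_allclose(hbo2, hbo, atol=1e-6)
    np.testing.assert_allclose(hbr2, hbr, atol=1e-6)


def test_mbll_halving_intensity_is_log2():
    I = np.ones((1, 2, 4))
    I[0, 0, 2:] = 0.5  # halve wavelength 0 in the second half
    base = np.ones((1, 2))
    dod = -np.log10(I / base[:, :, None])
    assert dod[0, 0, 3] == pytest.approx(np.log10(2))
    # and the concentration solve responds linearly to that ΔOD step
    hbo, hbr = mbll(I, 3.0, 6.0, baseline=base)
    assert hbo[0, 3] != 0 and hbr[0, 3] != 0


def test_mbll_rejects_nonpositive_and_singular():
    with pytest.raises(ValueError):
        mbll(np.zeros((1, 2, 3)), 3.0, 6.0)
    with pytest.raises(ValueError):
        mbll(np.ones((1, 2, 3)), 3.0, 6.0,
             extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))


# ---------------------------------------------------------------------------
# segmentation and windows
# ---------------------------------------------------------------------------

def _trial(data, fs=200.0, onset_s=-5.0, label=0):
    return TrialWindow("EEG", data, fs, onset_s, label)


def test_baseline_correct_constant_and_piecewise():
    const = _trial(np.full((2, 3000), 7.0))
    out = baseline_correct(const)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    data = np.zeros((1, 3000))
    data[:, 1000:1600] = 1.5   # [0, 3] s reference interval at 200 Hz
    data[:, 1600:] = 4.0
    out = baseline_correct(_trial(data))
    np.testing.assert_allclose(out.data[:, 1000:1600], 0.0, atol=1e-12)
    np.testing.assert_allclose(out.data[:, 1600:], 2.5, atol=1e-12)
    # per-channel mean over the reference interval is exactly zero
    assert abs(out.data[:, 1000:1600].mean()) < 1e-9


def test_baseline_interval_absent_rejected():
    with pytest.raises(ValueError):
        baseline_correct(_trial(np.zeros((1, 400)), onset_s=4.0))


def test_segment_trials_shapes_and_count(small_session):
    pair, _ = small_session
    pairs = segment_trials(pair)
    assert len(pairs) == len(pair.events)
    etw, ftw = pairs[0]
    assert etw.data.shape[1] == 3000   # 15 s x 200 Hz
    assert ftw.data.shape[1] == 270    # 27 s x 10 Hz
    assert etw.label == ftw.label and etw.trial_id == ftw.trial_id


def test_segment_skips_edge_events(small_session):
    pair, _ = small_session
    hacked = pair.events[:1] + [(2.0, 0)] + pair.events[1:]
    hacked.sort()
    bad = pp.RecordingPair(pair.eeg, pair.fs_eeg, pair.fnirs_hbo,
                           pair.fnirs_hbr, pair.fs_fnirs, hacked,
                           pair.montage_eeg, pair.montage_fnirs)
    with pytest.warns(UserWarning, match="skipped"):
        pairs = segment_trials(bad)
    assert len(pairs) == len(pair.events)


def test_sliding_anchor_count_and_bookkeeping():
    tw = _trial(np.zeros((2, 3000)))
    anchors = slide_eeg_windows(tw)
    assert len(anchors) == 13                       # (15 - 3)/1 + 1
    assert {a.trial_id for a in anchors} == {tw.trial_id}
    offs = [a.onset_s - tw.onset_s for a in anchors]
    np.testing.assert_allclose(offs, np.arange(13.0))

    single = slide_eeg_windows(_trial(np.zeros((2, 600))))
    assert len(single) == 1
    with pytest.raises(ValueError):
        slide_eeg_windows(_trial(np.zeros((2, 400))))


def test_candidate_windows_construction(small_session):
    pair, _ = small_session
    etw, ftw = segment_trials(pair)[0]
    ramp = np.arange(270, dtype=float)
    ftw = TrialWindow("fNIRS", np.vstack([np.tile(ramp, (8, 1)),
                                          np.tile(-ramp, (8, 1))]),
                      10.0, -5.0, 0)
    for anchor in slide_eeg_windows(etw):
        cand = candidate_fnirs_windows(anchor, ftw)
        assert cand.shape == (11, 2, 8, 30)
        # window k starts exactly k seconds (10 samples) after window 0
        for k in range(11):
            np.testing.assert_allclose(cand[k, 0, 0] - cand[0, 0, 0], 10.0 * k)
    # last anchor's last window must still fit inside the 27-s trial
    last = slide_eeg_windows(etw)[-1]
    start_offset = last.onset_s - ftw.onset_s + 10  # seconds into fNIRS trial
    assert start_offset + 3 <= 27


# ---------------------------------------------------------------------------
# topographic mapping
# ---------------------------------------------------------------------------

def test_grid_map_constant_field(small_montages):
    m, _ = small_montages
    g = grid_map(np.full(len(m), 3.25), m)
    assert g.values.shape == (16, 16)
    np.testing.assert_allclose(g.values, 3.25, atol=1e-9)


def test_grid_map_linear_field_inside_hull(small_montages):
    m, _ = small_montages
    f = lambda x, y: 2 * x - y
    g = grid_map(f(m.xy[:, 0], m.xy[:, 1]), m).values
    tri = Delaunay(m.xy)
    axis = np.linspace(-1, 1, 16)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    inside = tri.find_simplex(np.column_stack([gx.ravel(), gy.ravel()])) >= 0
    expected = f(gx.ravel(), gy.ravel())
    np.testing.assert_allclose(g.ravel()[inside], expected[inside], atol=1e-6)


def test_grid_map_nearest_fill_outside_hull(small_montages):
    m, _ = small_montages
    rng = np.random.default_rng(4)
    vals = rng.standard_normal(len(m))
    g = grid_map(vals, m).values.ravel()
    tri = Delaunay(m.xy)
    axis = np.linspace(-1, 1, 16)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    outside = tri.find_simplex(nodes) < 0
    assert outside.any()
    from scipy.spatial import cKDTree
    nearest = cKDTree(m.xy).query(nodes[outside])[1]
    np.testing.assert_allclose(g[outside], vals[nearest], atol=1e-12)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(perm_seed=st.integers(0, 10_000))
def test_grid_map_permutation_invariant(perm_seed):
    base, _ = __import__("bistfnet").make_montage(7, 7, seed=1)
    rng = np.random.default_rng(perm_seed)
    p = rng.permutation(len(base))
    vals = rng.standard_normal(len(base))
    permuted = Montage(tuple(base.names[i] for i in p), base.xy[p], "EEG")
    g1 = grid_map(vals, base).values
    g2 = grid_map(vals[p], permuted).values
    # equality up to the interpolator's internal gradient-solver tolerance
    np.testing.assert_allclose(g1, g2, atol=1e-5)


def test_grid_map_rejects_collinear():
    with pytest.raises(ValueError):
        Montage(("a", "b", "c"), [[0, 0], [0.3, 0.3], [0.6, 0.6]], "EEG")


# ---------------------------------------------------------------------------
# tensor assembly
# ---------------------------------------------------------------------------

def test_eeg_tensor_shape_and_slices(small_montages):
    m, _ = small_montages
    rng = np.random.default_rng(5)
    data = rng.standard_normal((len(m), 600))
    anchor = TrialWindow("EEG", data, 200.0, 0.0, 1)
    s = assemble_eeg_tensor(anchor, m)
    assert s.tensor.shape == (1, 600, 16, 16)
    np.testing.assert_allclose(s.tensor[0, 17], grid_map(data[:, 17], m).values,
                               atol=1e-12)
    const = assemble_eeg_tensor(
        TrialWindow("EEG", np.tile(data[:, :1], (1, 600)), 200.0, 0.0, 1), m)
    assert np.ptp(const.tensor, axis=1).max() < 1e-12  # all slices identical


def test_fnirs_tensor_shapes_and_roundtrip(small_montages):
    _, m = small_montages
    rng = np.random.default_rng(6)
    cand = rng.standard_normal((11, 2, len(m), 30))
    anchor = TrialWindow("EEG", np.zeros((1, 600)), 200.0, 0.0, 0)
    s = assemble_fnirs_tensor(cand, m, anchor)
    assert s.tensor5d.shape == (11, 16, 16, 30, 2)
    t4 = s.tensor4d
    assert t4.shape == (22, 30, 16, 16)
    np.testing.assert_array_equal(fnirs_4d_to_5d(t4), s.tensor5d)
    # window-major, chromophore-minor: channel 2k is HbO of window k
    np.testing.assert_array_equal(t4[6], s.tensor5d[3, :, :, :, 0].transpose(2, 0, 1))
    np.testing.assert_array_equal(t4[7], s.tensor5d[3, :, :, :, 1].transpose(2, 0, 1))


def test_standardize():
    x = np.random.default_rng(7).standard_normal((4, 5)) * 9 + 3
    z = standardize(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std() == pytest.approx(1.0, abs=1e-6)


def test_end_to_end_sample_count_and_finiteness(small_session):
    pair, _ = small_session
    data = build_samples(pair)
    assert len(data) == 13 * len(pair.events)
    assert data.eeg.shape[1:] == (1, 600, 16, 16)
    assert data.fnirs.shape[1:] == (22, 30, 16, 16)
    assert np.isfinite(data.eeg).all() and np.isfinite(data.fnirs).all()
    # all windows of one trial share its label
    for tid in np.unique(data.trial_ids):
        assert len(set(data.labels[data.trial_ids == tid])) == 1


def test_raster_mapping_places_channels(small_session):
    pair, _ = small_session
    data = build_samples(pair, mapping="raster", zscore=False)
    n_ch = len(pair.montage_eeg)
    flat = data.eeg[0, 0, 0].ravel()
    assert np.all(flat[n_ch:] == 0.0)
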