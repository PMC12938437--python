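"""ATA alignment, Pearson loss, SCAF fusion and classifier heads."""

import numpy as np
import pytest

from bistfnet.align_fuse import (ATA, SCAF, BiSTFNet, FNIRSSequenceEncoder,
                                 ModelConfig, pcc_loss)
from bistfnet.autodiff import Tensor
from bistfnet.losses_metrics import ce_loss_from_logits
from bistfnet.presets import reduced_model_config


# ---------------------------------------------------------------------------
# sequence encoder
# ---------------------------------------------------------------------------

def test_encoder_output_shape_full_contract(rng):
    enc = FNIRSSequenceEncoder(step_features=256, rng=rng)
    steps = Tensor(rng.standard_normal((3, 4, 256)))
    assert enc(steps).shape == (3, 4, 256)  # Bi-GRU: 2 x 128 hidden


def test_encoder_degenerate_single_step(rng):
    enc = FNIRSSequenceEncoder(step_features=10, rng=rng, proj_dim=8, hidden=4)
    out = enc(Tensor(rng.standard_normal((2, 1, 10))))
    assert out.shape == (2, 1, 8)
    assert np.isfinite(out.data).all()


def test_encoder_stateless(rng):
    enc = FNIRSSequenceEncoder(step_features=6, rng=rng, proj_dim=4, hidden=3)
    x = Tensor(rng.standard_normal((2, 5, 6)))
    np.testing.assert_array_equal(enc(x).data, enc(x).data)


# ---------------------------------------------------------------------------
# ATA
# ---------------------------------------------------------------------------

def test_ata_identical_steps_uniform_context(rng):
    ata = ATA(eeg_ch=4, d_model=8, rng=rng, n_heads=2, project_kv=False)
    h = Tensor(np.tile(rng.standard_normal((1, 1, 8)), (1, 5, 1)))
    e1 = Tensor(rng.standard_normal((1, 4, 6, 3, 3)))
    e2 = Tensor(rng.standard_normal((1, 4, 6, 3, 3)))
    _, _, ctx1 = ata(e1, h)
    w1 = ata.last_attention
    _, _, ctx2 = ata(e2, h)
    # context independent of the query content when all values are identical
    np.testing.assert_allclose(ctx1.data, ctx2.data, atol=1e-10)
    np.testing.assert_allclose(w1.sum(axis=-1), 1.0, atol=1e-9)


def test_ata_matches_loop_oracle(rng):
    """Single-head ATA against a hand-rolled attention computation."""
    ata = ATA(eeg_ch=3, d_model=6, rng=rng, n_heads=1, project_kv=False)
    e_block = rng.standard_normal((1, 3, 4, 2, 2))
    h = rng.standard_normal((1, 3, 6))
    aligned, q_sum, ctx = ata(Tensor(e_block), Tensor(h))

    pooled = e_block.mean(axis=(3, 4)).transpose(0, 2, 1)  # B, T_e, C
    q = pooled @ ata.q_proj.W.data + ata.q_proj.b.data
    Qp = q @ ata.mha.Wq.W.data + ata.mha.Wq.b.data
    ctxs = np.zeros((4, 6))
    for i in range(4):
        scores = np.array([Qp[0, i] @ h[0, j] for j in range(3)]) / np.sqrt(6)
        a = np.exp(scores - scores.max())
        a = a / a.sum()
        ctxs[i] = sum(a[j] * h[0, j] for j in range(3))
    ref_ctx = ctxs @ ata.mha.Wo.W.data + ata.mha.Wo.b.data
    np.testing.assert_allclose(ctx.data[0], ref_ctx.mean(axis=0), atol=1e-5)
    np.testing.assert_allclose(q_sum.data[0], q[0].mean(axis=0), atol=1e-10)


def test_ata_output_dim_contract(rng):
    ata = ATA(eeg_ch=16, d_model=256, rng=rng)
    aligned, q_sum, _ = ata(Tensor(rng.standard_normal((2, 16, 50, 4, 4))),
                            Tensor(rng.standard_normal((2, 4, 256))))
    assert aligned.shape == (2, 256) and q_sum.shape == (2, 256)


def test_ata_dimension_mismatch_rejected(rng):
    ata = ATA(eeg_ch=4, d_model=8, rng=rng, n_heads=2)
    with pytest.raises(ValueError):
        ata(Tensor(np.zeros((1, 4, 6, 3, 3))), Tensor(np.zeros((1, 3, 12))))


# ---------------------------------------------------------------------------
# Pearson loss
# ---------------------------------------------------------------------------

def test_pcc_affine_and_anticorrelated(rng):
    q = Tensor(rng.standard_normal((4, 256)))
    assert pcc_loss(q, q * 2.0 + 3.0).item() == pytest.approx(-1.0, abs=1e-6)
    assert pcc_loss(q, -q).item() == pytest.approx(1.0, abs=1e-6)


def test_pcc_matches_textbook_oracle(rng):
    for _ in range(20):
        q = rng.standard_normal((5, 33))
        f = rng.standard_normal((5, 33))
        rows = [np.corrcoef(qi, fi)[0, 1] for qi, fi in zip(q, f)]
        expected = -float(np.mean(rows))
        assert pcc_loss(Tensor(q), Tensor(f)).item() == \
            pytest.approx(expected, abs=1e-6)


def test_pcc_bounded_and_guarded(rng):
    # zero-variance row must not produce NaN (epsilon guard)
    q = np.ones((2, 8))
    f = rng.standard_normal((2, 8))
    v = pcc_loss(Tensor(q), Tensor(f)).item()
    assert np.isfinite(v) and -1.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# SCAF
# ---------------------------------------------------------------------------

def _tied_scaf(rng):
    sc = SCAF(d_in=16, rng=rng, d_model=8, n_heads=2)
    sc.fnirs_in.W.data = sc.eeg_in.W.data.copy()
    sc.fnirs_in.b.data = sc.eeg_in.b.data.copy()
    sc.refine_fnirs.W.data = sc.refine_eeg.W.data.copy()
    sc.refine_fnirs.b.data = sc.refine_eeg.b.data.copy()
    sc.pos.data[:] = 0.0
    return sc


def test_scaf_mse_zero_at_equality(rng):
    sc = _tied_scaf(rng)
    e = Tensor(rng.standard_normal((3, 16)))
    out = sc(e, e)  # identical inputs + tied weights -> identical refinements
    assert out["mse"].item() == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(out["f_eeg_refined"].data,
                               out["f_fnirs_refined"].data, atol=1e-12)


def test_scaf_swap_equivariance(rng):
    """With zero positional encoding and tied projections, swapping the two
    inputs swaps the refined features and leaves the fused sum unchanged."""
    sc = _tied_scaf(rng)
    e = Tensor(rng.standard_normal((2, 16)))
    f = Tensor(rng.standard_normal((2, 16)))
    o1 = sc(e, f)
    o2 = sc(f, e)
    np.testing.assert_allclose(o1["f_eeg_refined"].data,
                               o2["f_fnirs_refined"].data, atol=1e-10)
    np.testing.assert_allclose(o1["fused"].data, o2["fused"].data, atol=1e-10)


def test_scaf_attention_rows_and_fused_sum(rng):
    sc = SCAF(d_in=16, rng=rng, d_model=8, n_heads=2)
    out = sc(Tensor(rng.standard_normal((2, 16))),
             Tensor(rng.standard_normal((2, 16))))
    np.testing.assert_allclose(sc.mha.last_weights.sum(axis=-1), 1.0, atol=1e-9)
    np.testing.assert_array_equal(
        out["fused"].data,
        out["f_eeg_refined"].data + out["f_fnirs_refined"].data)


def test_scaf_shape_mismatch_rejected(rng):
    sc = SCAF(d_in=16, rng=rng, d_model=8, n_heads=2)
    with pytest.raises(ValueError):
        sc(Tensor(np.zeros((2, 16))), Tensor(np.zeros((2, 8))))


# ---------------------------------------------------------------------------
# classifier heads and full model
# ---------------------------------------------------------------------------

def test_classifier_shapes_and_uniform_at_zero_weights(rng):
    mc = reduced_model_config(n_classes=3)
    net = BiSTFNet(mc, rng).build((1, 60, 8, 8), (22, 30, 8, 8))
    eeg = Tensor(rng.standard_normal((3, 1, 60, 8, 8)))
    fn = Tensor(rng.standard_normal((3, 22, 30, 8, 8)))
    out = net(eeg, fn)
    assert out["logits_main"].shape == (3, 3)
    assert out["logits_aux"].shape == (3, 3)
    net.head_main.W.data[:] = 0.0
    net.head_main.b.data[:] = 0.0
    probs = net(eeg, fn)["logits_main"].softmax(axis=-1).data
    np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-12)


def test_n_classes_below_two_rejected():
    with pytest.raises(ValueError):
        ModelConfig(n_classes=1)


def test_aux_loss_gradients_do_not_reach_fnirs_branch(rng):
    mc = reduced_model_config(use_bicmg=False)
    net = BiSTFNet(mc, rng).build((1, 60, 8, 8), (22, 30, 8, 8))
    out = net(Tensor(rng.standard_normal((2, 1, 60, 8, 8))),
              Tensor(rng.standard_normal((2, 22, 30, 8, 8))))
    ce_loss_from_logits(np.array([0, 1]), out["logits_aux"]).backward()
    for stage in net.backbone.fnirs_stages:
        assert stage.conv.W.grad is None or np.all(stage.conv.W.grad == 0)
    assert net.seq_encoder.gru.fwd.Wx.grad is None or \
        np.all(net.seq_encoder.gru.fwd.Wx.grad == 0)
    # while the EEG path is live
    assert np.abs(net.backbone.eeg_stages[0].conv.W.grad).max() > 0


@pytest.mark.parametrize("switch", ["use_ata", "use_scaf"])
def test_ablation_switches_preserve_contracts(switch, rng):
    mc = reduced_model_config(**{switch: False})
    net = BiSTFNet(mc, rng).build((1, 60, 8, 8), (22, 30, 8, 8))
    out = net(Tensor(rng.standard_normal((2, 1, 60, 8, 8))),
              Tensor(rng.standard_normal((2, 22, 30, 8, 8))))
    assert out["logits_main"].shape == (2, 2)
    assert out["f_aligned"].shape == (2, mc.d_branch)
    assert np.isfinite(out["logits_main"].data).all()


@pytest.mark.parametrize("branch", ["use_eeg_branch", "use_fnirs_branch"])
def test_single_branch_models_run(branch, rng):
    mc = reduced_model_config(use_bicmg=False, **{branch: False})
    net = BiSTFNet(mc, rng).build((1, 60, 8, 8), (22, 30, 8, 8))
    out = net(Tensor(rng.standard_normal((2, 1, 60, 8, 8))),
              Tensor(rng.standard_normal((2, 22, 30, 8, 8))))
    assert out["logits_main"].shape == (2, 2)
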