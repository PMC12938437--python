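"""Canned desk-scale experiments: lag recovery, capacity check, ablations.

These are the package's reference experiments on its own synthetic data;
the test suite and the acceptance script both run them through this module
so the protocol is defined in exactly one place.

Problem sizes are deliberately small (8-channel montages, 8x8 grids,
envelope-domain EEG at 20 Hz, a handful of trials per class) so a complete
run takes minutes on one CPU while exercising every module end to end.
"""

from __future__ import annotations

import numpy as np

from .align_fuse import BiSTFNet
from .autodiff import Tensor, no_grad
from .presets import (reduced_dataset, reduced_lag_model_config,
                      reduced_model_config)
from .train_eval import (ABLATION_FLAGS, TrainConfig, apply_ablation,
                         train_one_fold)

__all__ = ["lag_recovery_experiment", "overfit_experiment", "ablation_smoke"]

# settings of the reduced lag-recovery experiment: few-sample batches and a
# faster base rate than the full protocol, because the reduced problem has
# only ~100 samples and the attention projections need enough optimizer
# steps inside the 50-epoch budget to break the initial symmetry
LAG_EXPERIMENT = dict(lr_init=3e-3, batch_size=16, epochs=50, patience=50,
                      loss_terms=("main", "pcc"))
LAG_S = 5.0
SNR_DB = 20.0
TASK_ANCHOR_RANGE = (0.0, 7.0)  # anchor offsets fully inside the task period


def lag_recovery_experiment(n_seeds: int = 10, seed0: int = 0,
                            n_trials_per_class: int = 4) -> dict:
    """Train the reduced windows-axis model per seed and read the lag off
    the time-marginal ATA attention.

    Success for a seed = attention argmax within +-1 window of the injected
    lag (5 s -> window index 5).  Returns per-seed peaks and the success
    count.
    """
    peaks = []
    for i in range(n_seeds):
        seed = seed0 + i
        data, _, _ = reduced_dataset(n_trials_per_class=n_trials_per_class,
                                     seed=seed, lag_s=LAG_S, snr_db=SNR_DB)
        model = BiSTFNet(reduced_lag_model_config(),
                         np.random.default_rng(100 + seed))
        cfg = TrainConfig(seed=seed, **LAG_EXPERIMENT)
        train_one_fold(model, data, np.arange(len(data)), [], cfg)
        lo, hi = TASK_ANCHOR_RANGE
        mask = (data.anchor_offsets >= lo) & (data.anchor_offsets <= hi)
        with no_grad():
            model(Tensor(data.eeg[mask]), Tensor(data.fnirs[mask]))
        marginal = model.ata.time_marginal_attention().mean(axis=0)
        peaks.append(int(np.argmax(marginal)))
    target = int(round(LAG_S))
    successes = sum(abs(p - target) <= 1 for p in peaks)
    return {"peaks": peaks, "successes": successes, "n_seeds": n_seeds,
            "target_window": target}


def overfit_experiment(seed: int = 42, n_samples: int = 64,
                       max_epochs: int = 100) -> dict:
    """Capacity check: the reduced full model must reach 100% training
    accuracy on a small separable synthetic sample within `max_epochs`."""
    data, _, _ = reduced_dataset(n_trials_per_class=3, seed=seed,
                                 lag_s=LAG_S, snr_db=SNR_DB)
    idx = np.arange(min(n_samples, len(data)))
    model = BiSTFNet(reduced_model_config(), np.random.default_rng(seed))
    cfg = TrainConfig(epochs=max_epochs, patience=max_epochs, seed=seed,
                      stop_when_train_perfect=True)
    _, hist = train_one_fold(model, data, idx, [], cfg)
    return {"train_accuracy": max(hist.train_acc),
            "epochs_used": hist.stop_epoch + 1, "n_samples": len(idx)}


def ablation_smoke(variant: str, seed: int = 0, epochs: int = 2) -> dict:
    """Train one ablation variant briefly on a tiny fixture and verify the
    input/output contracts hold (finite losses, correct logit shapes)."""
    if variant not in ABLATION_FLAGS:
        raise ValueError(f"unknown ablation {variant!r}")
    mapping = "raster" if variant == "no_spatial_mapping" else "topographic"
    data, _, _ = reduced_dataset(n_trials_per_class=2, seed=seed,
                                 lag_s=LAG_S, snr_db=SNR_DB, mapping=mapping)
    cfg = TrainConfig(epochs=epochs, patience=epochs, seed=seed,
                      ablation=(variant,) if variant != "no_spatial_mapping" else ())
    mc, data = apply_ablation(reduced_model_config(), data, cfg)
    model = BiSTFNet(mc, np.random.default_rng(seed))
    _, hist = train_one_fold(model, data, np.arange(len(data)), [], cfg)
    out_ok = all(np.isfinite(list(h.values())).all() for h in hist.loss if h)
    with no_grad():
        out = model(Tensor(data.eeg[:4]), Tensor(data.fnirs[:4]))
    return {"variant": variant, "losses_finite": bool(out_ok),
            "logits_shape": tuple(out["logits_main"].shape),
            "epochs": len(hist.train_acc)}
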