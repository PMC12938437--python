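"""Reduced-scale presets for desk-scale (single-CPU) experiments.

The full-resolution pipeline (16x16 grids, 600-deep EEG tensors, the
printed stage schedules) is the package default.  The presets here shrink
the spatial grid, the EEG temporal depth and the channel widths so that a
complete train/evaluate cycle runs in seconds on one CPU while every module
(backbone, Bi-CMG, ATA, SCAF, joint loss) keeps its exact structure.
"""

from __future__ import annotations

import numpy as np

from .align_fuse import ModelConfig
from .backbone import StageSpec
from .preprocess import build_samples
from .synthgen import SimulationConfig, make_montage, simulate_session

__all__ = ["reduced_model_config", "reduced_lag_model_config",
           "reduced_dataset"]

REDUCED_GRID = 8
REDUCED_EEG_FS = 20.0  # -> EEG tensor depth 60 for a 3-s anchor


def reduced_model_config(n_classes: int = 2, **overrides) -> ModelConfig:
    """Reduced full-architecture model for 8x8 grids and depth-60 EEG."""
    kwargs = dict(
        n_classes=n_classes,
        eeg_stages=(StageSpec(1, 8, stride=(2, 2, 2)),      # 60,8,8 -> 30,4,4
                    StageSpec(8, 16, stride=(3, 2, 2))),    # -> 10,2,2
        fnirs_stages=(StageSpec(22, 16, stride=(3, 2, 2)),  # 30,8,8 -> 10,4,4
                      StageSpec(16, 16, stride=(3, 2, 2), padding=(2, 1, 1))),
        d_branch=64, gru_hidden=32, gru_proj=32, d_fuse=32,
        bicmg_pool=(2, 2, 2),
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def reduced_lag_model_config(n_classes: int = 2, **overrides) -> ModelConfig:
    """Reduced model whose ATA sequence axis is the 11 candidate windows, so
    the attention map is directly indexed by hemodynamic lag (seconds)."""
    kwargs = dict(
        n_classes=n_classes,
        eeg_stages=(StageSpec(1, 8, stride=(2, 2, 2)),
                    StageSpec(8, 16, stride=(3, 2, 2))),
        # per-window encoder: normalization off so relative response
        # amplitude across the 11 windows (the lag cue) is preserved
        fnirs_stages=(StageSpec(2, 8, stride=(2, 2, 2), norm=False),  # 30,8,8 -> 15,4,4
                      StageSpec(8, 8, stride=(2, 2, 2), norm=False)),  # -> 8,2,2
        d_branch=64, gru_hidden=32, gru_proj=32, d_fuse=32,
        ata_axis="windows", ata_use_gru=False, use_bicmg=False,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def reduced_dataset(n_trials_per_class: int = 4, seed: int = 0,
                    lag_s: float = 5.0, snr_db: float = 20.0,
                    n_eeg: int = 8, n_fnirs: int = 8,
                    mapping: str = "topographic"):
    """Simulate a session at the generator's default trial structure and
    build reduced-resolution samples (8x8 grid, EEG at 20 Hz)."""
    cfg = SimulationConfig(n_trials_per_class=n_trials_per_class, seed=seed,
                           lag_s=lag_s, snr_db=snr_db)
    montages = make_montage(n_eeg, n_fnirs, seed=seed)
    pair = simulate_session(cfg, montages)
    data = build_samples(pair, grid_size=REDUCED_GRID, mapping=mapping,
                         eeg_fs_out=REDUCED_EEG_FS)
    return data, cfg, pair
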