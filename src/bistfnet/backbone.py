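"""Hierarchical 3-D CNN backbones with bidirectional cross-modal guidance.

Each modality has its own stack of strided 3-D convolution stages; after
every stage a Bi-CMG (bidirectional cross-modal guidance) unit lets the two
feature streams exchange spatial information through an efficient
cross-attention over low-resolution surrogate tokens:

* both blocks are adaptively average-pooled to a small token grid,
* tokens are layer-normalized and projected to the 64-d attention space,
* multi-head cross-attention (4 heads, d_k = 16, scale 1/sqrt(16)) queries
  one modality with the other's keys/values, in both directions,
* the guidance is projected back to the block's channel width, trilinearly
  upsampled to the original (D, H, W) resolution and added residually.

The attention output projection is zero-initialized, so at initialization
every Bi-CMG unit is exactly the identity and training starts from the
unguided backbone.

Default stage schedules reproduce the stage-2 feature-block contract:
EEG [B,1,600,16,16] -> [B,16,50,4,4]; fNIRS [B,22,30,16,16] -> [B,16,4,4,4].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import (AdaptiveAvgPool3d, Conv3d, ChannelNorm, LayerNorm, Linear,
                 Module, MultiheadAttention, trilinear_resize)

__all__ = ["StageSpec", "EEG_STAGES", "FNIRS_STAGES", "ConvStage", "BiCMG",
           "DualBackbone", "multihead_cross_attention", "AttentionParams"]


@dataclass(frozen=True)
class AttentionParams:
    d_model: int = 64
    n_heads: int = 4

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass(frozen=True)
class StageSpec:
    in_ch: int
    out_ch: int
    kernel: tuple = (3, 3, 3)
    stride: tuple = (2, 2, 2)
    padding: tuple = (1, 1, 1)
    norm: bool = True  # False when per-item normalization would erase the
    #                    across-item amplitude structure (per-window encoding)


# stage schedules hitting the printed stage-2 shapes
EEG_STAGES = (
    StageSpec(1, 8, stride=(4, 2, 2)),                     # 600,16,16 -> 150,8,8
    StageSpec(8, 16, stride=(3, 2, 2)),                    # 150,8,8  -> 50,4,4
)
FNIRS_STAGES = (
    StageSpec(22, 16, stride=(3, 2, 2)),                   # 30,16,16 -> 10,8,8
    StageSpec(16, 16, stride=(3, 2, 2), padding=(2, 1, 1)),  # 10,8,8 -> 4,4,4
)


class ConvStage(Module):
    """Strided 3-D convolution + per-channel normalization + ReLU."""

    def __init__(self, spec: StageSpec, rng: np.random.Generator):
        self.spec = spec
        self.conv = Conv3d(spec.in_ch, spec.out_ch, spec.kernel, spec.stride,
                           spec.padding, rng)
        self.norm = ChannelNorm(spec.out_ch) if spec.norm else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_ch:
            raise ValueError(f"expected {self.spec.in_ch} input channels, got {x.shape[1]}")
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        return y.relu()


def multihead_cross_attention(q: Tensor, k: Tensor, v: Tensor,
                              mha: MultiheadAttention) -> Tensor:
    """Functional multi-head cross-attention contract (B,N,d) x (B,M,d)."""
    if q.shape[1] == 0 or k.shape[1] == 0:
        raise ValueError("empty token sequence")
    return mha(q, k, v)


class _GuidanceBranch(Module):
    """One direction of Bi-CMG: tokens of `src` guide the `dst` block."""

    def __init__(self, dst_ch: int, src_ch: int, pool: tuple, params: AttentionParams,
                 rng: np.random.Generator):
        d = params.d_model
        self.pool = AdaptiveAvgPool3d(pool)
        self.pool_sizes = pool
        self.ln_q = LayerNorm(dst_ch)
        self.ln_kv = LayerNorm(src_ch)
        self.q_proj = Linear(dst_ch, d, rng)
        self.k_proj = Linear(src_ch, d, rng)
        self.v_proj = Linear(src_ch, d, rng)
        self.mha = MultiheadAttention(d, params.n_heads, rng, project_kv=False,
                                      zero_init_out=True)
        self.back_proj = Linear(d, dst_ch, rng)

    def _tokens(self, block: Tensor, ln: LayerNorm) -> Tensor:
        pooled = self.pool(block)                  # B,C,d,h,w
        B, C = pooled.shape[:2]
        n = int(np.prod(pooled.shape[2:]))
        toks = pooled.reshape(B, C, n).transpose(0, 2, 1)  # B,N,C
        return ln(toks)

    def forward(self, dst: Tensor, src: Tensor) -> Tensor:
        q = self.q_proj(self._tokens(dst, self.ln_q))
        kv = self._tokens(src, self.ln_kv)
        k, v = self.k_proj(kv), self.v_proj(kv)
        guid = multihead_cross_attention(q, k, v, self.mha)   # B,N,64
        guid = self.back_proj(guid)                           # B,N,C_dst
        B = dst.shape[0]
        pd, ph, pw = self.pool_sizes
        guid = guid.transpose(0, 2, 1).reshape(B, dst.shape[1], pd, ph, pw)
        up = trilinear_resize(guid, dst.shape[2:])
        return dst + up  # residual


class BiCMG(Module):
    """Bidirectional cross-modal guidance between same-stage feature blocks."""

    def __init__(self, eeg_ch: int, fnirs_ch: int, rng: np.random.Generator,
                 pool: tuple = (4, 4, 4), params: AttentionParams = AttentionParams()):
        self.eeg_from_fnirs = _GuidanceBranch(eeg_ch, fnirs_ch, pool, params, rng)
        self.fnirs_from_eeg = _GuidanceBranch(fnirs_ch, eeg_ch, pool, params, rng)

    def forward(self, f_eeg: Tensor, f_fnirs: Tensor) -> tuple:
        if f_eeg.shape[0] != f_fnirs.shape[0]:
            raise ValueError("batch sizes differ between modalities")
        return (self.eeg_from_fnirs(f_eeg, f_fnirs),
                self.fnirs_from_eeg(f_fnirs, f_eeg))


class DualBackbone(Module):
    """Two modality-specific conv stacks with a Bi-CMG unit after each stage."""

    def __init__(self, rng: np.random.Generator,
                 eeg_stages=EEG_STAGES, fnirs_stages=FNIRS_STAGES,
                 bicmg_pool: tuple = (4, 4, 4), use_bicmg: bool = True):
        if len(eeg_stages) != len(fnirs_stages):
            raise ValueError("stage schedules must have equal depth")
        self.eeg_stages = [ConvStage(s, rng) for s in eeg_stages]
        self.fnirs_stages = [ConvStage(s, rng) for s in fnirs_stages]
        self.use_bicmg = use_bicmg
        self.bicmg_units = [
            BiCMG(e.out_ch, f.out_ch, rng, pool=bicmg_pool)
            for e, f in zip(eeg_stages, fnirs_stages)
        ]

    def forward(self, eeg: Tensor, fnirs: Tensor) -> tuple:
        for stage_e, stage_f, cmg in zip(self.eeg_stages, self.fnirs_stages,
                                         self.bicmg_units):
            eeg, fnirs = stage_e(eeg), stage_f(fnirs)
            if self.use_bicmg:
                eeg, fnirs = cmg(eeg, fnirs)
        return eeg, fnirs
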