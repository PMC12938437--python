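"""Temporal alignment (ATA), symmetric fusion (SCAF) and classifier heads.

ATA — adaptive temporal alignment.  The stage-2 fNIRS feature block is
treated as a temporal sequence and encoded by a bidirectional GRU into
H in R^{B x T x 256}.  The EEG block is globally average-pooled over the
spatial axes only (never time), linearly projected into one 256-d query per
EEG time step, and multi-head cross-attention against H (H serving as key
and value, optionally through learned projections) retrieves lag-appropriate
fNIRS information.  The per-step contexts are mean-pooled over EEG time,
passed through a residual connection with the query summary and layer
normalization, yielding the aligned fNIRS feature F'_fNIRS in R^{B x 256}.
A Pearson-correlation loss between the query summary and F'_fNIRS
supervises the alignment.

SCAF — symmetric cross-attention fusion.  The projected EEG feature and the
aligned fNIRS feature are each mapped to 64-d tokens, concatenated into a
length-2 sequence, given a learned positional encoding, and passed through
one standard transformer encoder block (multi-head self-attention, then a
position-wise FFN, each followed by residual + layer norm).  The two output
tokens are refined by separate linear layers; an MSE consistency loss pulls
the refined features together, and their element-wise sum is the fused
feature driving the main classifier.  An auxiliary classifier sees only the
EEG branch feature.

The sequence axis over which ATA attends is configurable: ``"depth"``
attends over the stage-2 fNIRS temporal depth (T = 4, the literal
architecture), while ``"windows"`` attends over the 11 hemodynamic candidate
windows encoded by a shared per-window convolutional encoder — the variant
in which the attention map directly exposes the neurovascular lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .backbone import (AttentionParams, ConvStage, DualBackbone, EEG_STAGES,
                       FNIRS_STAGES, StageSpec)
from .nn import BiGRU, LayerNorm, Linear, Module, MultiheadAttention, Parameter

__all__ = ["ModelConfig", "FNIRSSequenceEncoder", "ATA", "SCAF", "pcc_loss",
           "BiSTFNet"]

EPS_PCC = 1e-8


def pcc_loss(q: Tensor, f: Tensor) -> Tensor:
    """Negative mean Pearson correlation across features, per batch row.

    Returns a scalar in [-1, 1]; -1 means perfectly (positively) linearly
    related query and aligned-feature vectors.
    """
    qc = q - q.mean(axis=1, keepdims=True)
    fc = f - f.mean(axis=1, keepdims=True)
    cov = (qc * fc).mean(axis=1)
    sq = (qc * qc).mean(axis=1).sqrt()
    sf = (fc * fc).mean(axis=1).sqrt()
    r = cov / (sq * sf + EPS_PCC)
    return -r.mean()


class FNIRSSequenceEncoder(Module):
    """Flatten each sequence step of a feature block and encode with a Bi-GRU."""

    def __init__(self, step_features: int, rng: np.random.Generator,
                 proj_dim: int = 128, hidden: int = 128):
        self.proj = Linear(step_features, proj_dim, rng)
        self.gru = BiGRU(proj_dim, hidden, rng)

    def forward(self, steps: Tensor) -> Tensor:
        """steps: (B, T, F) -> H: (B, T, 2*hidden)."""
        if steps.shape[1] < 1:
            raise ValueError("sequence must have at least one step")
        return self.gru(self.proj(steps))


class ATA(Module):
    """Adaptive temporal alignment of an encoded fNIRS sequence to EEG anchors."""

    def __init__(self, eeg_ch: int, d_model: int, rng: np.random.Generator,
                 n_heads: int = 4, project_kv: bool = True):
        self.q_proj = Linear(eeg_ch, d_model, rng)
        self.mha = MultiheadAttention(d_model, n_heads, rng, project_kv=project_kv)
        self.ln = LayerNorm(d_model)
        self.last_attention: np.ndarray | None = None

    def queries(self, eeg_block: Tensor) -> Tensor:
        """GAP over spatial dims only -> one query per EEG time step (B,T,d)."""
        pooled = eeg_block.mean(axis=(3, 4))          # B, C, T_e
        return self.q_proj(pooled.transpose(0, 2, 1))  # B, T_e, d

    def forward(self, eeg_block: Tensor, h: Tensor) -> tuple:
        """Returns (aligned feature (B, d), query summary (B, d),
        pre-residual attention context (B, d)).

        The context — the direct output of the attention computation — is the
        quantity the correlation loss supervises; routing the loss through
        the residual connection would let the query correlate with itself and
        remove all training pressure from the attention weights.
        """
        if eeg_block.shape[0] != h.shape[0]:
            raise ValueError("batch sizes differ")
        q = self.queries(eeg_block)
        if q.shape[-1] != h.shape[-1]:
            raise ValueError("query/key dimension mismatch")
        ctx = self.mha(q, h, h)                       # B, T_e, d
        self.last_attention = self.mha.last_weights   # B, heads, T_e, T
        q_summary = q.mean(axis=1)                    # B, d
        ctx_mean = ctx.mean(axis=1)
        aligned = self.ln(ctx_mean + q_summary)
        return aligned, q_summary, ctx_mean

    def time_marginal_attention(self) -> np.ndarray:
        """Mean attention mass per fNIRS sequence step (B, T)."""
        if self.last_attention is None:
            raise RuntimeError("no forward pass recorded")
        return self.last_attention.mean(axis=(1, 2))

    def export_attention_csv(self, path) -> None:
        """Diagnostic dump of the last per-sample time-marginal attention."""
        np.savetxt(path, self.time_marginal_attention(), delimiter=",",
                   fmt="%.6f")


class SCAF(Module):
    """Symmetric cross-attention fusion of the two 256-d branch features."""

    def __init__(self, d_in: int, rng: np.random.Generator, d_model: int = 64,
                 n_heads: int = 4, ffn_mult: int = 4):
        self.eeg_in = Linear(d_in, d_model, rng)
        self.fnirs_in = Linear(d_in, d_model, rng)
        self.pos = Parameter(np.zeros((1, 2, d_model)))
        self.mha = MultiheadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_mult * d_model, rng)
        self.ffn2 = Linear(ffn_mult * d_model, d_model, rng)
        self.refine_eeg = Linear(d_model, d_model, rng)
        self.refine_fnirs = Linear(d_model, d_model, rng)
        self.d_model = d_model

    def forward(self, e: Tensor, f: Tensor) -> dict:
        if e.shape != f.shape:
            raise ValueError("branch features must share shape (B, d)")
        B = e.shape[0]
        x = concat([self.eeg_in(e).reshape(B, 1, self.d_model),
                    self.fnirs_in(f).reshape(B, 1, self.d_model)], axis=1)
        x = x + self.pos
        x1 = self.ln1(x + self.mha(x, x, x))
        x2 = self.ln2(x1 + self.ffn2(self.ffn1(x1).relu()))
        fe = self.refine_eeg(x2[:, 0, :])
        ff = self.refine_fnirs(x2[:, 1, :])
        mse = ((fe - ff) ** 2).mean()
        return {"f_eeg_refined": fe, "f_fnirs_refined": ff,
                "fused": fe + ff, "mse": mse}


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    n_classes: int = 2
    eeg_stages: tuple = EEG_STAGES
    fnirs_stages: tuple = FNIRS_STAGES
    d_branch: int = 256          # branch feature width (queries, GRU output)
    gru_hidden: int = 128        # per direction; 2*gru_hidden must equal d_branch
    gru_proj: int = 128
    d_fuse: int = 64
    ata_heads: int = 4
    scaf_heads: int = 4
    ffn_mult: int = 4
    ata_project_kv: bool = True
    ata_axis: str = "depth"      # "depth" | "windows"
    ata_use_gru: bool = True     # False: window-local projection instead of a
    #                              Bi-GRU, keeping the attention map indexed
    #                              by physical window position (lag readout)
    bicmg_pool: tuple = (4, 4, 4)
    # ablation switches
    use_bicmg: bool = True
    use_ata: bool = True
    use_scaf: bool = True
    use_eeg_branch: bool = True
    use_fnirs_branch: bool = True

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if 2 * self.gru_hidden != self.d_branch:
            raise ValueError("d_branch must equal 2 * gru_hidden")
        if self.ata_axis not in ("depth", "windows"):
            raise ValueError("ata_axis must be 'depth' or 'windows'")
        if self.ata_axis == "windows" and self.use_bicmg:
            raise ValueError("per-window encoding is incompatible with Bi-CMG; "
                             "set use_bicmg=False")
        if not (self.use_eeg_branch or self.use_fnirs_branch):
            raise ValueError("at least one modality branch must be active")


class BiSTFNet(Module):
    """Decoupled bidirectional spatio-temporal fusion network.

    forward(eeg, fnirs) -> dict with logits and every intermediate needed by
    the joint loss: ``logits_main``, ``logits_aux``, ``q_summary``,
    ``f_aligned``, ``mse``, ``fused``.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = c = config
        self.backbone = DualBackbone(rng, c.eeg_stages, c.fnirs_stages,
                                     bicmg_pool=c.bicmg_pool, use_bicmg=c.use_bicmg)
        eeg_ch = c.eeg_stages[-1].out_ch
        f_ch = c.fnirs_stages[-1].out_ch
        if c.ata_axis == "windows":
            # shared per-window conv encoder: step feature = C * pooled depth
            self._win_in_ch = c.fnirs_stages[0].in_ch
            step_feat = None  # resolved lazily from the first forward
        self.ata = ATA(eeg_ch, c.d_branch, rng, n_heads=c.ata_heads,
                       project_kv=c.ata_project_kv)
        self._rng_state = rng  # kept only for lazy construction
        self.seq_encoder = None
        self._step_feat = None
        self.eeg_feat_proj = Linear(c.d_branch, c.d_branch, rng)
        self.scaf = SCAF(c.d_branch, rng, d_model=c.d_fuse,
                         n_heads=c.scaf_heads, ffn_mult=c.ffn_mult)
        self.concat_fuse = Linear(2 * c.d_fuse, c.d_fuse, rng)  # "w/o SCAF" path
        self.eeg_only_proj = Linear(c.d_branch, c.d_fuse, rng)
        self.fnirs_only_proj = Linear(c.d_branch, c.d_fuse, rng)
        self.head_main = Linear(c.d_fuse, c.n_classes, rng)
        self.head_aux = Linear(c.d_branch, c.n_classes, rng)

    def build(self, eeg_shape, fnirs_shape) -> "BiSTFNet":
        """Materialize lazily-shaped sub-modules with one dummy forward pass,
        so ``parameters()`` is complete before an optimizer is created."""
        from .autodiff import no_grad
        with no_grad():
            self.forward(Tensor(np.zeros((1,) + tuple(eeg_shape))),
                         Tensor(np.zeros((1,) + tuple(fnirs_shape))))
        return self

    # -- fNIRS sequence construction ---------------------------------------
    def _ensure_seq_encoder(self, step_feat: int):
        if self.seq_encoder is None:
            if self.config.ata_use_gru:
                self.seq_encoder = FNIRSSequenceEncoder(
                    step_feat, self._rng_state, proj_dim=self.config.gru_proj,
                    hidden=self.config.gru_hidden)
            else:
                self.seq_encoder = Linear(step_feat, self.config.d_branch,
                                          self._rng_state)
            self._step_feat = step_feat
        elif step_feat != self._step_feat:
            raise ValueError("fNIRS step feature size changed between calls")

    def _fnirs_sequence_depth(self, f_block: Tensor) -> Tensor:
        """Stage-2 block (B,C,T,h,w): depth axis as sequence, steps flattened."""
        B, C, T = f_block.shape[:3]
        steps = f_block.transpose(0, 2, 1, 3, 4).reshape(
            B, T, C * f_block.shape[3] * f_block.shape[4])
        self._ensure_seq_encoder(steps.shape[-1])
        return self.seq_encoder(steps)

    def _fnirs_sequence_windows(self, fnirs: Tensor) -> Tensor:
        """4-D input (B, 2*W, T, G, G): encode each 3-s candidate window with
        the shared conv stack; the window axis is the ATA sequence."""
        B, C2 = fnirs.shape[:2]
        n_w = C2 // 2
        x = fnirs.reshape(B, n_w, 2, *fnirs.shape[2:]).reshape(
            B * n_w, 2, *fnirs.shape[2:])
        for stage in self.backbone.fnirs_stages:
            x = stage(x)
        x = x.mean(axis=(3, 4))                       # (B*W, C, d)
        feat = x.reshape(B, n_w, x.shape[1] * x.shape[2])
        self._ensure_seq_encoder(feat.shape[-1])
        return self.seq_encoder(feat)

    # -- forward ------------------------------------------------------------
    def forward(self, eeg: Tensor, fnirs: Tensor) -> dict:
        c = self.config
        out: dict = {"q_summary": None, "f_aligned": None, "f_context": None,
                     "mse": None, "logits_aux": None}

        if c.ata_axis == "windows":
            if c.use_eeg_branch:
                e_block = eeg
                for stage in self.backbone.eeg_stages:
                    e_block = stage(e_block)
            h = self._fnirs_sequence_windows(fnirs) if c.use_fnirs_branch else None
        else:
            if c.use_eeg_branch and c.use_fnirs_branch:
                e_block, f_block = self.backbone(eeg, fnirs)
            elif c.use_eeg_branch:
                e_block = eeg
                for stage in self.backbone.eeg_stages:
                    e_block = stage(e_block)
                f_block = None
            else:
                f_block = fnirs
                for stage in self.backbone.fnirs_stages:
                    f_block = stage(f_block)
            h = self._fnirs_sequence_depth(f_block) if c.use_fnirs_branch else None

        if c.use_eeg_branch:
            q_all = self.ata.queries(e_block)
            q_summary = q_all.mean(axis=1)
            e_feat = self.eeg_feat_proj(q_summary)
            out["q_summary"] = q_summary
            out["logits_aux"] = self.head_aux(e_feat)

        # single-branch ablations
        if not c.use_fnirs_branch:
            fused = self.eeg_only_proj(e_feat)
            out.update(fused=fused, logits_main=self.head_main(fused))
            return out
        if not c.use_eeg_branch:
            f_feat = self.ata.ln(h.mean(axis=1))
            fused = self.fnirs_only_proj(f_feat)
            out.update(f_aligned=f_feat, fused=fused,
                       logits_main=self.head_main(fused))
            return out

        # alignment
        if c.use_ata:
            f_aligned, _, ctx_mean = self.ata(e_block, h)
            out["f_context"] = ctx_mean
        else:
            f_aligned = self.ata.ln(h.mean(axis=1))  # unweighted temporal mean
            out["f_context"] = None
        out["f_aligned"] = f_aligned

        # fusion
        if c.use_scaf:
            sc = self.scaf(e_feat, f_aligned)
            out.update(mse=sc["mse"], fused=sc["fused"],
                       f_eeg_refined=sc["f_eeg_refined"],
                       f_fnirs_refined=sc["f_fnirs_refined"])
        else:
            e64 = self.scaf.eeg_in(e_feat)
            f64 = self.scaf.fnirs_in(f_aligned)
            fused = self.concat_fuse(concat([e64, f64], axis=1))
            out["fused"] = fused
        out["logits_main"] = self.head_main(out["fused"])
        return out
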