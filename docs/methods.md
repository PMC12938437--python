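# Methods

## The model

BiSTF-Net decouples the two mismatches of hybrid EEG-fNIRS classification
and addresses each with a dedicated mechanism.

**Spatial fusion (Bi-CMG).** Both modalities are rendered as topographic
movies — each time point interpolated onto a 16 × 16 scalp grid — and
processed by modality-specific 3-D CNNs. After each conv stage a
bidirectional cross-modal guidance unit pools both feature blocks to a small
token grid (4 × 4 × 4 by default, N = 64 tokens), layer-normalizes and
projects the tokens to a 64-d attention space, and runs multi-head
cross-attention (4 heads, d_k = 16, scale 1/√16) in both directions: EEG
tokens query fNIRS keys/values and vice versa. Guidance is projected back to
the block's channel width, trilinearly upsampled to the block's full
(D, H, W) resolution, and added residually. The attention output projection
is zero-initialized, so at initialization the unit is exactly the identity
and optimization starts from the unguided backbone.

**Temporal alignment (ATA).** The stage-2 fNIRS block's depth axis is
encoded as a sequence by a bidirectional GRU (hidden 128/direction →
256-d steps). The EEG block is average-pooled over space only — never
time — so each EEG time step yields one 256-d query after linear
projection. Multi-head cross-attention (4 heads) retrieves a context per
EEG time step; contexts are mean-pooled over EEG time, passed through a
residual connection with the mean query and layer normalization, giving the
aligned fNIRS feature (B × 256). A Pearson-correlation loss
(ε = 1e-8 in the denominators) couples the mean query with the attention
context, pushing the attention toward fNIRS positions that co-vary with the
EEG.

The correlation loss deliberately supervises the *pre-residual* attention
context. Supervising the post-residual feature would let the query
correlate with its own residual copy and remove all training pressure from
the attention weights; the identity of the aligned feature (context +
query, normalized) is unchanged.

**Fusion (SCAF).** The projected EEG feature and the aligned fNIRS feature
are mapped to 64-d tokens, concatenated into a length-2 sequence, offset by
a learned positional encoding, and passed through one standard transformer
encoder block (multi-head self-attention, then a position-wise FFN of inner
width 4 × 64 = 256, each sub-layer with residual + layer norm). The two
output tokens are refined by separate linear layers; an MSE loss pulls the
refined features together and their element-wise sum is the fused feature.
The main classifier sees only the fused feature; an auxiliary classifier
sees only the EEG branch feature and regularizes that branch.

**Objective.** `L = w₁·L_main + w₂·L_aux + w₃·L_PCC + w₄(t)·L_MSE` with
w₁ = 2.0, w₂ = 1.0, w₃ = 0.2 fixed and w₄ ramped linearly 0 → 1 over the
first 50 epochs (consistency pressure is introduced only once the
classifier has taken shape). Training: AdamW (weight decay 1e-2), cosine
annealing 5e-4 → 1e-6 over 200 epochs, batch 64, early stopping after 30
epochs without validation improvement, fully seeded.

## Input construction

EEG: resample to 200 Hz, 50 Hz notch, 0.5–50 Hz Butterworth order 6,
common-average reference. fNIRS: resample to 10 Hz, modified Beer–Lambert
law (log base 10, extinction coefficients at 760/850 nm in 1/(mM·cm),
per-channel 2 × 2 solve), 0.01–0.1 Hz Butterworth order 6. All filtering is
zero-phase (forward–backward); the quoted orders are the design orders, so
the effective magnitude response is |H|². The 0.01 Hz edge implies impulse
responses lasting minutes; filtering pads reflectively for 100 s to tame
edge transients.

Trials are cut to 15 s of EEG (5 s pre / 10 s post task onset; 3000
samples) and 27 s of fNIRS (5 s pre / 22 s post; 270 samples), then
baseline-corrected against the [0, +3] s interval. That interval is
labelled a "pre-task reference" in common protocol descriptions even though
it sits after the onset; both readings are supported
(`baseline_correct(..., interval_s=...)`), the literal [0, +3] s being the
default. A 3-s window sliding by 1 s augments each trial into 13 anchors;
anchors inherit the trial id so cross-validation can fold whole trials. For
each anchor, 11 overlapping 3-s fNIRS windows starting 0..10 s after the
anchor onset form the hemodynamic search space — the only registration that
covers the typical 4–6 s latency symmetrically while every window stays
inside the 27-s trial for every anchor.

Grid mapping is Clough–Tocher (piecewise-cubic) interpolation inside the
sensor convex hull and nearest-neighbour fill outside, over the
[-1, 1]² square at 16 × 16 resolution. Because the map is linear in the
channel values, it is precomputed once per montage as a
(256 × n_channels) matrix; assembly of a tensor is then a single matrix
product. The fNIRS 5-D tensor [11 × 16 × 16 × 30 × 2] collapses to the
4-D input [22 × 30 × 16 × 16] in window-major, chromophore-minor order
(w0·HbO, w0·HbR, w1·HbO, ...), a fixed documented constant. Each sample
tensor is z-scored to mean 0 / sd 1 (input scaling is otherwise
unconstrained, and standardization keeps optimization stable across the µV
and molar scales); the raw assembly functions preserve physical units.

The backbone stage schedules are chosen to hit the stage-2 feature-block
contract: EEG [1, 600, 16, 16] → [16, 50, 4, 4] (temporal strides 4·3,
spatial 2·2), fNIRS [22, 30, 16, 16] → [16, 4, 4, 4] (temporal strides 3·3
with padding, spatial 2·2). Two stages per modality; channel widths
1→8→16 and 22→16→16. A printed-shape ambiguity exists in descriptions of
this architecture (both modalities quoted with depth 50 where the fNIRS
depth must be 4 for the Bi-GRU over depth); this implementation uses
EEG depth 50 / fNIRS depth 4.

## The synthetic generator

The generator is the package's ground-truth instrument; it emulates:

- the trial protocol (2-s cue, 10-s task, 15–17 s jittered rest, plus
  10 s / 30 s session padding);
- class structure: disjoint class-specific EEG channel groups carry
  8–30 Hz band-limited oscillations during task, gated by a smooth
  envelope with per-trial amplitude (0.7–1.3) and infra-slow
  waxing/waning (depth 0.5 at 0.05–0.12 Hz). The infra-slow modulation
  mirrors the documented sub-0.1 Hz fluctuation of cortical band-power
  envelopes, and it is what keeps the hemodynamic lag identifiable at the
  3-s-window scale: only sub-0.1 Hz envelope structure survives the HRF
  low-pass;
- neurovascular coupling: per class, the mean envelope of the active
  channels, downsampled to 10 Hz and convolved with a canonical
  double-gamma HRF (gamma-density difference, peak 5 s, undershoot 15 s,
  positive lobe normalized to unit sum), drives HbO on fNIRS channels
  weighted by a Gaussian spatial kernel (σ = 0.3) around the active EEG
  positions. The kernel is applied *peak-aligned*: the convolution output
  is shifted back by the kernel's own peak latency, so `lag_s` is the net
  envelope→HbO peak delay — the quantity an estimator recovers, with
  lag_s = 0 meaning instantaneous coupling;
- HbR = −0.4 × HbO plus independent noise (the standard anti-correlation
  stylization), sinusoidal drift at 0.005–0.02 Hz, and white noise at the
  configured SNR (defined against task-period signal RMS) on both
  modalities.

What it does **not** emulate: volume conduction and realistic forward
models, motion and ocular artifacts, non-stationary noise, short-channel
physiology, inter-subject variability. Passing tests therefore show that
the pipeline recovers structure *that is present by construction*; they do
not certify performance on real recordings.

`estimate_lag` is a matched filter: it cross-correlates the HRF-convolved
envelope (the zero-lag hemodynamic prediction) with responsive-channel HbO.
By symmetry of the autocorrelation its argmax sits exactly at the injected
lag; a *plain* envelope-HbO cross-correlation instead inherits a ~0.5 s
bias from the asymmetric HRF smoothing, which the tests document.

## Reduced-scale experiments

Desk-scale presets (`bistfnet.presets`) shrink the grid to 8 × 8, the EEG
depth to 60 and channel widths by ~4× so a train/evaluate cycle takes
seconds on one CPU. Below 100 Hz plain decimation would alias the 8–30 Hz
oscillations away, so reduced datasets use the envelope-domain EEG
(|Hilbert| before decimation to 20 Hz), which carries the same class and
timing information at low rates.

Two protocol tensions deserve explicit record:

- **Lag readout.** In the literal architecture the ATA sequence axis is the
  stage-2 fNIRS *depth* (T = 4, within-window time after the 11 candidate
  windows were folded into input channels), so its attention cannot be
  indexed by lag. The reduced lag-recovery model therefore runs ATA over
  the 11 candidate windows (`ata_axis="windows"`), encoding each window
  with a shared conv encoder. Two choices there are load-bearing: the
  per-window encoder uses no per-window normalization (it would erase the
  across-window amplitude differences that carry the lag), and the window
  features are projected directly rather than re-encoded by the Bi-GRU
  (`ata_use_gru=False`), because a trained recurrent encoder can relocate
  content across positions and decouple the attention map from physical
  window position.
- **Experiment scale.** The reduced lag experiment (~100 samples) uses
  batch 16 and base rate 3e-3 within its 50-epoch budget; the full
  protocol's batch 64 / 5e-4 would give only ~100 optimizer steps, too few
  for the attention scores to break their initial symmetry.

Under these conditions (lag 5 s, 20 dB SNR, 10 seeds) the trained
attention peaks at the injected lag ± 1 window on 9/10 seeds, with the
peak sometimes at 6 s — the rightward pull of the asymmetric HRF tail.

## Numerical choices

- Double precision throughout; gradients of every layer are verified
  against central finite differences.
- Softmax/log-softmax computed with max-subtraction; cross-entropy clamps
  logs at 1e-12; Pearson denominators carry ε = 1e-8.
- Macro metrics use the zero-division → 0 convention for classes never
  predicted (conservative); fold metrics are averaged per fold, then over
  folds.
- Fold construction is per-class shuffle + round-robin deal, giving class
  counts within one trial of proportionality per fold; validation trials
  (10%, stratified, at least one per class) are carved from the training
  trials only — early stopping never sees the test fold.
- Checkpoint selection: highest validation accuracy, earliest epoch on
  ties.

## Known limitations

- CPU-bound numpy training limits practical problem sizes; the full-size
  tensors run forward/backward but full-protocol training at batch 64 over
  200 epochs is out of desk-scale reach by design.
- The Clough–Tocher interpolation is permutation-invariant only to its
  internal gradient-solver tolerance (~1e-6 relative).
- The generator's linear, stationary neurovascular coupling is a
  stylization; real coupling is nonlinear and non-stationary.
- `read_snirf` covers the minimal processed-concentration SNIRF layout the
  package writes, not the full standard.
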