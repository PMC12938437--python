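"""From a raw paired recording to model-input tensors.

Shows the full preprocessing chain: band filtering per modality, trial
segmentation (15-s EEG / 27-s fNIRS windows), baseline correction, 3-s
sliding-window augmentation, the 11-window hemodynamic search space, and
topographic 16x16 grid mapping.
"""

from bistfnet import (SimulationConfig, build_samples, make_montage,
                      simulate_session)

config = SimulationConfig(n_trials_per_class=2, seed=1)
pair = simulate_session(config, make_montage(30, 36, seed=1))
data = build_samples(pair)

print(f"trials: {len(pair.events)}  ->  samples: {len(data)} "
      f"(13 sliding anchors per trial)")
print(f"EEG sample tensor:   {data.eeg.shape[1:]}  "
      "(1 channel x 600 time points x 16 x 16 grid)")
print(f"fNIRS sample tensor: {data.fnirs.shape[1:]}  "
      "(11 windows x 2 chromophores = 22 channels, 30 time points each)")
print(f"labels: {sorted(set(data.labels.tolist()))}, "
      f"trial ids keep windows fold-safe: {sorted(set(data.trial_ids.tolist()))}")
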