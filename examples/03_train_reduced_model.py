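"""Train a reduced-scale model end to end and evaluate it.

Uses the desk-scale presets (8x8 grids, envelope-domain EEG at 20 Hz,
narrow channel widths) so a full train/evaluate cycle takes well under a
minute on one CPU, while the architecture — dual 3-D CNN backbones with
bidirectional cross-modal guidance, adaptive temporal alignment, symmetric
cross-attention fusion, and the four-term joint loss — is exactly the full
pipeline's.
"""

import numpy as np

from bistfnet import BiSTFNet, TrainConfig, evaluate, train_one_fold
from bistfnet.presets import reduced_dataset, reduced_model_config

data, sim_cfg, _ = reduced_dataset(n_trials_per_class=4, seed=0)
tids = np.unique(data.trial_ids)
test_mask = np.isin(data.trial_ids, tids[-2:])   # hold out two trials
train_idx = np.nonzero(~test_mask)[0]
test_idx = np.nonzero(test_mask)[0]

model = BiSTFNet(reduced_model_config(), np.random.default_rng(42))
cfg = TrainConfig(epochs=20, patience=20, seed=42)
_, hist = train_one_fold(model, data, train_idx, [], cfg)
metrics = evaluate(model, data, test_idx, n_classes=2)

print(f"trained {len(hist.train_acc)} epochs; "
      f"final train accuracy {hist.train_acc[-1]:.2f}")
print(f"held-out trials: accuracy {metrics['accuracy']:.2f}, "
      f"macro F1 {metrics['f1']:.2f}")
print("confusion matrix (rows = true, cols = predicted):")
print(np.array(metrics["confusion"]))
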