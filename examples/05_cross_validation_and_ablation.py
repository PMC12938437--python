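"""Trial-level stratified cross-validation with an ablation switch.

Folds are made of whole trials, so no sliding-window sample of a trial can
appear on both sides of a split (leakage-safe by construction).  The same
harness trains any ablation variant; here the full model is compared with
"w/o ATA" (attention alignment replaced by an unweighted temporal mean).
A tiny 2-fold / few-epoch setting keeps the demo fast.
"""

import numpy as np

from bistfnet import ModelConfig, TrainConfig, run_cv
from bistfnet.presets import reduced_dataset, reduced_model_config

data, _, _ = reduced_dataset(n_trials_per_class=6, seed=5)

for ablation in ((), ("no_ata",)):
    cfg = TrainConfig(epochs=10, patience=10, k_folds=2, seed=42,
                      ablation=ablation)
    rep = run_cv(data, reduced_model_config(), cfg)
    name = ablation[0] if ablation else "full model"
    print(f"{name:>12}: accuracy {rep['mean']['accuracy']:.2f}  "
          f"macro F1 {rep['mean']['f1']:.2f}  "
          f"({len(rep['per_fold'])} folds, mean of fold metrics)")
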