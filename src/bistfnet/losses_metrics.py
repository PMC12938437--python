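"""Joint loss (weighted four-term objective with MSE warm-up) and metrics.

L_total = w1*L_main + w2*L_aux + w3*L_PCC + w4*L_MSE with w1 = 2.0,
w2 = 1.0, w3 = 0.2 fixed and w4 linearly warmed up from 0 to 1 over the
first 50 epochs.  Evaluation metrics are accuracy and macro-averaged
precision / recall / F1 from a one-vs-rest confusion-matrix decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["LossBundle", "ConfusionMatrix", "ce_loss", "ce_loss_from_logits",
           "w4_schedule", "joint_loss", "compute_metrics",
           "W1", "W2", "W3", "W4_WARMUP_EPOCHS"]

W1, W2, W3 = 2.0, 1.0, 0.2
W4_WARMUP_EPOCHS = 50
EPS_LOG = 1e-12


@dataclass
class LossBundle:
    main: Tensor
    aux: Tensor
    pcc: Tensor
    mse: Tensor
    w4: float
    total: Tensor

    def scalars(self) -> dict:
        def val(t):
            return float(t.item()) if isinstance(t, Tensor) else float(t)
        return {"main": val(self.main), "aux": val(self.aux),
                "pcc": val(self.pcc), "mse": val(self.mse),
                "w1": W1, "w2": W2, "w3": W3, "w4": self.w4,
                "total": val(self.total)}


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def ce_loss(y_true: np.ndarray, probs: Tensor | np.ndarray) -> Tensor:
    """Mean cross-entropy -1/B sum_i sum_c y_ic log p_ic over probability
    rows; ``y_true`` may be one-hot or integer labels.  Log clamped at 1e-12."""
    p = probs if isinstance(probs, Tensor) else Tensor(probs)
    y = np.asarray(y_true)
    if y.ndim == 1:
        y = _one_hot(y.astype(int), p.shape[-1])
    clamped = Tensor(np.maximum(p.data, EPS_LOG))  # clamp mask, constant wrt grad
    logp = (p + (clamped.data - p.data)).log()
    return -(Tensor(y) * logp).sum() * (1.0 / p.shape[0])


def ce_loss_from_logits(y_true: np.ndarray, logits: Tensor) -> Tensor:
    """Numerically stable cross-entropy on raw logits (training path)."""
    y = np.asarray(y_true)
    if y.ndim == 1:
        y = _one_hot(y.astype(int), logits.shape[-1])
    logp = logits.log_softmax(axis=-1)
    return -(Tensor(y) * logp).sum() * (1.0 / logits.shape[0])


def w4_schedule(epoch: int) -> float:
    """Linear warm-up of the MSE-consistency weight: 0 -> 1 over 50 epochs."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return min(epoch / W4_WARMUP_EPOCHS, 1.0)


def joint_loss(l_main, l_aux, l_pcc, l_mse, epoch: int) -> LossBundle:
    """Weighted four-term objective; zero Tensors stand in for disabled terms."""
    def t(x):
        return x if isinstance(x, Tensor) else Tensor(float(x))
    l_main, l_aux, l_pcc, l_mse = t(l_main), t(l_aux), t(l_pcc), t(l_mse)
    w4 = w4_schedule(epoch)
    total = W1 * l_main + W2 * l_aux + W3 * l_pcc + w4 * l_mse
    return LossBundle(l_main, l_aux, l_pcc, l_mse, w4, total)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, cols = predicted class

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int | None = None):
        y_true, y_pred = np.asarray(y_true, int), np.asarray(y_pred, int)
        if n_classes is None:
            n_classes = int(max(y_true.max(), y_pred.max())) + 1
        counts = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)

    def one_vs_rest(self, c: int) -> tuple:
        """(TP, TN, FP, FN) for class c."""
        tp = self.counts[c, c]
        fp = self.counts[:, c].sum() - tp
        fn = self.counts[c, :].sum() - tp
        tn = self.counts.sum() - tp - fp - fn
        return int(tp), int(tn), int(fp), int(fn)


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy + macro precision/recall/F1.

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); undefined ratios (zero denominator) count as 0.
    Macro averages are unweighted class means.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    n_classes = counts.shape[0]
    prec, rec, f1 = [], [], []
    for c in range(n_classes):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(f)
    return {"accuracy": counts.trace() / total,
            "precision": float(np.mean(prec)),
            "recall": float(np.mean(rec)),
            "f1": float(np.mean(f1)),
            "per_class": {"precision": prec, "recall": rec, "f1": f1}}
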