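"""Small deterministic softmax MLP trained with Adam.

Used as the dense fusion head of the deep pipeline.  Single-threaded numpy,
seeded initialization and a fixed shuffling stream make retraining with the
same seed bit-reproducible.  Early stopping monitors validation accuracy
and restores the best weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError


@dataclass
class MLPConfig:
    hidden: tuple = (128, 64)
    lr: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 80
    patience: int = 10
    weight_decay: float = 1e-4
    seed: int = 0


@dataclass
class TrainingLog:
    train_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    best_epoch: int = -1


class SoftmaxMLP:
    def __init__(self, n_in: int, n_classes: int, config: MLPConfig):
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        sizes = [n_in, *config.hidden, n_classes]
        self.W = [
            rng.normal(0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.fitted = False

    # ---- forward / backward -------------------------------------------
    def _forward(self, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        proba = e / e.sum(axis=1, keepdims=True)
        return acts, proba

    def _backward(self, acts, proba, onehot):
        B = onehot.shape[0]
        grads_W, grads_b = [None] * len(self.W), [None] * len(self.b)
        delta = (proba - onehot) / B
        for i in range(len(self.W) - 1, -1, -1):
            grads_W[i] = acts[i].T @ delta + self.config.weight_decay * self.W[i]
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return grads_W, grads_b

    # ---- training ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None) -> TrainingLog:
        """Train on (X, y) with labels 1..C; early-stop on validation accuracy."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.shape[0] == 0:
            raise DataError("empty training set")
        onehot_full = np.eye(self.n_classes)[y - 1]
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps, t = 0.9, 0.999, 1e-8, 0
        log = TrainingLog()
        best_val, best_state, since_best = -1.0, None, 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(X.shape[0])
            losses = []
            for start in range(0, X.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                acts, proba = self._forward(X[idx])
                oh = onehot_full[idx]
                losses.append(-np.mean(np.log(np.sum(proba * oh, axis=1) + 1e-12)))
                gW, gb = self._backward(acts, proba, oh)
                t += 1
                for i in range(len(self.W)):
                    for g, m, v, p in ((gW[i], mW[i], vW[i], self.W[i]),
                                       (gb[i], mb[i], vb[i], self.b[i])):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        mhat = m / (1 - beta1**t)
                        vhat = v / (1 - beta2**t)
                        p -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
            log.train_loss.append(float(np.mean(losses)))
            if X_val is not None and len(X_val):
                val_acc = float(np.mean(self.predict(X_val) == np.asarray(y_val)))
                log.val_accuracy.append(val_acc)
                if val_acc > best_val + 1e-12:
                    best_val, since_best = val_acc, 0
                    best_state = ([w.copy() for w in self.W],
                                  [b.copy() for b in self.b])
                    log.best_epoch = epoch
                else:
                    since_best += 1
                    if since_best >= cfg.patience:
                        break
        if best_state is not None:
            self.W, self.b = best_state
        self.fitted = True
        return log

    def predict_proba(self, X) -> np.ndarray:
        _, proba = self._forward(np.asarray(X, dtype=float))
        return proba

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1) + 1
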