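"""Feature-extraction backbone contract and a built-in tiny conv net.

The causal machinery only needs a callable that maps a preprocessed image
batch to a per-sample stack of n non-negative k x k feature maps taken
after the final pooling layer.  Any network satisfying that contract can be
plugged in (a fine-tuned VGG/ResNet wrapper, for instance); the package
ships a small conv net — three 3x3 conv + ReLU + 2x2 max-pool blocks —
written in numpy.  Freshly constructed it holds seeded He-initialized
random weights (a usable untrained random-features baseline);
:meth:`TinyConvBackbone.fit` fine-tunes the blocks end-to-end through a
temporary linear softmax head, after which the head is discarded and the
post-pooling feature maps feed the causality machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .causality_map import FeatureMapStack
from .exceptions import ShapeError

__all__ = ["BackboneContract", "TinyConvBackbone"]


@dataclass
class BackboneContract:
    """A named feature extractor with a fixed (n_channels, k) output shape."""

    extract: Callable[[np.ndarray], np.ndarray]  # (B,H,W,3) -> (B,n,k,k) >= 0
    name: str
    n_channels: int
    k: int
    input_side: int


def _im2col(x: np.ndarray, ksize: int) -> np.ndarray:
    """(B, H, W, C) -> (B, H-ks+1, W-ks+1, ks*ks*C) patch matrix."""
    B, H, W, C = x.shape
    out_h, out_w = H - ksize + 1, W - ksize + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, out_h, out_w, ksize, ksize, C),
        strides=(s0, s1, s2, s1, s2, s3),
        writeable=False,
    )
    return patches.reshape(B, out_h, out_w, ksize * ksize * C)


def _conv_relu_pool(x: np.ndarray, w: np.ndarray, b: np.ndarray, cache=None):
    """Same-padded 3x3 convolution, ReLU, then 2x2 max pooling."""
    ksize = int(round((w.shape[0] / x.shape[-1]) ** 0.5))
    pad = ksize // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = _im2col(xp, ksize)
    a = cols @ w + b
    np.maximum(a, 0.0, out=a)
    B, H, W, C = a.shape
    blocks = a.reshape(B, H // 2, 2, W // 2, 2, C)
    out = blocks.max(axis=(2, 4))
    if cache is not None:
        cache.append((cols, a, out, ksize, pad, x.shape))
    return out


def _conv_block_backward(dout, w, cache_entry):
    """Gradient of one conv-ReLU-pool block w.r.t. weights and input."""
    cols, a, out, ksize, pad, x_shape = cache_entry
    B, H, W, C = a.shape
    # route each pool gradient to the argmax position of its 2x2 window
    windows = (
        a.reshape(B, H // 2, 2, W // 2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(B, H // 2, W // 2, 4, C)
    )
    sel = windows.argmax(axis=3)  # (B, h, w, C)
    routed = np.eye(4, dtype=a.dtype)[sel].transpose(0, 1, 2, 4, 3) * dout[:, :, :, None, :]
    da = (
        routed.reshape(B, H // 2, W // 2, 2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(B, H, W, C)
    )
    da *= a > 0  # ReLU gate (a is post-ReLU; zero where clipped)
    dw = cols.reshape(-1, cols.shape[-1]).T @ da.reshape(-1, C)
    db = da.reshape(-1, C).sum(axis=0)
    dcols = da @ w.T
    dxp = np.zeros((B, H + 2 * pad, W + 2 * pad, x_shape[-1]), dtype=a.dtype)
    dcols = dcols.reshape(B, H, W, ksize, ksize, x_shape[-1])
    for i in range(ksize):
        for j in range(ksize):
            dxp[:, i : i + H, j : j + W, :] += dcols[:, :, :, i, j, :]
    dx = dxp[:, pad : pad + x_shape[1], pad : pad + x_shape[2], :]
    return dw, db, dx


class TinyConvBackbone:
    """Three-block conv net with seeded He-initialized fixed weights.

    For a 64 x 64 input the three 2x max-poolings give 8 x 8 feature maps
    (64 -> 32 -> 16 -> 8) over ``channels[-1]`` channels.
    """

    def __init__(
        self,
        input_side: int = 64,
        channels: Sequence[int] = (16, 32, 32),
        seed: int = 0,
        ksize: int = 3,
    ):
        if input_side % (2 ** len(channels)) != 0:
            raise ShapeError(
                f"input side {input_side} not divisible by {2 ** len(channels)}"
            )
        self._seed = seed
        self._ksize = ksize
        self.fitted = False
        self.input_side = input_side
        self.channels = tuple(channels)
        self.weights = self._init_weights(np.random.default_rng(seed))
        self.k = input_side // (2 ** len(channels))
        self.n_channels = channels[-1]

    def _init_weights(self, rng: np.random.Generator):
        weights = []
        fan_in_c = 3
        for c in self.channels:
            fan_in = self._ksize * self._ksize * fan_in_c
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c))
            weights.append((w.astype(np.float32), np.zeros(c, dtype=np.float32)))
            fan_in_c = c
        return weights

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.shape[1] != self.input_side or batch.shape[2] != self.input_side:
            raise ShapeError(
                f"expected {self.input_side}x{self.input_side} inputs, "
                f"got {batch.shape[1]}x{batch.shape[2]}"
            )
        x = batch
        for w, b in self.weights:
            x = _conv_relu_pool(x, w, b)
        return np.moveaxis(x, -1, 1)  # (B, n_channels, k, k)

    # ------------------------------------------------------------------
    # fine-tuning
    # ------------------------------------------------------------------
    def _forward_features(self, batch: np.ndarray, cache=None) -> np.ndarray:
        x = batch
        for w, b in self.weights:
            x = _conv_relu_pool(x, w, b, cache)
        return x  # channel-last (B, k, k, C)

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        val_images: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
        epochs: int = 15,
        lr: float = 3e-3,
        batch_size: int = 64,
        patience: int = 4,
        seed: int | None = None,
        freeze_blocks: int = 0,
        weight_decay: float = 1e-4,
        label_smoothing: float = 0.0,
    ) -> list[float]:
        """Fine-tune the conv blocks through a linear softmax head.

        The temporary head reads the flattened post-pooling feature maps.
        Labels are 1..C.  The head exists only during fine-tuning;
        afterwards calling the backbone still yields the post-pooling
        feature maps.  Early stopping monitors validation accuracy and
        restores the best block weights.  Returns the per-epoch
        training-loss history.

        ``freeze_blocks`` leaves the first blocks at their seeded random
        initialization (their outputs are precomputed once), which trades a
        little accuracy for a large speedup — the standard partial
        fine-tuning regime of transfer learning.
        """
        y = np.asarray(labels, dtype=int).ravel()
        n_classes = int(y.max())
        base_seed = self._seed + 17 if seed is None else seed
        history = self._fit_once(
            images, y, val_images, val_labels, epochs, lr, batch_size,
            patience, base_seed, freeze_blocks, weight_decay, label_smoothing,
            n_classes,
        )
        # dead-start guard: an unlucky initialization can leave every ReLU
        # path flat (loss pinned at ln C); reinitialize once at a lower rate
        if history and history[-1] > np.log(n_classes) - 0.10:
            rng = np.random.default_rng(base_seed + 101)
            self.weights = self._init_weights(rng)
            history = self._fit_once(
                images, y, val_images, val_labels, epochs, lr / 2, batch_size,
                patience, base_seed + 101, freeze_blocks, weight_decay,
                label_smoothing, n_classes,
            )
        self.fitted = True
        return history

    def _fit_once(
        self, images, y, val_images, val_labels, epochs, lr, batch_size,
        patience, seed, freeze_blocks, weight_decay, label_smoothing, n_classes,
    ) -> list[float]:
        rng = np.random.default_rng(seed)
        n_feat = self.n_channels * self.k * self.k
        Wh = rng.normal(0, np.sqrt(1.0 / n_feat), size=(n_feat, n_classes)).astype(
            np.float32
        )
        bh = np.zeros(n_classes, dtype=np.float32)

        def prefix(batch):
            x = np.asarray(batch, dtype=np.float32)
            outs = []
            for s in range(0, x.shape[0], 256):
                xi = x[s : s + 256]
                for w, b in self.weights[:freeze_blocks]:
                    xi = _conv_relu_pool(xi, w, b)
                outs.append(xi)
            return np.concatenate(outs)

        xs = prefix(images)
        xs_val = prefix(val_images) if val_images is not None and len(val_images) else None
        trainable = self.weights[freeze_blocks:]
        nb = len(trainable)
        params = [w for w, _ in trainable] + [b for _, b in trainable] + [Wh, bh]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps, t = 0.9, 0.999, 1e-8, 0
        onehot = np.eye(n_classes)[y - 1]
        if label_smoothing > 0:
            onehot = (1 - label_smoothing) * onehot + label_smoothing / n_classes
        history: list[float] = []
        best_val, best_state, since_best = -1.0, None, 0
        for _epoch in range(epochs):
            # linear warmup over the first three epochs guards the ReLU
            # paths against dying under large early Adam steps
            lr_t = lr * min(1.0, (_epoch + 1) / 3.0)
            order = rng.permutation(xs.shape[0])
            losses = []
            for start in range(0, xs.shape[0], batch_size):
                idx = order[start : start + batch_size]
                cache: list = []
                f = xs[idx]
                for w, b in trainable:
                    f = _conv_relu_pool(f, w, b, cache)
                flat = f.reshape(idx.size, -1)
                logits = flat @ Wh + bh
                logits -= logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                proba = e / e.sum(axis=1, keepdims=True)
                oh = onehot[idx]
                losses.append(-np.mean(np.log((proba * oh).sum(axis=1) + 1e-12)))
                delta = ((proba - oh) / idx.size).astype(np.float32)
                grads = [None] * len(params)
                grads[2 * nb] = flat.T @ delta + weight_decay * Wh
                grads[2 * nb + 1] = delta.sum(axis=0)
                dx = (delta @ Wh.T).reshape(f.shape)
                for blk in range(nb - 1, -1, -1):
                    dw, db, dx = _conv_block_backward(dx, trainable[blk][0], cache[blk])
                    grads[blk] = dw + weight_decay * trainable[blk][0]
                    grads[nb + blk] = db
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= lr_t * (mi / (1 - beta1**t)) / (
                        np.sqrt(vi / (1 - beta2**t)) + eps
                    )
            history.append(float(np.mean(losses)))
            if xs_val is not None:
                f_v = xs_val
                for w, b in trainable:
                    f_v = _conv_relu_pool(f_v, w, b)
                pred = (f_v.reshape(len(f_v), -1) @ Wh + bh).argmax(axis=1) + 1
                val_acc = float(np.mean(pred == np.asarray(val_labels)))
                if val_acc > best_val + 1e-12:
                    best_val, since_best = val_acc, 0
                    best_state = [(w.copy(), b.copy()) for w, b in trainable]
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        if best_state is not None:
            self.weights = self.weights[:freeze_blocks] + best_state
        return history

    def contract(self) -> BackboneContract:
        return BackboneContract(
            extract=self,
            name=f"tinyconv-{'x'.join(map(str, self.channels))}",
            n_channels=self.n_channels,
            k=self.k,
            input_side=self.input_side,
        )


def extract_feature_maps(backbone, batch: np.ndarray) -> list[FeatureMapStack]:
    """Run the backbone and wrap each sample as a FeatureMapStack.

    Negative activations (a contract violation for a post-ReLU layer) are
    clamped to zero with a warning.
    """
    extract = backbone.extract if isinstance(backbone, BackboneContract) else backbone
    maps = np.asarray(extract(batch), dtype=float)
    if maps.ndim != 4:
        raise ShapeError(f"backbone must return (B, n, k, k), got {maps.shape}")
    if np.any(maps < 0):
        import warnings

        warnings.warn("backbone produced negative activations; clamping at 0")
        maps = np.maximum(maps, 0.0)
    return [FeatureMapStack(maps=m) for m in maps]
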