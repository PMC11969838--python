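"""End-to-end causality-aware image classification pipeline.

The flow mirrors the two-branch design of the deep method: preprocessed
images pass through a convolutional backbone; the post-pooling feature-map
stack is routed (a) into the pairwise conditional-probability causality map
and (b) into flattened causal factors screened against the label with
kernel independence tests.  The flattened causality map, the kept causal
factors and the flattened feature maps are concatenated into one fused
vector per image and classified by a dense softmax head.  A paired "base"
model trains the same head on the flattened feature maps alone, giving the
ablation contrast between causality-aware and plain deep features.

Causal factor selection and feature standardization are fit on the training
split only and frozen before they touch validation or test data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from ._mlp import MLPConfig, SoftmaxMLP, TrainingLog
from .backbone import BackboneContract, TinyConvBackbone, extract_feature_maps
from .causality_map import CausalityMap, FeatureMapStack
from .exceptions import ConfigurationError, DataError, ShapeError
from .selection import FactorTable, SelectionConfig, select_causal_factors

__all__ = [
    "ImageDataset",
    "PipelineConfig",
    "FusedFeatureVector",
    "preprocess_images",
    "load_image_dataset",
    "make_split",
    "augment_training_set",
    "batch_causality_maps",
    "channel_presence_factors",
    "assemble_fused_features",
    "CICNNClassifier",
    "train_cicnn",
    "predict",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# dataset container and preprocessing
# --------------------------------------------------------------------------

@dataclass
class ImageDataset:
    """Images in [0, 1] with labels 1..C and an optional split assignment."""

    images: np.ndarray  # (N, H, W, 3)
    labels: np.ndarray  # (N,) ints 1..C
    class_names: Sequence[str]
    split: np.ndarray | None = None  # (N,) of {"train", "val", "test"}

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ShapeError(f"images must be (N, H, W, 3), got {self.images.shape}")
        if self.labels.shape[0] != self.images.shape[0]:
            raise DataError("labels length must match image count")
        if self.split is not None:
            self.split = np.asarray(self.split)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def indices(self, part: str) -> np.ndarray:
        if self.split is None:
            raise DataError("dataset has no split assignment; call make_split first")
        return np.flatnonzero(self.split == part)

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        return ImageDataset(
            images=self.images[idx],
            labels=self.labels[idx],
            class_names=self.class_names,
            split=None if self.split is None else self.split[idx],
        )


def preprocess_images(raw, side: int = 224) -> np.ndarray:
    """Resize every image to side x side and scale intensities to [0, 1].

    ``raw`` may be arrays or file paths; an unreadable file is reported with
    its path and skipped so the batch continues.
    """
    out, errors = [], []
    for item in raw:
        try:
            if isinstance(item, (str, Path)):
                arr = np.asarray(Image.open(item).convert("RGB"))
            else:
                arr = np.asarray(item)
            if arr.dtype.kind in "ui":
                arr = arr.astype(float) / 255.0
            else:
                arr = arr.astype(float)
            if arr.ndim == 2:
                arr = np.repeat(arr[:, :, None], 3, axis=2)
            arr = np.clip(arr, 0.0, 1.0)
            if arr.shape[0] != side or arr.shape[1] != side:
                im = Image.fromarray((arr * 255).astype(np.uint8))
                arr = np.asarray(im.resize((side, side), Image.BILINEAR)) / 255.0
            out.append(arr)
        except (OSError, ValueError) as exc:  # unreadable file: continue batch
            errors.append((item, exc))
            log.error("failed to read image %s: %s", item, exc)
    if errors and not out:
        raise DataError(f"no readable images; first error: {errors[0]}")
    return np.stack(out)


def load_image_dataset(directory, side: int | None = None) -> ImageDataset:
    """Read a directory-per-class dataset with a ``manifest.csv``.

    The manifest has columns ``filename,label[,split]``; filenames are
    relative to the dataset directory.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    class_names = sorted(manifest["label"].unique())
    label_idx = {name: i + 1 for i, name in enumerate(class_names)}
    images = preprocess_images(
        [directory / f for f in manifest["filename"]],
        side=side or np.asarray(Image.open(directory / manifest["filename"][0])).shape[0],
    )
    return ImageDataset(
        images=images,
        labels=np.array([label_idx[l] for l in manifest["label"]]),
        class_names=[str(c) for c in class_names],
        split=manifest["split"].to_numpy() if "split" in manifest else None,
    )


def make_split(
    dataset: ImageDataset,
    fractions: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> ImageDataset:
    """Per-class stratified train/val/test assignment (remainder to train)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    split = np.empty(dataset.labels.shape[0], dtype=object)
    n_parts = sum(f > 0 for f in fractions)
    for c in np.unique(dataset.labels):
        members = np.flatnonzero(dataset.labels == c)
        if members.size < 3 and n_parts == 3:
            raise DataError(
                f"class {dataset.class_names[c - 1]!r} has only {members.size} "
                "members; need at least 3 for a 3-way split"
            )
        members = rng.permutation(members)
        n_val = int(np.floor(fractions[1] * members.size))
        n_test = int(np.floor(fractions[2] * members.size))
        split[members[:n_test]] = "test"
        split[members[n_test : n_test + n_val]] = "val"
        split[members[n_test + n_val :]] = "train"
    return ImageDataset(
        images=dataset.images,
        labels=dataset.labels,
        class_names=dataset.class_names,
        split=split.astype(str),
    )


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def _augment_one(img: np.ndarray, pool: np.ndarray, rng: np.random.Generator):
    """One seeded random augmentation drawn from the five technique families."""
    from scipy import ndimage

    family = rng.integers(5)
    out = img
    if family == 0:  # geometric: rotation / flip / shift
        choice = rng.integers(3)
        if choice == 0:
            angle = rng.uniform(-25, 25)
            out = np.stack(
                [ndimage.rotate(img[..., c], angle, reshape=False, order=1,
                                mode="nearest") for c in range(3)], axis=-1)
        elif choice == 1:
            out = img[:, ::-1] if rng.random() < 0.5 else img[::-1]
        else:
            dy, dx = rng.integers(-5, 6, size=2)
            out = np.roll(img, (dy, dx), axis=(0, 1))
    elif family == 1:  # color space: brightness / per-channel gain
        gain = rng.uniform(0.85, 1.15, size=3)
        out = img * gain + rng.uniform(-0.05, 0.05)
    elif family == 2:  # kernel filters: blur or sharpen
        sigma = rng.uniform(0.4, 1.2)
        blurred = np.stack(
            [ndimage.gaussian_filter(img[..., c], sigma) for c in range(3)], axis=-1)
        out = blurred if rng.random() < 0.5 else np.clip(2 * img - blurred, 0, 1)
    elif family == 3:  # random erasing
        h, w = img.shape[:2]
        eh, ew = rng.integers(h // 8, h // 3), rng.integers(w // 8, w // 3)
        y0, x0 = rng.integers(0, h - eh), rng.integers(0, w - ew)
        out = img.copy()
        out[y0 : y0 + eh, x0 : x0 + ew] = img.mean(axis=(0, 1))
    else:  # image mixing with a same-class partner
        partner = pool[rng.integers(pool.shape[0])]
        lam = rng.uniform(0.55, 0.9)
        out = lam * img + (1 - lam) * partner
    return np.clip(out, 0.0, 1.0)


def augment_training_set(
    dataset: ImageDataset, factor: int, seed: int = 0
) -> ImageDataset:
    """Enlarge the training split to ``factor`` times its size.

    The originals are kept and (factor - 1) seeded random augmentations per
    image are appended; validation and test images pass through untouched,
    so label proportions within the training split are preserved exactly.
    """
    if factor < 1:
        raise ConfigurationError(f"augmentation factor must be >= 1, got {factor}")
    if factor == 1:
        return dataset
    rng = np.random.default_rng(seed)
    train_idx = dataset.indices("train")
    new_imgs, new_labels = [], []
    by_class = {
        c: dataset.images[train_idx[dataset.labels[train_idx] == c]]
        for c in np.unique(dataset.labels[train_idx])
    }
    for i in train_idx:
        img, lab = dataset.images[i], dataset.labels[i]
        for _ in range(factor - 1):
            new_imgs.append(_augment_one(img, by_class[lab], rng))
            new_labels.append(lab)
    images = np.concatenate([dataset.images, np.stack(new_imgs)])
    labels = np.concatenate([dataset.labels, np.array(new_labels)])
    split = np.concatenate([dataset.split, np.full(len(new_imgs), "train")])
    return ImageDataset(images, labels, dataset.class_names, split)


# --------------------------------------------------------------------------
# fused features
# --------------------------------------------------------------------------

def batch_causality_maps(maps: np.ndarray) -> np.ndarray:
    """Per-sample causality maps, vectorized over a (B, n, k, k) batch.

    Each sample is normalized by its own global maximum; entry (i, j) is
    max_i * max_j / sum_j of the normalized stack, with zero columns for
    all-zero channels.  Returns (B, n, n).
    """
    peak = maps.max(axis=(1, 2, 3), keepdims=True)
    norm = np.divide(maps, peak, out=np.zeros_like(maps), where=peak > 0)
    maxima = norm.max(axis=(2, 3))  # (B, n)
    sums = norm.sum(axis=(2, 3))  # (B, n)
    ratio = np.divide(maxima, sums, out=np.zeros_like(sums), where=sums > 0)
    return maxima[:, :, None] * ratio[:, None, :]


def channel_presence_factors(maps: np.ndarray, mode: str = "channel_max") -> np.ndarray:
    """Flatten feature maps into candidate causal factors.

    ``channel_max`` (default) takes each channel's peak activation as its
    presence value — one factor per channel; ``full`` exposes every pixel of
    every map as a factor.
    """
    if mode == "channel_max":
        return maps.max(axis=(2, 3))
    if mode == "full":
        return maps.reshape(maps.shape[0], -1)
    raise ConfigurationError(f"unknown flatten mode {mode!r}")


@dataclass
class FusedFeatureVector:
    """Concatenation of causality map, kept causal factors and flat maps."""

    values: np.ndarray
    offsets: dict  # segment name -> (start, stop)

    def segment(self, name: str) -> np.ndarray:
        start, stop = self.offsets[name]
        return self.values[start:stop]


def assemble_fused_features(
    stack: FeatureMapStack,
    cmap: CausalityMap,
    kept_channel_indices: Sequence[int],
) -> FusedFeatureVector:
    """Fuse one sample: [causality map (n^2), kept factors, flat maps (n k^2)]."""
    n = stack.n_channels
    if cmap.values.shape != (n, n):
        raise ShapeError(
            f"causality map {cmap.values.shape} inconsistent with {n}-channel stack"
        )
    factors = stack.maps.max(axis=(1, 2))[list(kept_channel_indices)]
    if factors.size == 0:
        log.warning("no kept causal factors; fused vector has an empty segment")
    flat = stack.maps.ravel()
    values = np.concatenate([cmap.values.ravel(), factors, flat])
    offsets = {
        "causality_map": (0, n * n),
        "causal_factors": (n * n, n * n + factors.size),
        "feature_maps": (n * n + factors.size, values.size),
    }
    return FusedFeatureVector(values=values, offsets=offsets)


# --------------------------------------------------------------------------
# the classifier
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Desk-scale defaults: 64 x 64 inputs, 32-channel tiny backbone (k = 8)."""

    side: int = 64
    backbone_channels: tuple = (16, 32, 32)
    backbone_epochs: int = 24  # 0 keeps the seeded random-feature backbone
    backbone_lr: float = 6e-3
    backbone_freeze_blocks: int = 1  # partial fine-tuning (first block random)
    backbone_patience: int = 6
    augment_factor: int = 4  # training-split enlargement before fitting
    alpha: float = 0.05
    n_permutations: int = 99
    selection_max_n: int = 300  # subsample size for the screening tests
    detect_pairs: bool = False  # pair detection is interpretability output
    pair_max_n: int = 150
    flatten: str = "channel_max"
    use_causal_features: bool = True  # False trains the ablation "base" model
    mlp: MLPConfig = field(default_factory=MLPConfig)
    seed: int = 0


class CICNNClassifier:
    """Causality-aware image classifier with a paired ablation baseline.

    ``fit`` extracts feature maps, builds per-sample causality maps, selects
    causal factors on the training split, fuses the three segments and
    trains the dense head.  With ``use_causal_features=False`` the same head
    is trained on the flattened feature maps alone (the base model of the
    ablation), under the same seed.
    """

    def __init__(
        self,
        config: PipelineConfig | None = None,
        backbone: TinyConvBackbone | None = None,
    ):
        self.config = config or PipelineConfig()
        cfg = self.config
        # an injected backbone (possibly already fine-tuned) is used as-is,
        # which lets the ablation pair share one backbone per seed
        self.backbone = backbone or TinyConvBackbone(
            input_side=cfg.side, channels=cfg.backbone_channels, seed=cfg.seed
        )
        self.head: SoftmaxMLP | None = None
        self.factor_set = None
        self.kept_channels: list[int] = []
        self._mu = self._sigma = None
        self.training_log: TrainingLog | None = None

    # ---- feature construction -----------------------------------------
    def _raw_maps(self, images: np.ndarray, batch: int = 128) -> np.ndarray:
        if images.shape[0] == 0:
            raise DataError("no images in this batch/split")
        chunks = [
            self.backbone(images[i : i + batch])
            for i in range(0, images.shape[0], batch)
        ]
        return np.concatenate(chunks)

    def _design_matrix(self, maps: np.ndarray) -> np.ndarray:
        peak = maps.max(axis=(1, 2, 3), keepdims=True)
        norm = np.divide(maps, peak, out=np.zeros_like(maps), where=peak > 0)
        flat = norm.reshape(norm.shape[0], -1)
        if not self.config.use_causal_features:
            return flat
        cmaps = batch_causality_maps(maps).reshape(maps.shape[0], -1)
        factors = channel_presence_factors(maps, self.config.flatten)
        return np.concatenate([cmaps, factors[:, self.kept_channels], flat], axis=1)

    # ---- fitting -------------------------------------------------------
    def fit(self, dataset: ImageDataset) -> "CICNNClassifier":
        cfg = self.config
        if cfg.augment_factor > 1:
            dataset = augment_training_set(dataset, cfg.augment_factor, seed=cfg.seed)
        train_idx = dataset.indices("train")
        val_idx = dataset.indices("val")
        if train_idx.size == 0:
            raise DataError("empty training split")
        y_train = dataset.labels[train_idx]
        if cfg.backbone_epochs > 0 and not self.backbone.fitted:
            self.backbone.fit(
                dataset.images[train_idx],
                y_train,
                dataset.images[val_idx] if val_idx.size else None,
                dataset.labels[val_idx] if val_idx.size else None,
                epochs=cfg.backbone_epochs,
                lr=cfg.backbone_lr,
                patience=cfg.backbone_patience,
                freeze_blocks=cfg.backbone_freeze_blocks,
                label_smoothing=0.05,
            )
        maps_train = self._raw_maps(dataset.images[train_idx])

        if cfg.use_causal_features:
            factors = channel_presence_factors(maps_train, cfg.flatten)
            rows = np.arange(factors.shape[0])
            if rows.size > cfg.selection_max_n:
                rows = np.sort(
                    np.random.default_rng(cfg.seed + 11).choice(
                        rows, cfg.selection_max_n, replace=False
                    )
                )
            table = FactorTable(
                values=factors[rows],
                factor_ids=[f"ch{i:03d}" for i in range(factors.shape[1])],
                label=y_train[rows],
            )
            sel_cfg = SelectionConfig(
                alpha=cfg.alpha,
                n_permutations=cfg.n_permutations,
                seed=cfg.seed,
                detect_pairs=cfg.detect_pairs,
                pair_max_n=cfg.pair_max_n,
            )
            self.factor_set = select_causal_factors(table, sel_cfg)
            self.kept_channels = sorted(int(f[2:]) for f in self.factor_set.kept)

        X_train = self._design_matrix(maps_train)
        self._mu = X_train.mean(axis=0)
        self._sigma = X_train.std(axis=0)
        self._sigma[self._sigma == 0] = 1.0
        X_train = (X_train - self._mu) / self._sigma

        X_val = y_val = None
        if val_idx.size:
            maps_val = self._raw_maps(dataset.images[val_idx])
            X_val = (self._design_matrix(maps_val) - self._mu) / self._sigma
            y_val = dataset.labels[val_idx]

        head_cfg = MLPConfig(**{**cfg.mlp.__dict__, "seed": cfg.seed})
        self.head = SoftmaxMLP(X_train.shape[1], dataset.n_classes, head_cfg)
        self.training_log = self.head.fit(X_train, y_train, X_val, y_val)
        return self

    # ---- inference -----------------------------------------------------
    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if self.head is None or not self.head.fitted:
            raise DataError("model is not trained; call fit first")
        X = self._design_matrix(self._raw_maps(np.asarray(images, dtype=float)))
        return self.head.predict_proba((X - self._mu) / self._sigma)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1) + 1

    def evaluate(self, dataset: ImageDataset, part: str = "test"):
        from .evaluation import evaluate_predictions

        idx = dataset.indices(part)
        proba = self.predict_proba(dataset.images[idx])
        return evaluate_predictions(dataset.labels[idx], proba, dataset.n_classes)

    # ---- persistence ---------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "model.npz",
            mu=self._mu,
            sigma=self._sigma,
            kept=np.array(self.kept_channels, dtype=int),
            **{f"W{i}": w for i, w in enumerate(self.head.W)},
            **{f"b{i}": b for i, b in enumerate(self.head.b)},
        )
        with open(path / "config.json", "w") as fh:
            json.dump(
                {**{k: v for k, v in self.config.__dict__.items() if k != "mlp"},
                 "mlp": self.config.mlp.__dict__},
                fh, indent=2, default=list,
            )
        if self.factor_set is not None:
            self.factor_set.to_json(path / "factors.json")


def train_cicnn(dataset: ImageDataset, config: PipelineConfig | None = None):
    """Convenience wrapper: fit a classifier and return (model, training log)."""
    model = CICNNClassifier(config).fit(dataset)
    return model, model.training_log


def predict(model: CICNNClassifier, images: np.ndarray):
    """Class probabilities (rows sum to 1) and argmax labels for a batch."""
    proba = model.predict_proba(images)
    return proba, proba.argmax(axis=1) + 1
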