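"""Nucleus/cytoplasm morphometrics and the classical classifier comparison.

A single-cell image is partitioned into nucleus and cytoplasm; from the two
binary masks the standard cytological shape descriptors are computed —
areas, the N/C ratio N/(N+C) (a key malignancy indicator), perimeters,
roundness (area over the area of the circle spanned by the longest
diameter), inscribed/circumscribed diameters, elongation (shortest over
longest diameter) and how centrally the nucleus sits in the cytoplasm.
Texture is summarized by four gray-level co-occurrence (GLCM) properties
over the cell region: contrast, correlation, energy and homogeneity.

The same feature tables drive the classical-classifier comparison
(KNN / SVM / RF), with or without kernel-test causal feature selection,
mirroring the with/without-selection experimental design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import MultiPoint, minimum_bounding_radius
from skimage import measure, morphology
from skimage.color import rgb2gray
from skimage.filters import threshold_multiotsu

from .exceptions import ConfigurationError, SegmentationError, ValidationError
from .selection import FactorTable, SelectionConfig, select_causal_factors

__all__ = [
    "SegmentationMasks",
    "ShapeFeatures",
    "TextureFeatures",
    "GLCMConfig",
    "segment_cell",
    "compute_shape_features",
    "compute_texture_features",
    "extract_cell_features",
    "features_dataframe",
    "classical_classify",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

@dataclass
class SegmentationMasks:
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    provenance: str = "computed"  # or "ground_truth"

    def __post_init__(self):
        if self.nucleus_mask.shape != self.cytoplasm_mask.shape:
            raise ValidationError("masks must share a shape")
        if not self.nucleus_mask.any() or not self.cytoplasm_mask.any():
            raise SegmentationError("empty nucleus or cytoplasm mask")

    @property
    def cell_mask(self) -> np.ndarray:
        return self.nucleus_mask | self.cytoplasm_mask


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def segment_cell(image: np.ndarray, opening_radius: int = 1) -> SegmentationMasks:
    """Two-level intensity segmentation of a single stained cell.

    Multi-Otsu thresholding splits the grayscale image into three intensity
    bands; the darkest band is the nucleus, the middle band the cytoplasm
    (the background being lightest in a bright-field preparation).  Each
    mask is cleaned by morphological opening/closing and reduced to its
    largest connected component; the nucleus is filled and carved out of
    the cell region.
    """
    img = np.asarray(image, dtype=float)
    gray = rgb2gray(img) if img.ndim == 3 else img
    if np.ptp(gray) < 1e-6:
        raise SegmentationError("image has no intensity contrast")
    try:
        lo, hi = threshold_multiotsu(gray, classes=3)
    except ValueError as exc:
        raise SegmentationError(f"thresholding failed: {exc}") from exc
    footprint = morphology.disk(opening_radius)
    nucleus = gray < lo
    cell = gray < hi
    nucleus = morphology.closing(morphology.opening(nucleus, footprint), footprint)
    cell = morphology.closing(morphology.opening(cell, footprint), footprint)
    if not nucleus.any() or not cell.any():
        raise SegmentationError(
            f"empty compartment after cleanup (thresholds {lo:.3f}, {hi:.3f})"
        )
    cell = ndimage.binary_fill_holes(_largest_component(cell))
    nucleus = ndimage.binary_fill_holes(_largest_component(nucleus & cell))
    cytoplasm = cell & ~nucleus
    if not nucleus.any() or not cytoplasm.any():
        raise SegmentationError("nucleus or cytoplasm vanished after cleanup")
    return SegmentationMasks(nucleus, cytoplasm, provenance="computed")


# --------------------------------------------------------------------------
# shape features
# --------------------------------------------------------------------------

@dataclass
class ShapeFeatures:
    nucleus_area: float
    cytoplasm_area: float
    nc_ratio: float
    nucleus_perimeter: float
    cytoplasm_perimeter: float
    nucleus_roundness: float
    cytoplasm_roundness: float
    nucleus_shortest_diameter: float
    nucleus_longest_diameter: float
    cytoplasm_shortest_diameter: float
    cytoplasm_longest_diameter: float
    nucleus_elongation: float
    cytoplasm_elongation: float
    nucleus_position: float


def _mask_geometry(mask: np.ndarray):
    """area, perimeter, shortest/longest diameter, roundness, centroid."""
    if not mask.any():
        raise ValidationError("empty mask")
    area = float(mask.sum())
    perimeter = float(measure.perimeter(mask))
    ys, xs = np.nonzero(mask)
    longest = 2.0 * float(
        minimum_bounding_radius(MultiPoint(np.column_stack([xs, ys])))
    )
    # largest inscribed circle via the Euclidean distance transform
    shortest = 2.0 * float(ndimage.distance_transform_edt(mask).max())
    longest = max(longest, shortest, 1.0)
    roundness = area / (np.pi * (longest / 2.0) ** 2)
    centroid = np.array([xs.mean(), ys.mean()])
    return area, perimeter, shortest, longest, roundness, centroid


def compute_shape_features(masks: SegmentationMasks) -> ShapeFeatures:
    """All Table-style shape descriptors from nucleus and cytoplasm masks.

    The cytoplasm compartment descriptors are computed on the whole cell
    region (nucleus plus cytoplasm), which is the closed outer contour; the
    N/C ratio is nucleus area over total cell area.
    """
    n_area, n_perim, n_short, n_long, n_round, n_cent = _mask_geometry(
        masks.nucleus_mask
    )
    c_area_only = float(masks.cytoplasm_mask.sum())
    _, c_perim, c_short, c_long, c_round, c_cent = _mask_geometry(masks.cell_mask)
    nc_ratio = n_area / (n_area + c_area_only)
    position = 1.0 - float(np.linalg.norm(n_cent - c_cent)) / (c_long / 2.0)
    return ShapeFeatures(
        nucleus_area=n_area,
        cytoplasm_area=c_area_only,
        nc_ratio=nc_ratio,
        nucleus_perimeter=n_perim,
        cytoplasm_perimeter=c_perim,
        nucleus_roundness=n_round,
        cytoplasm_roundness=c_round,
        nucleus_shortest_diameter=n_short,
        nucleus_longest_diameter=n_long,
        cytoplasm_shortest_diameter=c_short,
        cytoplasm_longest_diameter=c_long,
        nucleus_elongation=n_short / n_long,
        cytoplasm_elongation=c_short / c_long,
        nucleus_position=float(np.clip(position, 0.0, 1.0)),
    )


# --------------------------------------------------------------------------
# texture features
# --------------------------------------------------------------------------

@dataclass
class GLCMConfig:
    levels: int = 8
    distance: int = 1
    angles: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def _masked_glcm(q: np.ndarray, mask: np.ndarray, d: int, angle: float, levels: int):
    """Symmetric co-occurrence counts restricted to pixel pairs inside mask."""
    dy = int(round(d * np.sin(angle)))
    dx = int(round(d * np.cos(angle)))
    H, W = q.shape
    y0, y1 = max(0, -dy), min(H, H - dy)
    x0, x1 = max(0, -dx), min(W, W - dx)
    src = q[y0:y1, x0:x1]
    dst = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    valid = mask[y0:y1, x0:x1] & mask[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    counts = np.zeros((levels, levels))
    np.add.at(counts, (src[valid], dst[valid]), 1.0)
    return counts + counts.T  # symmetric


def compute_texture_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    config: GLCMConfig | None = None,
) -> TextureFeatures:
    """GLCM texture properties over the masked region.

    Intensities in [0, 1] are quantized into ``levels`` uniform bins; the
    co-occurrence matrices for the configured offsets are made symmetric,
    averaged over angles and normalized to a probability table P.  Then

        contrast    = sum P(i,j) (i - j)^2
        energy      = sqrt(sum P(i,j)^2)              (root of the ASM)
        homogeneity = sum P(i,j) / (1 + |i - j|)
        correlation = covariance / (sigma_i sigma_j), = 1 at zero variance
    """
    config = config or GLCMConfig()
    img = np.asarray(image, dtype=float)
    gray = rgb2gray(img) if img.ndim == 3 else img
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    mask = mask.astype(bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    q = np.clip((gray * config.levels).astype(int), 0, config.levels - 1)
    total = np.zeros((config.levels, config.levels))
    for angle in config.angles:
        total += _masked_glcm(q, mask, config.distance, angle, config.levels)
    if total.sum() == 0:
        raise ValidationError(
            "mask smaller than the co-occurrence offset support"
        )
    P = total / total.sum()
    i = np.arange(config.levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(P * (ii - jj) ** 2))
    energy = float(np.sqrt(np.sum(P**2)))
    homogeneity = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    mu_i = float(np.sum(P * ii))
    mu_j = float(np.sum(P * jj))
    var_i = float(np.sum(P * (ii - mu_i) ** 2))
    var_j = float(np.sum(P * (jj - mu_j) ** 2))
    if var_i <= 1e-15 or var_j <= 1e-15:
        correlation = 1.0  # constant region is perfectly self-correlated
    else:
        cov = float(np.sum(P * (ii - mu_i) * (jj - mu_j)))
        correlation = cov / np.sqrt(var_i * var_j)
    return TextureFeatures(contrast, correlation, energy, homogeneity)


# --------------------------------------------------------------------------
# feature tables and classical classifiers
# --------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "nucleus_area", "cytoplasm_area", "nc_ratio",
    "nucleus_perimeter", "cytoplasm_perimeter",
    "nucleus_roundness", "cytoplasm_roundness",
    "nucleus_shortest_diameter", "nucleus_longest_diameter",
    "cytoplasm_shortest_diameter", "cytoplasm_longest_diameter",
    "nucleus_elongation", "cytoplasm_elongation", "nucleus_position",
    "contrast", "correlation", "energy", "homogeneity",
]


def extract_cell_features(
    image: np.ndarray,
    masks: SegmentationMasks | None = None,
    glcm_config: GLCMConfig | None = None,
) -> dict:
    """One row of shape + texture features; segments the image if no masks."""
    if masks is None:
        masks = segment_cell(image)
    shape = compute_shape_features(masks)
    texture = compute_texture_features(image, masks.cell_mask, glcm_config)
    row = {**shape.__dict__, **texture.__dict__}
    return {k: row[k] for k in FEATURE_COLUMNS}


def features_dataframe(images, masks_list=None, labels=None) -> pd.DataFrame:
    """Fixed-column-order feature table for a batch of cell images."""
    rows = []
    for i, img in enumerate(images):
        masks = masks_list[i] if masks_list is not None else None
        rows.append(extract_cell_features(img, masks))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if labels is not None:
        df["y"] = np.asarray(labels)
    return df


def _make_model(model_kind: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    kind = model_kind.upper()
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if kind == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if kind == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ConfigurationError(f"unknown model kind {model_kind!r}")


def classical_classify(
    features: pd.DataFrame,
    labels,
    model_kind: str = "SVM",
    use_causal_selection: bool = False,
    test_fraction: float = 0.25,
    seed: int = 0,
    selection_config: SelectionConfig | None = None,
):
    """Train/evaluate a classical model on a cell-feature table.

    Features are standardized on training statistics.  With
    ``use_causal_selection`` the kernel-test selection (marginal screen +
    cause-pair detection) runs on the training split only and the
    classifier consumes the kept features.  Returns a
    :class:`~causalcyto.evaluation.MetricsReport` on the held-out test split.
    """
    from .evaluation import evaluate_predictions

    X = features.drop(columns=["y"], errors="ignore")
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValidationError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(y.size, dtype=bool)
    for c in np.unique(y):  # stratified split
        members = rng.permutation(np.flatnonzero(y == c))
        test_mask[members[: max(1, int(round(test_fraction * members.size)))]] = True
    X_train, X_test = X[~test_mask], X[test_mask]
    y_train, y_test = y[~test_mask], y[test_mask]

    mu, sigma = X_train.mean(), X_train.std().replace(0, 1.0)
    X_train = (X_train - mu) / sigma
    X_test = (X_test - mu) / sigma

    selected = list(X.columns)
    factor_set = None
    if use_causal_selection:
        cfg = selection_config or SelectionConfig(seed=seed)
        table = FactorTable(
            values=X_train.to_numpy(), factor_ids=list(X.columns), label=y_train
        )
        factor_set = select_causal_factors(table, cfg)
        selected = [c for c in X.columns if c in set(factor_set.kept)]
        if not selected:
            log.warning("selection removed every feature; falling back to all")
            selected = list(X.columns)

    model = _make_model(model_kind, seed)
    model.fit(X_train[selected], y_train)
    proba = model.predict_proba(X_test[selected])
    # align probability columns to classes 1..C
    n_classes = int(y.max())
    full = np.zeros((proba.shape[0], n_classes))
    for k, cls in enumerate(model.classes_):
        full[:, int(cls) - 1] = proba[:, k]
    report = evaluate_predictions(y_test, full, n_classes)
    return report, factor_set
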