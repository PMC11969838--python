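"""Synthetic fixtures with known ground truth.

Two generators make the whole package testable without any external data:

* :func:`generate_scm_features` draws tabular factors from a small
  structural causal model in which some columns *cause* the class label,
  some are *effects* of it, and the rest are independent noise — the three
  roles the selection scheme must recover.

* :func:`generate_cell_image` renders a five-class single-cell cytology
  look-alike: one elliptical cytoplasm containing one elliptical nucleus on
  a light background, with ground-truth masks and all generative latents
  returned.  The class controls the causal morphology along a monotone
  severity axis — the nucleus-to-cell area ratio (N/C) rises with class,
  the nucleus grows more elongated and more eccentric — with overlapping
  bands so classes are separable but not trivially so, as in real cytology.
  A *nuisance* grating texture and hue shift on the cytoplasm carries no
  morphological information; in ``confounded`` mode its identity correlates
  with the class, in ``clean`` mode it is independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import ConfigurationError, ValidationError
from .pipeline import ImageDataset
from .selection import FactorTable

__all__ = [
    "SCMSpec",
    "generate_scm_features",
    "CellImageConfig",
    "CellImageRecord",
    "generate_cell_image",
    "generate_image_dataset",
    "nc_threshold_predict",
]


# --------------------------------------------------------------------------
# structural causal model for tabular factors
# --------------------------------------------------------------------------

@dataclass
class SCMSpec:
    """Study conditions for the tabular cause/effect/independent benchmark."""

    n_causes: int = 5
    n_effects: int = 5
    n_independent: int = 10
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_samples: int = 300
    n_classes: int = 5
    seed: int = 0


def generate_scm_features(spec: SCMSpec):
    """Draw a FactorTable plus the ground-truth role of every factor.

    Causes are standard Gaussians; the label discretizes their weighted sum
    plus noise into ``n_classes`` quantile bins; effects are a centered
    class coding of the label plus Gaussian noise; independents are pure
    Gaussian noise.
    """
    if spec.n_causes < 1:
        raise ConfigurationError("the SCM needs at least one cause")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    causes = rng.normal(size=(n, spec.n_causes))
    score = spec.effect_size * causes.sum(axis=1) + rng.normal(
        scale=spec.noise_sd, size=n
    )
    edges = np.quantile(score, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
    y = np.searchsorted(edges, score) + 1  # labels 1..n_classes

    coding = y - (spec.n_classes + 1) / 2.0  # centered class coding
    effects = coding[:, None] + rng.normal(
        scale=spec.noise_sd, size=(n, spec.n_effects)
    )
    independents = rng.normal(size=(n, spec.n_independent))

    ids = (
        [f"cause_{i}" for i in range(spec.n_causes)]
        + [f"effect_{i}" for i in range(spec.n_effects)]
        + [f"indep_{i}" for i in range(spec.n_independent)]
    )
    roles = {f: f.split("_")[0] for f in ids}
    table = FactorTable(
        values=np.concatenate([causes, effects, independents], axis=1),
        factor_ids=ids,
        label=y,
    )
    return table, roles


# --------------------------------------------------------------------------
# synthetic single-cell images
# --------------------------------------------------------------------------

# Versioned class-latent bands (5-class layout).  One row per class along a
# monotone severity axis; values are (low, high) uniform bands.
CLASS_BANDS_5 = {
    # class: (nc_ratio, nucleus axis ratio, centroid offset fraction)
    1: ((0.06, 0.14), (0.85, 1.00), (0.00, 0.12)),
    2: ((0.13, 0.24), (0.78, 0.95), (0.05, 0.18)),
    3: ((0.22, 0.36), (0.70, 0.88), (0.10, 0.25)),
    4: ((0.33, 0.48), (0.62, 0.82), (0.15, 0.35)),
    5: ((0.45, 0.60), (0.55, 0.75), (0.20, 0.45)),
}


def _interp_bands(n_classes: int) -> dict:
    """Resample the 5-class severity axis onto n_classes levels."""
    keys = sorted(CLASS_BANDS_5)
    src = np.array([[*CLASS_BANDS_5[k][0], *CLASS_BANDS_5[k][1], *CLASS_BANDS_5[k][2]]
                    for k in keys])
    pos = np.linspace(0, len(keys) - 1, n_classes)
    out = {}
    for c, p in enumerate(pos, start=1):
        row = np.array([np.interp(p, np.arange(len(keys)), src[:, j])
                        for j in range(6)])
        out[c] = ((row[0], row[1]), (row[2], row[3]), (row[4], row[5]))
    return out


@dataclass
class CellImageConfig:
    side: int = 64
    n_classes: int = 5
    cytoplasm_radius_frac: tuple = (0.28, 0.37)  # of image side
    cytoplasm_axis_ratio: tuple = (0.75, 1.0)
    background_level: float = 0.94
    cytoplasm_color: tuple = (0.74, 0.62, 0.80)
    nucleus_color: tuple = (0.34, 0.20, 0.44)
    texture_amplitude: float = 0.06
    n_texture_ids: int = 4
    confound_strength: float = 0.8  # P(texture id matches class) in confounded mode
    pixel_noise_sd: float = 0.015
    edge_softness: float = 1.0  # anti-aliasing width in pixels

    def bands(self) -> dict:
        return CLASS_BANDS_5 if self.n_classes == 5 else _interp_bands(self.n_classes)


@dataclass
class CellImageRecord:
    image: np.ndarray
    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    class_label: int
    latent: dict = field(default_factory=dict)
    seed: int = 0


def _ellipse_rho(side, center, a, b, theta):
    """Normalized elliptical radius field (rho <= 1 inside the ellipse)."""
    yy, xx = np.mgrid[0:side, 0:side]
    dx, dy = xx - center[0], yy - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def generate_cell_image(
    class_label: int,
    config: CellImageConfig | None = None,
    seed: int = 0,
    texture_id: int | None = None,
) -> CellImageRecord:
    """Render one cell with its truth masks and generative latents."""
    config = config or CellImageConfig()
    if not 1 <= class_label <= config.n_classes:
        raise ValidationError(
            f"class_label must be in 1..{config.n_classes}, got {class_label}"
        )
    rng = np.random.default_rng(seed)
    side = config.side
    nc_band, q_band, off_band = config.bands()[class_label]

    # cytoplasm ellipse
    a_c = rng.uniform(*config.cytoplasm_radius_frac) * side
    b_c = a_c * rng.uniform(*config.cytoplasm_axis_ratio)
    theta = rng.uniform(0, np.pi)
    center = np.array([side / 2, side / 2]) + rng.uniform(-2, 2, size=2) * side / 64

    # nucleus geometry from the class latents
    nc_target = rng.uniform(*nc_band)
    q = rng.uniform(*q_band)
    cell_area = np.pi * a_c * b_c
    a_n = np.sqrt(nc_target * cell_area / (np.pi * q))
    b_n = q * a_n
    a_n = min(a_n, 0.97 * a_c)
    b_n = min(b_n, 0.97 * b_c)
    offset_frac = rng.uniform(*off_band)
    phi = rng.uniform(0, 2 * np.pi)
    margin_a = max(a_c - a_n, 0.0)
    margin_b = max(b_c - b_n, 0.0)
    ct, st = np.cos(theta), np.sin(theta)
    du = 0.9 * offset_frac * margin_a * np.cos(phi)
    dv = 0.9 * offset_frac * margin_b * np.sin(phi)
    n_center = center + np.array([du * ct - dv * st, du * st + dv * ct])

    rho_c = _ellipse_rho(side, center, a_c, b_c, theta)
    rho_n = _ellipse_rho(side, n_center, a_n, b_n, theta)
    soft = config.edge_softness
    w_c = np.clip((1.0 - rho_c) * min(a_c, b_c) / soft + 0.5, 0.0, 1.0)
    w_n = np.clip((1.0 - rho_n) * min(a_n, b_n) / soft + 0.5, 0.0, 1.0)

    # nuisance texture on the cytoplasm: grating frequency/orientation + hue
    tid = int(texture_id) if texture_id is not None else int(
        rng.integers(config.n_texture_ids)
    )
    freqs = np.linspace(0.15, 0.55, config.n_texture_ids)
    angles = np.linspace(0, np.pi, config.n_texture_ids, endpoint=False)
    yy, xx = np.mgrid[0:side, 0:side]
    grating = np.sin(
        2 * np.pi * freqs[tid] * (xx * np.cos(angles[tid]) + yy * np.sin(angles[tid]))
        + rng.uniform(0, 2 * np.pi)
    )
    hue_shift = np.zeros(3)
    hue_shift[tid % 3] = 0.03 * (1 if tid % 2 == 0 else -1)

    img = np.full((side, side, 3), config.background_level)
    img += rng.normal(0, config.pixel_noise_sd, size=img.shape)
    cyt = np.asarray(config.cytoplasm_color) + hue_shift
    tex = config.texture_amplitude * grating
    for ch in range(3):
        layer = cyt[ch] + tex
        img[..., ch] = img[..., ch] * (1 - w_c) + layer * w_c
        img[..., ch] = img[..., ch] * (1 - w_n) + config.nucleus_color[ch] * w_n
    img = np.clip(img, 0.0, 1.0)

    nucleus_mask = rho_n <= 1.0
    cell_mask = rho_c <= 1.0
    cytoplasm_mask = cell_mask & ~nucleus_mask
    latent = {
        "nc_target": nc_target,
        "nc_band": nc_band,
        "nucleus_axis_ratio": q,
        "offset_frac": offset_frac,
        "cytoplasm_a": a_c,
        "cytoplasm_b": b_c,
        "nucleus_a": a_n,
        "nucleus_b": b_n,
        "theta": theta,
        "texture_id": tid,
        "center": center.tolist(),
        "nucleus_center": n_center.tolist(),
    }
    return CellImageRecord(
        image=img,
        nucleus_mask=nucleus_mask,
        cytoplasm_mask=cytoplasm_mask,
        class_label=class_label,
        latent=latent,
        seed=seed,
    )


CLASS_NAMES_5 = ["superficial", "intermediate", "parabasal", "lsil", "hsil"]


def generate_image_dataset(
    n_per_class: int,
    mode: str = "clean",
    seed: int = 0,
    out_dir=None,
    config: CellImageConfig | None = None,
):
    """Stratified synthetic dataset; optionally written to disk.

    Returns ``(ImageDataset, records)``.  On disk the layout is one PNG
    directory per class plus ``manifest.csv``, a ``masks/`` subfolder and a
    JSON file of all generative latents.
    """
    if n_per_class < 3:
        raise ConfigurationError("n_per_class must be >= 3")
    if mode not in ("clean", "confounded"):
        raise ConfigurationError(f"mode must be clean or confounded, got {mode!r}")
    config = config or CellImageConfig()
    rng = np.random.default_rng(seed)
    names = (
        CLASS_NAMES_5
        if config.n_classes == 5
        else [f"class{i}" for i in range(1, config.n_classes + 1)]
    )
    records, images, labels = [], [], []
    for c in range(1, config.n_classes + 1):
        for i in range(n_per_class):
            if mode == "confounded" and rng.random() < config.confound_strength:
                tid = (c - 1) % config.n_texture_ids
            else:
                tid = int(rng.integers(config.n_texture_ids))
            rec = generate_cell_image(
                c, config, seed=int(rng.integers(2**31 - 1)), texture_id=tid
            )
            records.append(rec)
            images.append(rec.image)
            labels.append(c)
    dataset = ImageDataset(
        images=np.stack(images), labels=np.array(labels), class_names=names
    )
    if out_dir is not None:
        _write_dataset(Path(out_dir), dataset, records, names)
    return dataset, records


def _write_dataset(out_dir, dataset, records, names):
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    rows, latents = [], {}
    counters = {}
    for rec in records:
        name = names[rec.class_label - 1]
        counters[name] = counters.get(name, 0) + 1
        fname = f"{name}/{name}_{counters[name]:04d}.png"
        (out_dir / name).mkdir(exist_ok=True)
        Image.fromarray((rec.image * 255).astype(np.uint8)).save(out_dir / fname)
        mask = (
            rec.nucleus_mask.astype(np.uint8) * 255 // 2
            + rec.cytoplasm_mask.astype(np.uint8) * 255
        )
        Image.fromarray(mask).save(out_dir / "masks" / Path(fname).name)
        rows.append({"filename": fname, "label": name})
        latents[fname] = {**rec.latent, "seed": rec.seed,
                          "class_label": rec.class_label}
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "latents.json", "w") as fh:
        json.dump(latents, fh, indent=1, default=float)


def nc_threshold_predict(nc_values: np.ndarray, config: CellImageConfig | None = None):
    """Oracle classifier: assign the class whose N/C band center is nearest.

    Used to audit that the generated dataset is learnable from morphology
    alone.
    """
    config = config or CellImageConfig()
    bands = config.bands()
    centers = np.array(
        [(bands[c][0][0] + bands[c][0][1]) / 2 for c in sorted(bands)]
    )
    nc = np.asarray(nc_values, dtype=float)
    return np.abs(nc[:, None] - centers[None, :]).argmin(axis=1) + 1
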