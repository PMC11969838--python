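"""Pairwise conditional-probability causality map over CNN feature maps.

After the final pooling layer of a convolutional network, each channel i of
a sample is a k x k non-negative activation grid F^i (post-ReLU).  Once the
stack is normalized to [0, 1] by the sample's single largest activation, the
entries can be read as feature-presence probabilities, and the conditional
probability of feature i given feature j is estimated as

    P(F^i | F^j) = max(F^i) * max(F^j) / sum(F^j)

with max/sum running over the k x k grid.  The numerator is the joint
presence of both features at their strongest locations; the denominator
normalizes by the total evidence for feature j.  Since every entry of F^i
is <= 1 and sum(F^j) >= max(F^j), the estimate always lies in [0, 1].
A channel with no activation anywhere (sum = 0) carries no conditional
evidence and its column is set to 0 by convention.

The n x n matrix of these estimates over all ordered channel pairs is the
causality map; flattened, it is one of the three segments fused into the
classifier head (see :mod:`causalcyto.pipeline`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ShapeError, ValidationError

__all__ = [
    "FeatureMapStack",
    "CausalityMap",
    "normalize_stack",
    "conditional_probability",
    "build_causality_map",
]


@dataclass
class FeatureMapStack:
    """Per-sample stack of n non-negative k x k feature maps."""

    maps: np.ndarray  # (n, k, k)
    normalized: bool = False
    channel_ids: Sequence[str] | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ShapeError(f"stack must be (n, k, k), got {self.maps.shape}")
        if np.any(self.maps < 0):
            raise ValidationError(
                "feature maps must be non-negative (post-ReLU activations)"
            )
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.maps.shape[0])]
        elif len(self.channel_ids) != self.maps.shape[0]:
            raise ShapeError("channel_ids length must match number of maps")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    @property
    def k(self) -> int:
        return self.maps.shape[1]


@dataclass
class CausalityMap:
    """n x n matrix with entry (i, j) = estimated P(F^i | F^j)."""

    values: np.ndarray
    channel_ids: Sequence[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=list(self.channel_ids), columns=list(self.channel_ids)
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CausalityMap":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), channel_ids=list(df.columns))

    def to_npz(self, path) -> None:
        np.savez(
            path,
            values=self.values,
            channel_ids=np.array(list(self.channel_ids), dtype=str),
        )

    @classmethod
    def from_npz(cls, path) -> "CausalityMap":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                values=data["values"], channel_ids=list(data["channel_ids"])
            )

    def plot(self, path=None, ax=None):
        """Render the map as a heat-map (PNG when ``path`` is given)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(self.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_xlabel("conditioning channel j")
        ax.set_ylabel("channel i")
        ax.figure.colorbar(im, ax=ax, label="P(F^i | F^j)")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def normalize_stack(stack: FeatureMapStack, per_map: bool = False) -> FeatureMapStack:
    """Scale activations to [0, 1] by the sample-wide maximum.

    The default divides every entry by the single largest activation across
    all n channels, preserving relative channel magnitudes.  ``per_map=True``
    normalizes each channel by its own maximum instead (every non-zero
    channel then peaks at exactly 1); it is exposed for comparison only.
    An all-zero stack is returned unchanged, flagged as normalized.
    """
    maps = stack.maps
    if per_map:
        peaks = maps.max(axis=(1, 2), keepdims=True)
        scaled = np.divide(maps, peaks, out=np.zeros_like(maps), where=peaks > 0)
    else:
        peak = maps.max()
        scaled = maps / peak if peak > 0 else maps.copy()
    return FeatureMapStack(maps=scaled, normalized=True, channel_ids=stack.channel_ids)


def _check_normalized(F: np.ndarray, name: str) -> None:
    if F.max(initial=0.0) > 1.0 + 1e-12:
        raise ValidationError(f"{name} is not normalized to [0, 1]")


def conditional_probability(Fi: np.ndarray, Fj: np.ndarray) -> float:
    """Estimate P(F^i | F^j) = max(F^i) max(F^j) / sum(F^j) for one pair."""
    Fi = np.asarray(Fi, dtype=float)
    Fj = np.asarray(Fj, dtype=float)
    if Fi.shape != Fj.shape:
        raise ShapeError(f"feature maps differ in shape: {Fi.shape} vs {Fj.shape}")
    _check_normalized(Fi, "F^i")
    _check_normalized(Fj, "F^j")
    denom = Fj.sum()
    if denom == 0:
        return 0.0
    return float(Fi.max() * Fj.max() / denom)


def build_causality_map(stack: FeatureMapStack) -> CausalityMap:
    """All ordered pairwise conditional probabilities of a normalized stack.

    Vectorized: entry (i, j) depends only on the per-channel maxima and the
    per-channel sums, so the full n x n map costs O(n^2) after one pass over
    the activations.
    """
    if stack.n_channels < 1:
        raise ShapeError("stack is empty")
    if not stack.normalized:
        raise ValidationError("stack must be normalized first (normalize_stack)")
    maxima = stack.maps.max(axis=(1, 2))
    sums = stack.maps.sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.outer(maxima, maxima / np.where(sums > 0, sums, 1.0))
    values[:, sums == 0] = 0.0
    return CausalityMap(values=values, channel_ids=list(stack.channel_ids))
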