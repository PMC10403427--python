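"""Per-pixel feature descriptors and feature-space similarity.

Pairwise registration in this package is driven by *feature* similarity
rather than raw pixel similarity: the photometric loss and the
cumulative-error weights both operate on per-pixel descriptor maps.  The
default extractor is a fixed, training-free multi-scale bank — Gaussian-
smoothed intensity plus first derivatives at three scales, each channel
standardized per image — which is deterministic, translation-equivariant up
to boundary effects, and invariant to global affine intensity changes by
construction.  A learned descriptor model can be plugged in through the
same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureMap",
    "DescriptorExtractor",
    "MultiscaleExtractor",
    "CallableExtractor",
    "extract_features",
    "feature_distance",
    "feature_photometric_loss",
    "get_extractor",
]


@dataclass
class FeatureMap:
    """Per-pixel descriptor planes of shape (rows, cols, C)."""

    channels: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[2] < 1:
            raise ValueError("feature map must have shape (rows, cols, C), C >= 1")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("feature map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[2]


@runtime_checkable
class DescriptorExtractor(Protocol):
    name: str
    deterministic: bool

    def __call__(self, image: np.ndarray) -> FeatureMap: ...


def _standardize(plane: np.ndarray) -> np.ndarray:
    # Exact affine-intensity invariance: no epsilon in the scale unless the
    # plane is (numerically) constant, in which case the channel is zeroed.
    mu = plane.mean()
    sd = plane.std()
    if sd < 1e-12:
        return np.zeros_like(plane)
    return (plane - mu) / sd


@dataclass
class MultiscaleExtractor:
    """Default descriptor: smoothed intensity + (dy, dx) derivatives at
    ``sigmas`` scales, every channel standardized to zero mean / unit
    variance per image."""

    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)
    name: str = "multiscale"
    deterministic: bool = field(default=True)

    def __call__(self, image: np.ndarray) -> FeatureMap:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("expected a 2-D section image")
        planes = []
        for s in self.sigmas:
            sm = ndimage.gaussian_filter(image, s, mode="nearest")
            gy = ndimage.gaussian_filter(image, s, order=(1, 0), mode="nearest")
            gx = ndimage.gaussian_filter(image, s, order=(0, 1), mode="nearest")
            planes += [_standardize(sm), _standardize(gy), _standardize(gx)]
        return FeatureMap(np.stack(planes, axis=-1), self.name)


@dataclass
class CallableExtractor:
    """Adapter wrapping an external per-pixel descriptor function."""

    fn: Callable[[np.ndarray], np.ndarray]
    name: str = "external"
    deterministic: bool = True

    def __call__(self, image: np.ndarray) -> FeatureMap:
        return FeatureMap(np.atleast_3d(self.fn(np.asarray(image))), self.name)


def get_extractor(spec: str = "multiscale") -> DescriptorExtractor:
    """Resolve an extractor by config name (``multiscale`` is the default)."""
    if spec == "multiscale":
        return MultiscaleExtractor()
    raise ValueError(f"unknown descriptor extractor {spec!r}")


def extract_features(image: np.ndarray, extractor: DescriptorExtractor | None = None) -> FeatureMap:
    if extractor is None:
        extractor = MultiscaleExtractor()
    return extractor(image)


def _check_congruent(a: FeatureMap, b: FeatureMap) -> None:
    if a.channels.shape != b.channels.shape:
        raise ValueError(
            f"feature shapes differ: {a.channels.shape} vs {b.channels.shape}"
        )
    if a.extractor_id != b.extractor_id:
        raise ValueError(
            f"feature maps come from different extractors: "
            f"{a.extractor_id!r} vs {b.extractor_id!r}"
        )


def feature_distance(a: FeatureMap, b: FeatureMap) -> float:
    """Euclidean (L2) norm of the elementwise descriptor difference, over all
    pixels and channels — the inter-section distance d_i used for
    cumulative-error weighting."""
    _check_congruent(a, b)
    return float(np.linalg.norm(a.channels - b.channels))


def feature_photometric_loss(ref_feat: FeatureMap, warped_feat: FeatureMap) -> float:
    """Squared-L2 feature photometric loss, normalized by the pixel·channel
    count so its magnitude is resolution-independent.

    ``warped_feat`` must be extracted from the *warped image* (features of
    the warp, not a warp of the features).
    """
    _check_congruent(ref_feat, warped_feat)
    diff = ref_feat.channels - warped_feat.channels
    return float(np.sum(diff * diff) / diff.size)
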