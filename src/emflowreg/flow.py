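"""Dense displacement fields, rigid transforms, and warping.

The package-wide convention is *backward* (target-to-source) mapping: a flow
``F`` warps an image via ``out(p) = in(p + F(p))``, sampled bilinearly for
intensities and nearest-neighbor for labels.  Flow components are stored as
two planes ``(dy, dx)`` in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import ndimage

__all__ = [
    "FlowField",
    "RigidTransform",
    "warp_image",
    "warp_labels",
    "warp_validity_mask",
    "scale_flow",
    "compose_flows",
    "rigid_to_flow",
    "apply_rigid",
    "resample_flow",
    "invert_flow",
    "read_flow",
    "write_flow",
]


@dataclass
class FlowField:
    """Per-pixel 2-D displacement map in pixels, backward convention."""

    dy: np.ndarray
    dx: np.ndarray

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=np.float64)
        self.dx = np.asarray(self.dx, dtype=np.float64)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx must share one shape")
        if self.dy.ndim != 2:
            raise ValueError("flow planes must be 2-D")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("flow contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "FlowField":
        return cls(np.zeros(shape), np.zeros(shape))

    @classmethod
    def constant(cls, shape: tuple[int, int], dy: float, dx: float) -> "FlowField":
        return cls(np.full(shape, float(dy)), np.full(shape, float(dx)))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)


@dataclass
class RigidTransform:
    """Rotation by ``theta`` (radians, about the image center) followed by a
    translation ``t = (ty, tx)`` in pixels, in (row, col) coordinates."""

    theta: float = 0.0
    t: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (-np.pi < self.theta <= np.pi):
            # wrap into (-pi, pi]
            th = (self.theta + np.pi) % (2 * np.pi) - np.pi
            self.theta = np.pi if th == -np.pi else th
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite translation")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "RigidTransform":
        Rinv = self.matrix.T
        return RigidTransform(-self.theta, tuple(-(Rinv @ np.asarray(self.t))))

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return self ∘ inner (apply ``inner`` first, about a shared center)."""
        t = self.matrix @ np.asarray(inner.t) + np.asarray(self.t)
        return RigidTransform(self.theta + inner.theta, tuple(t))

    def apply_points(self, pts: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Forward-map (row, col) points: q = R (p - c) + c + t."""
        pts = np.asarray(pts, dtype=float)
        return (pts - center) @ self.matrix.T + center + np.asarray(self.t)


def _sample_coords(flow: FlowField) -> np.ndarray:
    rows, cols = flow.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr + flow.dy, cc + flow.dx])


def warp_image(image: np.ndarray, flow: FlowField, fill: str = "zeros") -> np.ndarray:
    """Backward-warp ``image`` by ``flow`` with bilinear interpolation.

    ``fill`` controls samples outside the image: ``zeros`` pads with 0,
    ``edge`` clamps to the border value.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != flow.shape:
        raise ValueError(f"image shape {image.shape} != flow shape {flow.shape}")
    coords = _sample_coords(flow)
    if fill == "zeros":
        # pad one zero pixel so partially-outside samples blend with the fill
        # value per neighbor instead of being zeroed wholesale
        padded = np.pad(image, 1, mode="constant")
        return ndimage.map_coordinates(
            padded, coords + 1.0, order=1, mode="constant", cval=0.0
        )
    if fill == "edge":
        return ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    raise ValueError(f"unknown fill policy {fill!r}")


def warp_validity_mask(flow: FlowField) -> np.ndarray:
    """Boolean mask of pixels whose sample location lies inside the image."""
    rows, cols = flow.shape
    coords = _sample_coords(flow)
    return (
        (coords[0] >= 0)
        & (coords[0] <= rows - 1)
        & (coords[1] >= 0)
        & (coords[1] <= cols - 1)
    )


def warp_labels(labels: np.ndarray, flow: FlowField) -> np.ndarray:
    """Backward-warp an integer label map with nearest-neighbor sampling;
    out-of-bounds samples become background (0)."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integer-typed")
    if labels.shape != flow.shape:
        raise ValueError(f"label shape {labels.shape} != flow shape {flow.shape}")
    coords = _sample_coords(flow)
    rows, cols = labels.shape
    # half-up rounding to the nearest source pixel
    yy = np.floor(coords[0] + 0.5).astype(np.int64)
    xx = np.floor(coords[1] + 0.5).astype(np.int64)
    valid = (yy >= 0) & (yy < rows) & (xx >= 0) & (xx < cols)
    out = np.zeros_like(labels)
    out[valid] = labels[yy[valid], xx[valid]]
    return out


def scale_flow(flow: FlowField, alpha: float) -> FlowField:
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return FlowField(flow.dy * alpha, flow.dx * alpha)


def compose_flows(outer: FlowField, inner: FlowField) -> FlowField:
    """Flow equivalent to warping by ``inner`` then by ``outer``.

    ``F(p) = outer(p) + inner(p + outer(p))`` with bilinear, edge-clamped
    sampling of the inner field, so ``warp(img, F) ≈ warp(warp(img, inner),
    outer)`` up to interpolation error.
    """
    if outer.shape != inner.shape:
        raise ValueError("flow shapes differ")
    coords = _sample_coords(outer)
    dy = ndimage.map_coordinates(inner.dy, coords, order=1, mode="nearest")
    dx = ndimage.map_coordinates(inner.dx, coords, order=1, mode="nearest")
    return FlowField(outer.dy + dy, outer.dx + dx)


def _image_center(shape: tuple[int, int]) -> np.ndarray:
    return np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])


def rigid_to_flow(T: RigidTransform, shape: tuple[int, int]) -> FlowField:
    """Backward flow such that ``warp_image(img, F)`` applies ``T`` to the
    image: each output pixel q samples the source at R⁻¹(q − c − t) + c."""
    rows, cols = shape
    c = _image_center(shape)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    q = np.stack([rr, cc], axis=-1).astype(float)
    p = (q - c - np.asarray(T.t)) @ T.matrix + c  # (q-c-t) @ R^T.T == R^-1 (q-c-t)
    d = p - q
    return FlowField(d[..., 0], d[..., 1])


def apply_rigid(image: np.ndarray, T: RigidTransform, fill: str = "zeros") -> np.ndarray:
    return warp_image(image, rigid_to_flow(T, np.asarray(image).shape), fill=fill)


def resample_flow(flow: FlowField, shape: tuple[int, int]) -> FlowField:
    """Bilinearly resample a flow to a new shape, rescaling displacement
    values by the per-axis zoom factor."""
    ry = shape[0] / flow.shape[0]
    rx = shape[1] / flow.shape[1]
    dy = ndimage.zoom(flow.dy, (shape[0] / flow.shape[0], shape[1] / flow.shape[1]),
                      order=1, mode="nearest", grid_mode=True) * ry
    dx = ndimage.zoom(flow.dx, (shape[0] / flow.shape[0], shape[1] / flow.shape[1]),
                      order=1, mode="nearest", grid_mode=True) * rx
    return FlowField(dy, dx)


def invert_flow(flow: FlowField, iterations: int = 20) -> FlowField:
    """Approximate inverse displacement field by fixed-point iteration:
    find G with G(p) + F(p + G(p)) = 0, so warping by G undoes warping by F
    (up to interpolation error; converges for smooth, moderate fields)."""
    g = FlowField.zeros(flow.shape)
    for _ in range(iterations):
        coords = _sample_coords(g)
        fy = ndimage.map_coordinates(flow.dy, coords, order=1, mode="nearest")
        fx = ndimage.map_coordinates(flow.dx, coords, order=1, mode="nearest")
        g = FlowField(-fy, -fx)
    return g


def write_flow(flow: FlowField, path, dataset_key: str = "flow") -> None:
    """Serialize as a (2, rows, cols) float dataset, channel order (dy, dx)."""
    with h5py.File(path, "w") as f:
        f.create_dataset(dataset_key, data=np.stack([flow.dy, flow.dx]).astype(np.float32))


def read_flow(path, dataset_key: str = "flow") -> FlowField:
    with h5py.File(path, "r") as f:
        arr = f[dataset_key][()]
    return FlowField(arr[0], arr[1])
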