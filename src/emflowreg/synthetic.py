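"""Synthetic deformations and phantoms with known ground truth.

Real serial-section data acquires nonlinear in-plane deformation during
sectioning.  The simulation protocol mirrors the standard evaluation setup
for this problem: thin-plate-spline (TPS) warps driven by displacement
vectors sampled from a zero-mean normal distribution at control points
placed uniformly over the section, applied to otherwise clean images whose
original geometry serves as ground truth.  Tilted-cylinder neurite
phantoms provide labeled stacks whose per-section centroids follow known
straight axes — the geometry the cumulative-error model assumes — so
drift-compensation experiments have an analytic reference.

All randomness flows from a single seed through named substreams
(controls, vectors, texture, ...), so components are independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

from .flow import FlowField, invert_flow, warp_image, warp_labels
from .stack_io import LabelStack, SectionStack

__all__ = [
    "TPSDeformSpec",
    "PhantomSpec",
    "tps_deform",
    "make_phantom",
    "inject_drift",
    "make_registration_pairs",
    "make_textured_image",
    "axial_subsample",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF  # stable across processes
    ss = np.random.SeedSequence([seed, tag])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class TPSDeformSpec:
    """Thin-plate-spline deformation: ``n_control`` random locations, each
    displaced by a vector with components ~ N(0, sigma_px²); locations are
    uniform over the image minus a ``margin_px`` border."""

    n_control: int = 10
    sigma_px: float = 4.0
    margin_px: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3:
            raise ValueError("need at least 3 control points")
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")


def _sample_controls(
    shape: tuple[int, int], spec: TPSDeformSpec, attempt: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    rng_pos = _substream(spec.seed + attempt, "controls")
    rng_vec = _substream(spec.seed + attempt, "vectors")
    m = min(spec.margin_px, (min(shape) - 1) / 4.0)
    pts = np.column_stack(
        [
            rng_pos.uniform(m, shape[0] - 1 - m, spec.n_control),
            rng_pos.uniform(m, shape[1] - 1 - m, spec.n_control),
        ]
    )
    vecs = rng_vec.normal(0.0, spec.sigma_px, size=(spec.n_control, 2))
    return pts, vecs


def _controls_degenerate(pts: np.ndarray) -> bool:
    centered = pts - pts.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-8) < 2


def boundary_anchors(shape: tuple[int, int]) -> np.ndarray:
    """Zero-displacement anchor locations (corners and edge midpoints) that
    pin the section frame so the spline's affine part cannot translate or
    shear the whole image; deformation stays local to the random controls."""
    r, c = shape[0] - 1, shape[1] - 1
    return np.array(
        [
            [0, 0], [0, c], [r, 0], [r, c],
            [0, c / 2], [r, c / 2], [r / 2, 0], [r / 2, c],
        ],
        dtype=float,
    )


def tps_fit_field(
    pts: np.ndarray, vecs: np.ndarray, shape: tuple[int, int]
) -> FlowField:
    """Dense TPS interpolation (r²·log r radial basis plus affine part) of
    the control displacements, evaluated at every pixel."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    interp = RBFInterpolator(pts, vecs, kernel="thin_plate_spline", degree=1)
    dense = interp(grid).reshape(rows, cols, 2)
    return FlowField(dense[..., 0], dense[..., 1])


def tps_deform(
    image: np.ndarray, spec: TPSDeformSpec
) -> tuple[np.ndarray, FlowField]:
    """Deform a section by a random TPS field; returns the warped image and
    the ground-truth field in the backward convention (so
    ``warp_image(image, field)`` reproduces the deformed image).

    Degenerate (collinear) control draws are resampled from the next
    substream.
    """
    image = np.asarray(image, dtype=np.float64)
    if spec.sigma_px == 0:
        return image.copy(), FlowField.zeros(image.shape)
    for attempt in range(16):
        pts, vecs = _sample_controls(image.shape, spec, attempt)
        if not _controls_degenerate(pts):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not sample non-degenerate TPS control points")
    anchors = boundary_anchors(image.shape)
    pts = np.vstack([pts, anchors])
    vecs = np.vstack([vecs, np.zeros_like(anchors)])
    fieldf = tps_fit_field(pts, vecs, image.shape)
    deformed = warp_image(image, fieldf, fill="edge")
    return deformed, fieldf


@dataclass(frozen=True)
class PhantomSpec:
    """Tilted-cylinder neurite phantom.

    Each neurite is a disk whose center moves linearly with section index
    (a tilted cylinder); ``tilt_max_px`` bounds the per-section (dy, dx)
    slope, drawn uniformly per neurite.  Intensities combine a membrane
    ring, per-neurite interior texture that travels with the disk, a static
    background texture, and per-section sensor noise.  ``margin_px``
    reserves an empty border around the placement region — set it to the
    largest drift you intend to inject so tubes survive the translation.
    """

    n_sections: int = 16
    rows: int = 160
    cols: int = 160
    n_neurites: int = 8
    radius_range: tuple[float, float] = (5.0, 9.0)
    tilt_max_px: float = 0.5
    noise_sigma: float = 0.02
    contrast: float = 0.55
    margin_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 3:
            raise ValueError("phantom needs at least 3 sections")
        if self.n_neurites < 1:
            raise ValueError("need at least one neurite")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    z = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="wrap")
    z -= z.min()
    span = z.max()
    return z / span if span > 0 else z


def _place_centers(
    spec: PhantomSpec, radii: np.ndarray, tilts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample non-overlapping start centers such that every tube
    stays inside the frame across all sections."""
    centers = np.zeros((spec.n_neurites, 2))
    nz = spec.n_sections - 1
    for k in range(spec.n_neurites):
        r = radii[k]
        m = spec.margin_px
        # frame bounds valid for the whole tube extent
        lo_r = m + r + 2 + max(0.0, -tilts[k, 0] * nz)
        hi_r = spec.rows - 1 - m - r - 2 - max(0.0, tilts[k, 0] * nz)
        lo_c = m + r + 2 + max(0.0, -tilts[k, 1] * nz)
        hi_c = spec.cols - 1 - m - r - 2 - max(0.0, tilts[k, 1] * nz)
        if hi_r <= lo_r or hi_c <= lo_c:
            raise ValueError("infeasible packing: tube cannot stay inside the frame")
        for _ in range(2000):
            cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
            if all(
                np.linalg.norm(cand - centers[j]) > radii[k] + radii[j] + 3
                for j in range(k)
            ):
                centers[k] = cand
                break
        else:
            raise ValueError("infeasible packing: could not place all neurites")
    return centers


def make_phantom(
    spec: PhantomSpec,
) -> tuple[SectionStack, LabelStack, np.ndarray]:
    """Build a tilted-cylinder phantom.

    Returns ``(stack, labels, centroids)`` where ``centroids[i, k]`` is the
    ground-truth (row, col) center of neurite ``k`` (label ``k+1``) on
    section ``i``.
    """
    rng_geom = _substream(spec.seed, "geometry")
    rng_tex = _substream(spec.seed, "texture")
    rng_noise = _substream(spec.seed, "noise")

    radii = rng_geom.uniform(*spec.radius_range, size=spec.n_neurites)
    tilts = rng_geom.uniform(
        -spec.tilt_max_px, spec.tilt_max_px, size=(spec.n_neurites, 2)
    )
    # zero-mean tilts: the consensus frame of the endpoints carries no net
    # in-plane shift, mimicking a block whose axis is the stacking axis
    tilts -= tilts.mean(axis=0, keepdims=True)
    centers0 = _place_centers(spec, radii, tilts, rng_geom)

    background = 0.45 + 0.25 * _smooth_noise(rng_tex, (spec.rows, spec.cols), 3.0)
    # per-neurite interior texture patch, sampled in disk-local coordinates
    pad = 4
    patches = []
    for k in range(spec.n_neurites):
        side = int(np.ceil(2 * radii[k])) + 2 * pad
        patches.append(_smooth_noise(rng_tex, (side, side), 1.5))

    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    data = np.empty((spec.n_sections, spec.rows, spec.cols))
    labels = np.zeros((spec.n_sections, spec.rows, spec.cols), dtype=np.int32)
    centroids = np.empty((spec.n_sections, spec.n_neurites, 2))
    for i in range(spec.n_sections):
        img = background.copy()
        for k in range(spec.n_neurites):
            c = centers0[k] + tilts[k] * i
            centroids[i, k] = c
            dist = np.hypot(rr - c[0], cc - c[1])
            disk = dist <= radii[k]
            ring = (dist <= radii[k]) & (dist >= radii[k] - 1.5)
            # sample the neurite's texture patch at disk-local coordinates,
            # so the texture travels (sub-pixel) with the centroid
            patch = patches[k]
            off = (np.asarray(patch.shape) - 1) / 2.0
            py = rr[disk] - c[0] + off[0]
            px = cc[disk] - c[1] + off[1]
            tex = ndimage.map_coordinates(
                patch, np.stack([py, px]), order=1, mode="nearest"
            )
            img[disk] = 0.35 + spec.contrast * 0.5 * tex
            img[ring] = 1.0 - spec.contrast
            labels[i][disk] = k + 1
        img = img + rng_noise.normal(0.0, spec.noise_sigma, img.shape)
        data[i] = np.clip(img, 0.0, 1.0)
    return SectionStack(data), LabelStack(labels), centroids


def inject_drift(
    stack: SectionStack, delta
) -> tuple[SectionStack, list[FlowField]]:
    """Translate section i by the cumulative sum Σ_{j≤i} delta_j — the
    constructible analogue of accumulated registration error e_i.

    ``delta`` is a constant (dy, dx) pair or one pair per section (the
    first entry applies to section 1; section 0 never moves).  Returns the
    drifted stack and the per-section ground-truth cumulative fields
    (backward convention: warping the *original* section by the field
    yields the drifted one).
    """
    delta = np.asarray(delta, dtype=np.float64)
    if delta.ndim == 1:
        deltas = np.tile(delta, (stack.n, 1))
        deltas[0] = 0.0
    else:
        if delta.shape != (stack.n, 2):
            raise ValueError("per-section delta must have shape (n, 2)")
        deltas = delta.copy()
        deltas[0] = 0.0
    cum = np.cumsum(deltas, axis=0)
    out = np.empty_like(stack.data)
    fields: list[FlowField] = []
    for i in range(stack.n):
        # drifted(p) = original(p - e_i): content moves *by* +e_i
        f = FlowField.constant(stack.shape, -cum[i, 0], -cum[i, 1])
        fields.append(f)
        out[i] = stack[i] if np.all(cum[i] == 0) else warp_image(stack[i], f, fill="edge")
    return SectionStack(out), fields


def drift_labels(labels: LabelStack, fields: Sequence[FlowField]) -> LabelStack:
    """Apply per-section drift fields (from :func:`inject_drift`) to a label
    stack with nearest-neighbor sampling."""
    out = np.empty_like(labels.data)
    for i in range(labels.n):
        out[i] = warp_labels(labels[i], fields[i])
    return LabelStack(out)


def make_textured_image(
    shape: tuple[int, int], seed: int = 0, scale: float = 2.0
) -> np.ndarray:
    """A band-limited random texture in [0, 1] with structure at ``scale``
    px — a generic stand-in for a well-textured EM section."""
    rng = _substream(seed, "textured_image")
    fine = _smooth_noise(rng, shape, scale)
    coarse = _smooth_noise(rng, shape, 4 * scale)
    img = 0.65 * fine + 0.35 * coarse
    return np.clip(img, 0.0, 1.0)


def make_registration_pairs(
    n_pairs: int,
    spec: TPSDeformSpec,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    source: Optional[SectionStack] = None,
) -> list[tuple[np.ndarray, np.ndarray, FlowField]]:
    """Training/evaluation pairs: the reference is a clean section, the
    moving image its TPS-deformed copy, and the stored field is the
    ground-truth backward registration flow (the inverse of the deformation
    field), i.e. ``warp_image(moving, field) ≈ reference``.

    Sections come from ``source`` (cycled) when given, otherwise from
    random textures.  Deterministic for a fixed seed.
    """
    pairs = []
    for k in range(n_pairs):
        if source is not None:
            ref = np.asarray(source[k % source.n], dtype=np.float64)
        else:
            ref = make_textured_image(shape, seed=seed * 100_003 + k)
        pair_spec = TPSDeformSpec(
            n_control=spec.n_control,
            sigma_px=spec.sigma_px,
            margin_px=spec.margin_px,
            seed=spec.seed + 7919 * k + seed,
        )
        moving, deform = tps_deform(ref, pair_spec)
        gt = invert_flow(deform) if spec.sigma_px > 0 else deform
        pairs.append((moving, ref, gt))
    return pairs


def axial_subsample(stack: SectionStack, keep_every: int = 8) -> SectionStack:
    """Keep every k-th section (default 8) — reproduces the thickness
    protocol that turns an isotropic FIB volume into ssEM-like spacing."""
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    return SectionStack(
        stack.data[::keep_every].copy(),
        pixel_size_nm=stack.pixel_size_nm,
        thickness_nm=(stack.thickness_nm or 0) * keep_every or None,
    )
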