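"""Pairwise dense-flow estimation between two sections.

Two backends implement one estimator interface:

* :class:`ClassicalFlowEstimator` — a deterministic coarse-to-fine pyramid
  (five octaves by default) with iterative multi-channel Lucas–Kanade
  refinement computed on *descriptor maps* rather than raw pixels.  It is
  training-free and serves as the default backend and test oracle.
* :class:`PWCLiteModel` — a lightweight coarse-to-fine cost-volume matcher
  in the PWC style: a frozen descriptor pyramid, per-level local
  correlation volumes, and a soft-argmax flow decoder whose small parameter
  vector is trained with the unsupervised losses
  ``L = L_ph + λ_s·L_smooth + λ_a·L_aug`` (feature photometric, flow
  smoothness, and augmentation-consistency terms).

Both return backward flows: ``warp_image(moving, F) ≈ reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .descriptors import (
    DescriptorExtractor,
    MultiscaleExtractor,
    extract_features,
    feature_photometric_loss,
)
from .flow import (
    FlowField,
    RigidTransform,
    apply_rigid,
    resample_flow,
    warp_image,
    warp_validity_mask,
)

__all__ = [
    "FlowEstimator",
    "PyramidConfig",
    "LossWeights",
    "ClassicalFlowEstimator",
    "PWCLiteModel",
    "estimate_flow_classical",
    "estimate_flow_learned",
    "smoothness_loss",
    "charbonnier",
    "AugmentationSample",
    "sample_augmentation",
    "augmentation_loss",
    "train_unsupervised",
]

MIN_LEVEL_SIDE = 8


@runtime_checkable
class FlowEstimator(Protocol):
    name: str

    def estimate(self, moving: np.ndarray, reference: np.ndarray) -> FlowField: ...


@dataclass(frozen=True)
class PyramidConfig:
    """Coarse-to-fine pyramid settings (five octaves, 2x per octave)."""

    octaves: int = 5
    downscale: float = 2.0
    iterations_per_level: int = 10
    window: int = 9
    global_init: bool = True  # phase-correlation translation seed at the coarsest level

    def __post_init__(self) -> None:
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.downscale <= 1:
            raise ValueError("downscale must exceed 1")

    def validate_for(self, shape: tuple[int, int]) -> None:
        side = min(shape) / self.downscale ** (self.octaves - 1)
        if side < MIN_LEVEL_SIDE:
            raise ValueError(
                f"image shape {shape} too small for {self.octaves} octaves "
                f"(coarsest side {side:.1f} < {MIN_LEVEL_SIDE} px)"
            )

    @classmethod
    def for_shape(
        cls, shape: tuple[int, int], max_octaves: int = 5, min_side: int = 16, **kw
    ) -> "PyramidConfig":
        """Largest feasible pyramid capped at ``max_octaves``; the coarsest
        level keeps at least ``min_side`` px so windowed least squares still
        sees structure there."""
        octaves = 1
        side = min(shape)
        while octaves < max_octaves and side / 2.0 >= max(min_side, MIN_LEVEL_SIDE):
            side /= 2.0
            octaves += 1
        return cls(octaves=octaves, **kw)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the smoothness and augmentation terms relative to the
    (normalized) feature photometric loss."""

    lambda_smooth: float = 5.0
    lambda_aug: float = 0.25

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_smooth) and np.isfinite(self.lambda_aug)):
            raise ValueError("loss weights must be finite")
        if self.lambda_smooth < 0 or self.lambda_aug < 0:
            raise ValueError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# shared pyramid helpers


def _pyramid(image: np.ndarray, n_levels: int, downscale: float) -> list[np.ndarray]:
    """Level 0 is full resolution; each level shrinks by ``downscale``."""
    levels = [np.asarray(image, dtype=np.float64)]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        shape = (
            max(MIN_LEVEL_SIDE, int(round(prev.shape[0] / downscale))),
            max(MIN_LEVEL_SIDE, int(round(prev.shape[1] / downscale))),
        )
        levels.append(resize(prev, shape, anti_aliasing=True, mode="edge"))
    return levels


def _warp_planes(planes: np.ndarray, flow: FlowField) -> np.ndarray:
    out = np.empty_like(planes)
    rows, cols = flow.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr + flow.dy, cc + flow.dx])
    for c in range(planes.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            planes[..., c], coords, order=1, mode="nearest"
        )
    return out


# ---------------------------------------------------------------------------
# classical estimator: multi-channel pyramidal Lucas–Kanade on descriptors


def _masked_residual(mov_feat: np.ndarray, ref_feat: np.ndarray, flow: FlowField) -> float:
    wm = _warp_planes(mov_feat, flow)
    valid = warp_validity_mask(flow)
    if valid.sum() < 0.25 * valid.size:
        return np.inf
    diff = (wm - ref_feat)[valid]
    return float(np.mean(diff * diff))


def _lk_refine(
    mov_feat: np.ndarray,
    ref_feat: np.ndarray,
    flow: FlowField,
    iterations: int,
    window: int,
) -> FlowField:
    dy, dx = flow.dy.copy(), flow.dx.copy()
    reg = 1e-4
    max_step = 1.0  # px per iteration; keeps the linearization valid
    best = None
    best_res = np.inf
    for _ in range(iterations):
        f = FlowField(dy, dx)
        wm = _warp_planes(mov_feat, f)
        valid = warp_validity_mask(f).astype(float)
        it = (wm - ref_feat) * valid[..., None]
        res = float(np.sum(it * it) / max(valid.sum() * wm.shape[2], 1.0))
        if res < best_res:
            best_res = res
            best = (dy.copy(), dx.copy())
        a11 = np.zeros(dy.shape)
        a12 = np.zeros(dy.shape)
        a22 = np.zeros(dy.shape)
        b1 = np.zeros(dy.shape)
        b2 = np.zeros(dy.shape)
        for c in range(wm.shape[2]):
            gy, gx = np.gradient(wm[..., c])
            gy *= valid  # out-of-frame samples must not drive the update
            gx *= valid
            a11 += ndimage.uniform_filter(gy * gy, window, mode="nearest")
            a12 += ndimage.uniform_filter(gy * gx, window, mode="nearest")
            a22 += ndimage.uniform_filter(gx * gx, window, mode="nearest")
            b1 -= ndimage.uniform_filter(gy * it[..., c], window, mode="nearest")
            b2 -= ndimage.uniform_filter(gx * it[..., c], window, mode="nearest")
        a11 += reg
        a22 += reg
        det = a11 * a22 - a12 * a12
        sy = (a22 * b1 - a12 * b2) / det
        sx = (a11 * b2 - a12 * b1) / det
        np.clip(sy, -max_step, max_step, out=sy)
        np.clip(sx, -max_step, max_step, out=sx)
        sy = ndimage.gaussian_filter(sy, 1.0, mode="nearest")
        sx = ndimage.gaussian_filter(sx, 1.0, mode="nearest")
        dy += sy
        dx += sx
        if max(np.abs(sy).mean(), np.abs(sx).mean()) < 0.01:
            break
    # keep the iterate with the lowest feature residual (guards divergence)
    wm = _warp_planes(mov_feat, FlowField(dy, dx))
    if float(np.mean((wm - ref_feat) ** 2)) <= best_res or best is None:
        return FlowField(dy, dx)
    return FlowField(*best)


def estimate_flow_classical(
    moving: np.ndarray,
    reference: np.ndarray,
    config: Optional[PyramidConfig] = None,
    extractor: Optional[DescriptorExtractor] = None,
) -> FlowField:
    """Deterministic coarse-to-fine flow on descriptor maps.

    At each pyramid level the upsampled coarser flow is refined by iterative
    windowed least squares (Lucas–Kanade normal equations) against the
    descriptor maps of both images.
    """
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference shapes differ")
    if config is None:
        config = PyramidConfig.for_shape(moving.shape)
    config.validate_for(moving.shape)
    extractor = extractor or MultiscaleExtractor()

    mov_levels = _pyramid(moving, config.octaves, config.downscale)
    ref_levels = _pyramid(reference, config.octaves, config.downscale)
    flow: Optional[FlowField] = None
    for level in reversed(range(config.octaves)):
        mf = extractor(mov_levels[level]).channels
        rf = extractor(ref_levels[level]).channels
        shape = mov_levels[level].shape
        if flow is None:
            flow = FlowField.zeros(shape)
            if config.global_init:
                # large shared translations (drift) exceed the Lucas-Kanade
                # capture range; seed the coarsest level by phase correlation,
                # but only keep the seed when it actually lowers the masked
                # feature residual (on purely local deformation the periodic
                # correlation peak can be spurious)
                shift, _, _ = phase_cross_correlation(
                    reference, moving, upsample_factor=4
                )
                scale = shape[0] / moving.shape[0], shape[1] / moving.shape[1]
                candidate = FlowField.constant(
                    shape, -shift[0] * scale[0], -shift[1] * scale[1]
                )
                if _masked_residual(mf, rf, candidate) < _masked_residual(mf, rf, flow):
                    flow = candidate
        else:
            flow = resample_flow(flow, shape)
        flow = _lk_refine(mf, rf, flow, config.iterations_per_level, config.window)
    assert flow is not None
    return flow


@dataclass
class ClassicalFlowEstimator:
    """:class:`FlowEstimator` wrapper around :func:`estimate_flow_classical`."""

    config: Optional[PyramidConfig] = None
    extractor: Optional[DescriptorExtractor] = None
    name: str = "classical"

    def estimate(self, moving: np.ndarray, reference: np.ndarray) -> FlowField:
        return estimate_flow_classical(moving, reference, self.config, self.extractor)


# ---------------------------------------------------------------------------
# losses


def charbonnier(x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Robust penalty ρ(x) = sqrt(x² + ε²) − ε (zero at zero, ~|x| for large x)."""
    return np.sqrt(x * x + eps * eps) - eps


def smoothness_loss(flow: FlowField, eps: float = 1e-3) -> float:
    """First-order flow smoothness: the mean Charbonnier penalty of the
    horizontal and vertical finite differences of both flow components."""
    terms = []
    for plane in (flow.dy, flow.dx):
        terms.append(charbonnier(np.diff(plane, axis=0), eps))
        terms.append(charbonnier(np.diff(plane, axis=1), eps))
    total = sum(t.sum() for t in terms)
    count = sum(t.size for t in terms)
    return float(total / count)


@dataclass(frozen=True)
class AugmentationSample:
    """A sampled spatial (small rigid) + appearance (gain/bias) transform."""

    spatial: RigidTransform
    gain: float = 1.0
    bias: float = 0.0

    def apply_image(self, image: np.ndarray) -> np.ndarray:
        out = apply_rigid(image, self.spatial, fill="edge")
        return np.clip(out * self.gain + self.bias, 0.0, 1.0)


def sample_augmentation(
    rng: np.random.Generator,
    max_rot_deg: float = 3.0,
    max_shift_px: float = 2.0,
    max_gain: float = 0.15,
    max_bias: float = 0.05,
) -> AugmentationSample:
    theta = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
    t = tuple(rng.uniform(-max_shift_px, max_shift_px, size=2))
    gain = 1.0 + rng.uniform(-max_gain, max_gain)
    bias = rng.uniform(-max_bias, max_bias)
    return AugmentationSample(RigidTransform(theta, t), gain, bias)


def _transport_flow(flow: FlowField, T: RigidTransform) -> tuple[FlowField, np.ndarray]:
    """Pseudo-label transport: if both images of a pair are spatially
    transformed by ``T``, the flow of the transformed pair at q equals
    R_θ · F(T⁻¹ q).  Returns the transported field and its validity mask."""
    rows, cols = flow.shape
    c = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    q = np.stack([rr, cc], axis=-1).astype(float)
    p = T.inverse().apply_points(q.reshape(-1, 2), c).reshape(rows, cols, 2)
    valid = (
        (p[..., 0] >= 0) & (p[..., 0] <= rows - 1)
        & (p[..., 1] >= 0) & (p[..., 1] <= cols - 1)
    )
    coords = np.stack([p[..., 0], p[..., 1]])
    fy = ndimage.map_coordinates(flow.dy, coords, order=1, mode="nearest")
    fx = ndimage.map_coordinates(flow.dx, coords, order=1, mode="nearest")
    R = T.matrix
    ty = R[0, 0] * fy + R[0, 1] * fx
    tx = R[1, 0] * fy + R[1, 1] * fx
    return FlowField(ty, tx), valid


def augmentation_loss(
    model: "FlowEstimator",
    moving: np.ndarray,
    reference: np.ndarray,
    aug: AugmentationSample,
    eps: float = 1e-3,
) -> float:
    """ARFlow-style augmentation consistency: the prediction on the original
    pair, held fixed as a pseudo-label and transported through the spatial
    transform, must match the prediction on the augmented pair over the
    validly transported region."""
    base = model.estimate(moving, reference)
    aug_flow = model.estimate(aug.apply_image(moving), aug.apply_image(reference))
    target, valid = _transport_flow(base, aug.spatial)
    if not valid.any():
        raise ValueError("degenerate augmentation: empty valid region")
    err = np.hypot(aug_flow.dy - target.dy, aug_flow.dx - target.dx)
    return float(charbonnier(err, eps)[valid].mean())


# ---------------------------------------------------------------------------
# learned coarse-to-fine cost-volume model ("pwc-lite" style)


def _unit_normalize(feat: np.ndarray) -> np.ndarray:
    norm = np.sqrt(np.sum(feat * feat, axis=2, keepdims=True)) + 1e-8
    return feat / norm


@dataclass
class PWCLiteModel:
    """Lightweight coarse-to-fine cost-volume flow model.

    A frozen multi-scale descriptor pyramid provides per-level features; at
    each of up to five octaves a local correlation volume (search radius 4)
    is decoded into a flow increment by a temperature-controlled soft-argmax
    followed by Gaussian smoothing.  The trainable parameters are, per
    level: the softmax temperature, the increment gain, and the smoothing
    scale — a deliberately small vector so the model can be optimized by
    stochastic gradient descent on the unsupervised loss without autodiff
    machinery.

    Inference is fully deterministic for fixed parameters.
    """

    n_levels: int = 5
    radius: int = 4
    params: np.ndarray = field(default=None)  # type: ignore[assignment]
    extractor: DescriptorExtractor = field(default_factory=MultiscaleExtractor)
    name: str = "pwc_lite"

    N_PARAMS_PER_LEVEL = 3  # [log temperature, gain, log smoothing sigma]

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = self.init_params(self.n_levels)
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.shape != (self.n_levels * self.N_PARAMS_PER_LEVEL,):
            raise ValueError("parameter vector has the wrong length")

    @staticmethod
    def init_params(n_levels: int) -> np.ndarray:
        # modest temperature / unit gain / 1-px smoothing at every level
        per = np.array([np.log(4.0), 1.0, 0.0])
        return np.tile(per, n_levels)

    def _level_params(self, level: int) -> tuple[float, float, float]:
        base = min(level, self.n_levels - 1) * self.N_PARAMS_PER_LEVEL
        log_t, gain, log_s = self.params[base : base + 3]
        return float(np.exp(log_t)), float(gain), float(np.exp(log_s))

    def _effective_levels(self, shape: tuple[int, int]) -> int:
        # the coarsest level must comfortably contain the search window,
        # else cost volumes there sample mostly padding
        min_side = max(MIN_LEVEL_SIDE, 4 * self.radius)
        levels = 1
        side = min(shape)
        while levels < self.n_levels and side / 2.0 >= min_side:
            side /= 2.0
            levels += 1
        return levels

    def estimate(self, moving: np.ndarray, reference: np.ndarray) -> FlowField:
        moving = np.asarray(moving, dtype=np.float64)
        reference = np.asarray(reference, dtype=np.float64)
        if moving.shape != reference.shape:
            raise ValueError("moving and reference shapes differ")
        levels = self._effective_levels(moving.shape)
        mult = 2 ** (levels - 1)
        pad_r = (-moving.shape[0]) % mult
        pad_c = (-moving.shape[1]) % mult
        if pad_r or pad_c:
            pad = ((0, pad_r), (0, pad_c))
            mov = np.pad(moving, pad, mode="reflect")
            ref = np.pad(reference, pad, mode="reflect")
        else:
            mov, ref = moving, reference
        flow = self._infer(mov, ref, levels)
        if pad_r or pad_c:
            flow = FlowField(
                flow.dy[: moving.shape[0], : moving.shape[1]],
                flow.dx[: moving.shape[0], : moving.shape[1]],
            )
        return flow

    def _infer(self, moving: np.ndarray, reference: np.ndarray, levels: int) -> FlowField:
        mov_levels = _pyramid(moving, levels, 2.0)
        ref_levels = _pyramid(reference, levels, 2.0)
        flow: Optional[FlowField] = None
        for level in reversed(range(levels)):
            mf = _unit_normalize(self.extractor(mov_levels[level]).channels)
            rf = _unit_normalize(self.extractor(ref_levels[level]).channels)
            shape = mov_levels[level].shape
            flow = FlowField.zeros(shape) if flow is None else resample_flow(flow, shape)
            temp, gain, sigma = self._level_params(level)
            wm = _warp_planes(mf, flow)
            dy_inc, dx_inc = self._decode_cost_volume(wm, rf, temp)
            dy_inc = ndimage.gaussian_filter(dy_inc * gain, sigma, mode="nearest")
            dx_inc = ndimage.gaussian_filter(dx_inc * gain, sigma, mode="nearest")
            flow = FlowField(flow.dy + dy_inc, flow.dx + dx_inc)
        assert flow is not None
        return flow

    def _decode_cost_volume(
        self, wm: np.ndarray, rf: np.ndarray, temperature: float
    ) -> tuple[np.ndarray, np.ndarray]:
        r = self.radius
        rows, cols, _ = wm.shape
        padded = np.pad(wm, ((r, r), (r, r), (0, 0)), mode="edge")
        offsets = [(oy, ox) for oy in range(-r, r + 1) for ox in range(-r, r + 1)]
        cv = np.empty((len(offsets), rows, cols))
        for k, (oy, ox) in enumerate(offsets):
            shifted = padded[r + oy : r + oy + rows, r + ox : r + ox + cols, :]
            cv[k] = np.mean(rf * shifted, axis=2)
        z = temperature * cv
        z -= z.max(axis=0, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=0, keepdims=True)
        oys = np.array([o[0] for o in offsets], dtype=float)
        oxs = np.array([o[1] for o in offsets], dtype=float)
        dy = np.tensordot(oys, p, axes=(0, 0))
        dx = np.tensordot(oxs, p, axes=(0, 0))
        return dy, dx

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            params=self.params,
            n_levels=self.n_levels,
            radius=self.radius,
            config_hash=np.frombuffer(
                _config_digest(self.n_levels, self.radius), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path, extractor: Optional[DescriptorExtractor] = None) -> "PWCLiteModel":
        with np.load(path) as data:
            n_levels = int(data["n_levels"])
            radius = int(data["radius"])
            digest = data["config_hash"].tobytes()
            if digest != _config_digest(n_levels, radius):
                raise ValueError("checkpoint config hash mismatch")
            return cls(
                n_levels=n_levels,
                radius=radius,
                params=data["params"],
                extractor=extractor or MultiscaleExtractor(),
            )


def _config_digest(n_levels: int, radius: int) -> bytes:
    import hashlib

    return hashlib.sha256(f"pwc_lite:{n_levels}:{radius}".encode()).digest()


def estimate_flow_learned(
    moving: np.ndarray, reference: np.ndarray, model: PWCLiteModel
) -> FlowField:
    """Run the learned coarse-to-fine model in inference mode."""
    return model.estimate(moving, reference)


# ---------------------------------------------------------------------------
# unsupervised training


def _pair_loss(
    model: PWCLiteModel,
    moving: np.ndarray,
    reference: np.ndarray,
    extractor: DescriptorExtractor,
    weights: LossWeights,
    aug: Optional[AugmentationSample],
) -> dict[str, float]:
    flow = model.estimate(moving, reference)
    warped = warp_image(moving, flow, fill="edge")
    ph = feature_photometric_loss(
        extract_features(reference, extractor), extract_features(warped, extractor)
    )
    terms = {"ph": ph}
    if weights.lambda_smooth > 0:
        terms["smooth"] = smoothness_loss(flow)
    if weights.lambda_aug > 0 and aug is not None:
        aug_flow = model.estimate(aug.apply_image(moving), aug.apply_image(reference))
        target, valid = _transport_flow(flow, aug.spatial)
        err = np.hypot(aug_flow.dy - target.dy, aug_flow.dx - target.dx)
        terms["aug"] = float(charbonnier(err)[valid].mean())
    total = (
        terms["ph"]
        + weights.lambda_smooth * terms.get("smooth", 0.0)
        + weights.lambda_aug * terms.get("aug", 0.0)
    )
    terms["total"] = total
    return terms


def _batch_loss(
    model: PWCLiteModel,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    extractor: DescriptorExtractor,
    weights: LossWeights,
    augs: Sequence[Optional[AugmentationSample]],
) -> dict[str, float]:
    acc: dict[str, float] = {}
    for (mov, ref), aug in zip(pairs, augs):
        terms = _pair_loss(model, mov, ref, extractor, weights, aug)
        for k, v in terms.items():
            acc[k] = acc.get(k, 0.0) + v / len(pairs)
    return acc


def train_unsupervised(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    extractor: Optional[DescriptorExtractor] = None,
    weights: LossWeights = LossWeights(),
    epochs: int = 100,
    seed: int = 0,
    model: Optional[PWCLiteModel] = None,
    batch_size: int = 4,
    lr: float = 0.05,
    perturb: float = 0.05,
    checkpoint_path=None,
    checkpoint_every: int = 50,
) -> tuple[PWCLiteModel, list[dict[str, float]]]:
    """Train the cost-volume model on unlabeled pairs.

    Each epoch performs one stochastic-gradient step on a sampled minibatch;
    the gradient of the total loss with respect to the (small) parameter
    vector is estimated by simultaneous perturbation (two loss evaluations
    per step with a shared ±1 Rademacher direction), which keeps training a
    plain SGD loop without an autodiff dependency.  The history records each
    loss term per epoch, evaluated on a fixed probe subset.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(seed)
    extractor = extractor or MultiscaleExtractor()
    if model is None:
        model = PWCLiteModel(extractor=extractor)
    probe = list(pairs)[: min(8, len(pairs))]
    probe_augs: list[Optional[AugmentationSample]] = [
        sample_augmentation(np.random.default_rng(seed + 10_000 + i))
        if weights.lambda_aug > 0
        else None
        for i in range(len(probe))
    ]
    history: list[dict[str, float]] = []
    params = model.params.copy()
    for epoch in range(epochs):
        idx = rng.choice(len(pairs), size=min(batch_size, len(pairs)), replace=False)
        batch = [pairs[i] for i in idx]
        augs = [
            sample_augmentation(rng) if weights.lambda_aug > 0 else None
            for _ in batch
        ]
        delta = rng.choice([-1.0, 1.0], size=params.shape)
        model.params = params + perturb * delta
        l_plus = _batch_loss(model, batch, extractor, weights, augs)["total"]
        model.params = params - perturb * delta
        l_minus = _batch_loss(model, batch, extractor, weights, augs)["total"]
        if not (np.isfinite(l_plus) and np.isfinite(l_minus)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: L+={l_plus}, L-={l_minus}"
            )
        ghat = (l_plus - l_minus) / (2.0 * perturb) * delta
        step = lr / (1.0 + 0.01 * epoch) * ghat
        np.clip(step, -0.2, 0.2, out=step)
        params = params - step
        model.params = params
        record = _batch_loss(model, probe, extractor, weights, probe_augs)
        if not np.isfinite(record["total"]):
            raise FloatingPointError(f"non-finite probe loss at epoch {epoch}")
        history.append(record)
        if checkpoint_path is not None and (epoch + 1) % checkpoint_every == 0:
            model.save(checkpoint_path)
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, history
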