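"""Sequential short-series registration with fixed rigid endpoints.

The first section is the reference and is never deformed.  The last section
is placed by a rigid (rotation + translation) transform — estimated from
SIFT keypoint matches with RANSAC, or supplied by the caller (e.g. by the
long-series benchmark chain) — and is likewise never deformed afterwards.
Every interior section i is registered to the previously *warped* section:
``F_{i→i-1} = E(s_i, ws_{i-1})`` and ``ws_i = φ_F(s_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import EuclideanTransform

from .flow import FlowField, RigidTransform, apply_rigid, warp_image
from .pairwise import FlowEstimator
from .stack_io import SectionStack

__all__ = [
    "RigidRegistrationError",
    "SerialResult",
    "register_rigid",
    "sequential_register",
]


class RigidRegistrationError(RuntimeError):
    """Raised when SIFT+RANSAC cannot find a stable rigid transform."""


@dataclass
class SerialResult:
    """Output of :func:`sequential_register`.

    ``warped`` holds ws_1..ws_n; ``flows[i]`` (i = 2..n−2, 0-based interior
    indices 1..n−2) is the backward flow that produced ws_i; the endpoints
    carry no flow.  ``endpoint_rigid`` is the transform placing s_n.
    """

    warped: SectionStack
    flows: dict[int, FlowField]
    endpoint_rigid: RigidTransform
    first_rigid: RigidTransform = field(default_factory=RigidTransform)

    @property
    def n(self) -> int:
        return self.warped.n


def _to_ubyte(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255).astype(np.uint8)


def register_rigid(
    moving: np.ndarray,
    reference: np.ndarray,
    min_inliers: int = 3,
    residual_threshold: float = 3.0,
    max_trials: int = 2000,
    seed: int = 0,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``
    from SIFT keypoint matches filtered by RANSAC, refined by least squares
    on the inliers.

    Returns T such that ``apply_rigid(moving, T) ≈ reference``.  Raises
    :class:`RigidRegistrationError` when too few keypoints or inliers exist
    (the caller may fall back to identity with a warning).
    """
    det_m, det_r = SIFT(), SIFT()
    try:
        det_m.detect_and_extract(_to_ubyte(moving))
        det_r.detect_and_extract(_to_ubyte(reference))
    except RuntimeError as exc:  # skimage raises when no keypoints survive
        raise RigidRegistrationError(f"SIFT found no keypoints: {exc}") from exc
    if len(det_m.keypoints) < min_inliers or len(det_r.keypoints) < min_inliers:
        raise RigidRegistrationError("too few SIFT keypoints")
    matches = match_descriptors(
        det_m.descriptors, det_r.descriptors, cross_check=True, max_ratio=0.8
    )
    if len(matches) < min_inliers:
        raise RigidRegistrationError(f"only {len(matches)} descriptor matches")
    src = det_m.keypoints[matches[:, 0]].astype(float)  # (row, col) in moving
    dst = det_r.keypoints[matches[:, 1]].astype(float)
    try:
        tform, inliers = ransac(
            (src, dst),
            EuclideanTransform,
            min_samples=2,
            residual_threshold=residual_threshold,
            max_trials=max_trials,
            rng=seed,
        )
    except ValueError as exc:
        raise RigidRegistrationError(f"RANSAC failed: {exc}") from exc
    if tform is None or inliers is None or inliers.sum() < min_inliers:
        raise RigidRegistrationError("RANSAC found too few inliers")
    # least-squares refit on the inlier set
    refined = EuclideanTransform.from_estimate(src[inliers], dst[inliers])
    if not refined:
        raise RigidRegistrationError("inlier least-squares refit failed")
    M = refined.params  # 3x3 acting on (row, col, 1) column conventions
    R = M[:2, :2]
    if np.linalg.det(R) < 0:
        raise RigidRegistrationError("estimated transform is a reflection")
    theta = float(np.arctan2(M[1, 0], M[0, 0]))
    t0 = M[:2, 2]
    shape = np.asarray(moving).shape
    c = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    # convert origin-based (q = R p + t0) to center-based (q = R (p-c) + c + t)
    t = t0 + R @ c - c
    return RigidTransform(theta, (float(t[0]), float(t[1])))


def sequential_register(
    stack: SectionStack,
    estimator: FlowEstimator,
    endpoint_mode: str = "rigid_pair",
    endpoint_rigid: Optional[RigidTransform] = None,
    first_rigid: Optional[RigidTransform] = None,
) -> SerialResult:
    """Run the sequential short-series registration.

    ``endpoint_mode='rigid_pair'`` estimates the last section's placement by
    registering s_n to s_1; ``'provided'`` uses ``endpoint_rigid`` (and an
    optional ``first_rigid`` placing s_1, used by the long-series chain).
    """
    n = stack.n
    if n < 3:
        raise ValueError("serial registration needs n >= 3 sections")
    if endpoint_mode == "rigid_pair":
        T_end = register_rigid(stack[n - 1], stack[0])
        T_first = RigidTransform()
    elif endpoint_mode == "provided":
        if endpoint_rigid is None:
            raise ValueError("endpoint_mode='provided' requires endpoint_rigid")
        T_end = endpoint_rigid
        T_first = first_rigid or RigidTransform()
    else:
        raise ValueError(f"unknown endpoint_mode {endpoint_mode!r}")

    identity_first = T_first.theta == 0.0 and T_first.t == (0.0, 0.0)
    warped = np.empty_like(stack.data)
    warped[0] = stack[0] if identity_first else apply_rigid(stack[0], T_first, fill="edge")
    warped[n - 1] = apply_rigid(stack[n - 1], T_end, fill="edge")
    flows: dict[int, FlowField] = {}
    for i in range(1, n - 1):
        try:
            flow = estimator.estimate(stack[i], warped[i - 1])
        except Exception as exc:
            raise RuntimeError(f"flow estimation failed at section {i}: {exc}") from exc
        flows[i] = flow
        warped[i] = warp_image(stack[i], flow, fill="edge")
    return SerialResult(
        warped=SectionStack(
            warped, pixel_size_nm=stack.pixel_size_nm, thickness_nm=stack.thickness_nm
        ),
        flows=flows,
        endpoint_rigid=T_end,
        first_rigid=T_first,
    )
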