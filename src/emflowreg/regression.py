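"""Structural regression: cumulative-error estimation and compensation.

Sequential pairwise registration accrues error: each pairwise step leaves a
residual Δe_i, and the residuals add up across the series (e_i = Σ_{j≤i}
Δe_j).  Because a neurite in a short series is approximately cylindrical,
these residuals share a direction, so the *total* accumulated error shows
up as the misalignment between the last deformably warped section ws_{n−1}
and the rigidly anchored last section ws_n.  The flow between those two
sections therefore approximates the total cumulative error, and a weighted
fraction of it is removed from every interior section, with weights derived
from descriptor distances between consecutive warped sections:

    w_i = (Σ_{j≤i} d_j) / (Σ_{j≤n} d_j),   d_1 := 0.

The endpoints are rigid anchors and are never compensated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .descriptors import DescriptorExtractor, MultiscaleExtractor, extract_features, feature_distance
from .flow import FlowField, scale_flow, warp_image
from .pairwise import FlowEstimator
from .serial import SerialResult
from .stack_io import SectionStack

__all__ = [
    "CumulativeErrorModel",
    "estimate_error_flow",
    "compute_weights",
    "compensate",
    "run_structural_regression",
]


@dataclass
class CumulativeErrorModel:
    """Error flow (the F_{n−1→n} estimate of the total cumulative error),
    per-section descriptor distances d_1..d_n (d_1 = 0), and the derived
    compensation weights w_1..w_n."""

    error_flow: FlowField
    distances: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.distances.shape != self.weights.shape:
            raise ValueError("distances and weights must have equal length")
        if np.any(np.diff(self.weights) < -1e-12):
            raise ValueError("weights must be nondecreasing")


def estimate_error_flow(
    ws_prev_last: np.ndarray, ws_last: np.ndarray, estimator: FlowEstimator
) -> FlowField:
    """Flow from ws_{n−1} to ws_n (backward convention): warping ws_{n−1} by
    the result aligns it to the rigid anchor ws_n."""
    ws_prev_last = np.asarray(ws_prev_last)
    ws_last = np.asarray(ws_last)
    if ws_prev_last.shape != ws_last.shape:
        raise ValueError("section shapes differ")
    return estimator.estimate(ws_prev_last, ws_last)


def compute_weights(distances) -> np.ndarray:
    """Compensation weights w_i = (Σ_{j≤i} d_j) / (Σ_{j≤n} d_j).

    ``d_1`` must be 0 by convention (the reference section carries no
    error).  If every distance is zero the weights fall back to the linear
    ramp w_i = (i−1)/(n−1).
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need a 1-D vector of at least two distances")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    total = d.sum()
    if total == 0:
        return np.arange(len(d)) / (len(d) - 1)
    return np.cumsum(d) / total


def compensate(result: SerialResult, model: CumulativeErrorModel) -> SectionStack:
    """Remove the weighted cumulative error from each interior section:
    final_i = warp(ws_i, w_i · error_flow); the endpoints pass through
    untouched."""
    n = result.n
    if len(model.weights) != n:
        raise ValueError("weight vector length must equal the section count")
    out = result.warped.data.copy()
    for i in range(1, n - 1):
        w = float(model.weights[i])
        if w == 0.0:
            continue
        out[i] = warp_image(
            result.warped[i], scale_flow(model.error_flow, w), fill="edge"
        )
    return SectionStack(
        out,
        pixel_size_nm=result.warped.pixel_size_nm,
        thickness_nm=result.warped.thickness_nm,
    )


def run_structural_regression(
    result: SerialResult,
    extractor: Optional[DescriptorExtractor] = None,
    estimator: Optional[FlowEstimator] = None,
    return_model: bool = False,
):
    """Full §-pipeline step on a completed sequential registration: compute
    descriptor distances on the warped sections, derive weights, estimate
    the error flow between the last two warped sections, and compensate.

    Returns the compensated stack, or ``(stack, CumulativeErrorModel)`` when
    ``return_model`` is set.
    """
    if estimator is None:
        from .pairwise import ClassicalFlowEstimator

        estimator = ClassicalFlowEstimator()
    extractor = extractor or MultiscaleExtractor()
    n = result.n
    feats = [extract_features(result.warped[i], extractor) for i in range(n)]
    d = np.zeros(n)
    for i in range(1, n):
        d[i] = feature_distance(feats[i], feats[i - 1])
    w = compute_weights(d)
    error_flow = estimate_error_flow(
        result.warped[n - 2], result.warped[n - 1], estimator
    )
    model = CumulativeErrorModel(error_flow=error_flow, distances=d, weights=w)
    final = compensate(result, model)
    if return_model:
        return final, model
    return final
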