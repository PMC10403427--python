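"""Self-contained synthetic studies exercising the full pipeline.

Each experiment builds its own ground-truth data from the synthetic module,
runs the relevant pipeline stage, and returns the quantities of interest.
They are the package's reference experiments: the test suite runs reduced
versions and the reproduction script reports their headline numbers.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .flow import RigidTransform, scale_flow, warp_labels
from .metrics import endpoint_error, ncc, top_k_dice
from .pairwise import ClassicalFlowEstimator, FlowEstimator, LossWeights, train_unsupervised
from .regression import run_structural_regression
from .serial import SerialResult, sequential_register
from .stack_io import LabelStack, SectionStack
from .synthetic import (
    PhantomSpec,
    TPSDeformSpec,
    drift_labels,
    inject_drift,
    make_phantom,
    make_registration_pairs,
    tps_deform,
)

__all__ = [
    "pairwise_recovery_experiment",
    "drift_compensation_experiment",
    "serial_tps_experiment",
    "training_experiment",
]


def pairwise_recovery_experiment(
    n_seeds: int = 10,
    shape: tuple[int, int] = (128, 128),
    shift_max_px: float = 3.0,
    tps_spec: Optional[TPSDeformSpec] = None,
    estimator: Optional[FlowEstimator] = None,
    seed: int = 0,
) -> dict:
    """Flow-recovery accuracy on constant shifts and TPS pairs.

    Returns mean endpoint error on integer-free random shifts (interior
    region), and the mean EPE / mean true displacement ratio on TPS pairs.
    """
    from .synthetic import make_textured_image

    estimator = estimator or ClassicalFlowEstimator()
    shift_epes = []
    for s in range(n_seeds):
        ref = make_textured_image(shape, seed=seed * 1000 + s)
        rng = np.random.default_rng(seed * 1000 + s)
        sh = rng.uniform(-shift_max_px, shift_max_px, 2)
        mov = ndimage.shift(ref, -sh, order=1, mode="nearest")  # content moves +sh
        F = estimator.estimate(mov, ref)
        inner = (slice(10, -10), slice(10, -10))
        shift_epes.append(
            float(np.hypot(F.dy[inner] + sh[0], F.dx[inner] + sh[1]).mean())
        )
    tps_spec = tps_spec or TPSDeformSpec(n_control=6, sigma_px=4.0)
    tps_epes, tps_disps = [], []
    for s in range(n_seeds):
        spec_s = TPSDeformSpec(
            tps_spec.n_control, tps_spec.sigma_px, tps_spec.margin_px, seed=seed * 1000 + s
        )
        mov, ref, gt = make_registration_pairs(1, spec_s, seed=seed * 1000 + s, shape=shape)[0]
        F = estimator.estimate(mov, ref)
        tps_epes.append(endpoint_error(F, gt))
        tps_disps.append(float(np.hypot(gt.dy, gt.dx).mean()))
    return {
        "shift_epe_px": float(np.mean(shift_epes)),
        "tps_epe_px": float(np.mean(tps_epes)),
        "tps_mean_displacement_px": float(np.mean(tps_disps)),
        "tps_epe_ratio": float(np.mean(tps_epes) / np.mean(tps_disps)),
    }


def _label_centroids(labels: np.ndarray, n_neurites: int) -> np.ndarray:
    n = labels.shape[0]
    cs = np.full((n, n_neurites, 2), np.nan)
    for i in range(n):
        for k in range(n_neurites):
            m = labels[i] == k + 1
            if m.any():
                cs[i, k] = ndimage.center_of_mass(m)
    return cs


def _centroid_rms(labels: np.ndarray, gt_centroids: np.ndarray) -> float:
    cs = _label_centroids(labels, gt_centroids.shape[1])
    dev = np.linalg.norm(cs - gt_centroids, axis=2)
    return float(np.sqrt(np.nanmean(dev[1:-1] ** 2)))


def drift_compensation_experiment(
    seed: int = 0,
    drift: tuple[float, float] = (1.0, 0.0),
    spec: Optional[PhantomSpec] = None,
    estimator: Optional[FlowEstimator] = None,
) -> dict:
    """Cumulative-error removal on a tilted-cylinder phantom.

    A constant per-section drift — the constructible analogue of the
    accumulated registration error e_i = Σ Δe_j — is injected into the
    interior sections of a phantom whose last section is held at its rigid
    anchor placement (its drift removed, as the endpoint registration
    guarantees).  Structural regression estimates the error flow between
    the last two sections, weights it per section, and compensates; the
    figure of merit is the RMS deviation of neurite centroids from their
    ground-truth tilted axes, before vs after compensation.
    """
    if spec is None:
        margin = float(np.abs(drift).max() * 15 + 6)
        spec = PhantomSpec(n_sections=16, rows=160, cols=160, margin_px=margin, seed=seed)
    estimator = estimator or ClassicalFlowEstimator()
    stack, labels, centroids = make_phantom(spec)
    n = stack.n
    drifted, fields = inject_drift(stack, drift)
    ws = drifted.data.copy()
    ws[n - 1] = stack[n - 1]  # rigid anchor: endpoint drift removed
    result = SerialResult(
        warped=SectionStack(ws), flows={}, endpoint_rigid=RigidTransform()
    )
    final, model = run_structural_regression(
        result, estimator=estimator, return_model=True
    )
    dlab = drift_labels(labels, fields).data.copy()
    dlab[n - 1] = labels[n - 1]
    comp = dlab.copy()
    for i in range(1, n - 1):
        comp[i] = warp_labels(dlab[i], scale_flow(model.error_flow, float(model.weights[i])))
    rms_before = _centroid_rms(dlab, centroids)
    rms_after = _centroid_rms(comp, centroids)
    return {
        "rms_uncompensated_px": rms_before,
        "rms_compensated_px": rms_after,
        "reduction": 1.0 - rms_after / rms_before,
        "weights": model.weights,
        "final_stack": final,
    }


def serial_tps_experiment(
    seed: int = 0,
    spec: Optional[PhantomSpec] = None,
    tps: Optional[TPSDeformSpec] = None,
    estimator: Optional[FlowEstimator] = None,
    top_k: int = 50,
) -> dict:
    """End-to-end short-series registration of a TPS-deformed phantom.

    Every interior section of a labeled phantom is independently
    TPS-deformed (sectioning-style nonlinear distortion); the endpoints
    stay clean, mirroring their rigid anchoring.  The full pipeline
    (sequential registration + structural regression) is compared with the
    unregistered stack via mean NCC to the ground truth and top-k Dice of
    the neurite labels.
    """
    spec = spec or PhantomSpec(n_sections=16, rows=160, cols=160, margin_px=8.0, seed=seed)
    tps = tps or TPSDeformSpec(n_control=8, sigma_px=3.0)
    estimator = estimator or ClassicalFlowEstimator()
    stack, labels, _ = make_phantom(spec)
    n = stack.n
    deformed = stack.data.copy()
    deformed_labels = labels.data.copy()
    for i in range(1, n - 1):
        spec_i = TPSDeformSpec(tps.n_control, tps.sigma_px, tps.margin_px, seed=seed * 977 + i)
        deformed[i], fieldf = tps_deform(stack[i], spec_i)
        deformed_labels[i] = warp_labels(labels[i], fieldf)
    moving = SectionStack(deformed)
    result = sequential_register(
        moving, estimator, endpoint_mode="provided", endpoint_rigid=RigidTransform()
    )
    final, model = run_structural_regression(result, estimator=estimator, return_model=True)
    # carry the labels through the same transforms the images received
    reg_labels = deformed_labels.copy()
    for i, f in result.flows.items():
        reg_labels[i] = warp_labels(deformed_labels[i], f)
    for i in range(1, n - 1):
        w = float(model.weights[i])
        if w > 0:
            reg_labels[i] = warp_labels(reg_labels[i], scale_flow(model.error_flow, w))
    gt_labels = labels
    dice_before, used = top_k_dice(gt_labels, LabelStack(deformed_labels), k=top_k)
    dice_after, _ = top_k_dice(gt_labels, LabelStack(reg_labels), k=top_k)
    ncc_before = float(np.mean([ncc(deformed[i], stack[i]) for i in range(n)]))
    ncc_after = float(np.mean([ncc(final[i], stack[i]) for i in range(n)]))
    return {
        "dice_unregistered": dice_before,
        "dice_registered": dice_after,
        "ncc_unregistered": ncc_before,
        "ncc_registered": ncc_after,
        "labels_used": used,
    }


def training_experiment(
    seed: int = 0,
    n_pairs: int = 50,
    n_holdout: int = 20,
    shape: tuple[int, int] = (64, 64),
    epochs: int = 100,
    weights: LossWeights = LossWeights(),
    tps: Optional[TPSDeformSpec] = None,
) -> dict:
    """Unsupervised training smoke study.

    Trains the cost-volume model on synthetic TPS pairs and evaluates on a
    held-out set: reports the initial and final total loss and the fraction
    of held-out pairs where warping with the predicted flow raises NCC to
    the reference above the identity baseline.
    """
    tps = tps or TPSDeformSpec(n_control=6, sigma_px=4.0)
    train_pairs = [
        (m, r)
        for m, r, _ in make_registration_pairs(n_pairs, tps, seed=seed, shape=shape)
    ]
    held = make_registration_pairs(n_holdout, tps, seed=seed + 990_001, shape=shape)
    model, history = train_unsupervised(
        train_pairs, weights=weights, epochs=epochs, seed=seed
    )
    wins = 0
    from .flow import warp_image

    for mov, ref, _ in held:
        F = model.estimate(mov, ref)
        if ncc(warp_image(mov, F, fill="edge"), ref) > ncc(mov, ref):
            wins += 1
    return {
        "loss_initial": history[0]["total"],
        "loss_final": history[-1]["total"],
        "holdout_win_fraction": wins / len(held),
        "history": history,
        "model": model,
    }
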