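"""Synthetic data: TPS deformation against a linear-system oracle, phantom
geometry, drift injection, and pair generation."""

import numpy as np
import pytest

from emflowreg.flow import FlowField
from emflowreg.metrics import endpoint_error
from emflowreg.stack_io import SectionStack
from emflowreg.synthetic import (
    PhantomSpec,
    TPSDeformSpec,
    _sample_controls,
    axial_subsample,
    boundary_anchors,
    inject_drift,
    make_phantom,
    make_registration_pairs,
    make_textured_image,
    tps_deform,
    tps_fit_field,
)


def tps_oracle(pts, vecs, shape):
    """Independent dense TPS evaluation: solve the r² log r + affine system
    by hand and evaluate per pixel with nested loops over control points."""
    n = len(pts)

    def kern(r2):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 0.5 * r2 * np.log(r2)
        return np.where(r2 > 0, out, 0.0)

    # system: [K P; P^T 0] [w; a] = [v; 0], P = [1, y, x]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    K = kern(d2)
    P = np.column_stack([np.ones(n), pts])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = vecs
    sol = np.linalg.solve(A, rhs)
    w, a = sol[:n], sol[n:]
    rows, cols = shape
    dy = np.zeros(shape)
    dx = np.zeros(shape)
    for r in range(rows):
        for c in range(cols):
            q = np.array([r, c], dtype=float)
            r2 = ((pts - q) ** 2).sum(-1)
            basis = kern(r2)
            val = w.T @ basis + a[0] + a[1] * r + a[2] * c
            dy[r, c], dx[r, c] = val
    return FlowField(dy, dx)


class TestTPS:
    def test_sigma_zero_identity(self, textured_image):
        out, field = tps_deform(textured_image, TPSDeformSpec(6, 0.0, seed=1))
        assert np.array_equal(out, textured_image)
        assert np.all(field.magnitude() == 0)

    def test_interpolation_condition_at_controls(self):
        # integer control locations so the pixel grid contains the controls
        spec = TPSDeformSpec(6, 4.0, seed=3)
        pts, vecs = _sample_controls((48, 48), spec)
        pts = np.round(pts)
        anchors = boundary_anchors((48, 48))
        all_pts = np.vstack([pts, anchors])
        all_vecs = np.vstack([vecs, np.zeros_like(anchors)])
        field = tps_fit_field(all_pts, all_vecs, (48, 48))
        for (py, px), (vy, vx) in zip(pts, vecs):
            iy, ix = int(py), int(px)
            assert field.dy[iy, ix] == pytest.approx(vy, abs=1e-8)
            assert field.dx[iy, ix] == pytest.approx(vx, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_field_matches_linear_system_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(3, 20, (5, 2))
        vecs = rng.normal(0, 2, (5, 2))
        field = tps_fit_field(pts, vecs, (24, 24))
        oracle = tps_oracle(pts, vecs, (24, 24))
        assert np.abs(field.dy - oracle.dy).max() < 1e-6
        assert np.abs(field.dx - oracle.dx).max() < 1e-6

    def test_control_vector_half_normal_mean(self):
        mags = []
        for seed in range(100):
            _, vecs = _sample_controls((64, 64), TPSDeformSpec(10, 4.0, seed=seed))
            mags.append(np.abs(vecs).mean())
        # |N(0, s)| has mean s*sqrt(2/pi)
        expected = 4.0 * np.sqrt(2 / np.pi)
        assert np.mean(mags) == pytest.approx(expected, rel=0.05)


class TestPhantom:
    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec(n_sections=4, rows=64, cols=64, n_neurites=3, seed=5)
        s1, l1, c1 = make_phantom(spec)
        s2, l2, c2 = make_phantom(spec)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(l1.data, l2.data)
        assert np.array_equal(c1, c2)

    def test_zero_tilt_gives_static_labels(self):
        spec = PhantomSpec(n_sections=4, rows=64, cols=64, n_neurites=3, tilt_max_px=0.0, seed=2)
        _, labels, centroids = make_phantom(spec)
        for i in range(1, 4):
            assert np.array_equal(labels[i], labels[0])
        assert np.allclose(centroids[1:], centroids[:-1])

    def test_centroids_follow_linear_tilt(self):
        spec = PhantomSpec(n_sections=6, rows=96, cols=96, n_neurites=4, tilt_max_px=0.5, seed=3)
        _, _, centroids = make_phantom(spec)
        steps = np.diff(centroids, axis=0)
        assert np.allclose(steps, steps[0], atol=1e-9)  # constant slope per neurite

    def test_disk_area_close_to_circle(self):
        spec = PhantomSpec(
            n_sections=3, rows=96, cols=96, n_neurites=2, radius_range=(6.0, 8.0), seed=7
        )
        _, labels, _ = make_phantom(spec)
        from emflowreg.synthetic import _substream

        radii = _substream(7, "geometry").uniform(6.0, 8.0, size=2)
        for k, r in enumerate(radii):
            area = (labels[0] == k + 1).sum()
            assert area == pytest.approx(np.pi * r**2, rel=0.10)

    def test_infeasible_packing_raises(self):
        spec = PhantomSpec(n_sections=3, rows=32, cols=32, n_neurites=20, seed=0)
        with pytest.raises(ValueError):
            make_phantom(spec)


class TestInjectDrift:
    def test_zero_delta_identity(self, small_stack):
        out, fields = inject_drift(small_stack, (0.0, 0.0))
        assert np.array_equal(out.data, small_stack.data)
        assert all(f.magnitude().max() == 0 for f in fields)

    def test_constant_delta_accumulates(self, small_stack):
        out, fields = inject_drift(small_stack, (1.0, 0.0))
        # section i carries cumulative shift (i, 0): field is -(i, 0)
        for i, f in enumerate(fields):
            assert np.allclose(f.dy, -float(i)) and np.allclose(f.dx, 0.0)

    def test_random_deltas_match_prefix_sum_oracle(self, small_stack, rng):
        deltas = rng.uniform(-1, 1, (small_stack.n, 2))
        _, fields = inject_drift(small_stack, deltas)
        deltas[0] = 0
        for i, f in enumerate(fields):
            expect = deltas[: i + 1].sum(axis=0)
            assert np.allclose([-f.dy[0, 0], -f.dx[0, 0]], expect)


class TestRegistrationPairs:
    def test_same_seed_identical(self):
        spec = TPSDeformSpec(5, 3.0, seed=2)
        p1 = make_registration_pairs(3, spec, seed=4, shape=(48, 48))
        p2 = make_registration_pairs(3, spec, seed=4, shape=(48, 48))
        for (m1, r1, g1), (m2, r2, g2) in zip(p1, p2):
            assert np.array_equal(m1, m2) and np.array_equal(r1, r2)
            assert np.array_equal(g1.dy, g2.dy)

    def test_sigma_zero_pairs_identical_images(self):
        spec = TPSDeformSpec(5, 0.0, seed=2)
        mov, ref, gt = make_registration_pairs(1, spec, seed=1, shape=(48, 48))[0]
        assert np.array_equal(mov, ref)
        assert np.all(gt.magnitude() == 0)

    def test_zero_flow_epe_equals_mean_gt_magnitude(self):
        spec = TPSDeformSpec(6, 3.0, seed=5)
        mov, ref, gt = make_registration_pairs(1, spec, seed=5, shape=(48, 48))[0]
        zero = FlowField.zeros(gt.shape)
        assert endpoint_error(zero, gt) == pytest.approx(gt.magnitude().mean())

    def test_gt_flow_registers_moving_onto_reference(self):
        from emflowreg.flow import warp_image
        from emflowreg.metrics import ncc

        spec = TPSDeformSpec(6, 3.0, seed=6)
        mov, ref, gt = make_registration_pairs(1, spec, seed=6, shape=(64, 64))[0]
        warped = warp_image(mov, gt, fill="edge")
        assert ncc(warped, ref) > ncc(mov, ref)
        assert ncc(warped, ref) > 0.9


def test_axial_subsample_keeps_every_kth(rng):
    stack = SectionStack(rng.random((17, 16, 16)))
    sub = axial_subsample(stack, keep_every=8)
    assert sub.n == 3
    assert np.array_equal(sub[1], stack[8])
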