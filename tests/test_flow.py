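"""Warping, flow algebra, and rigid transforms against brute-force oracles."""

import numpy as np
import pytest

from emflowreg.flow import (
    FlowField,
    RigidTransform,
    apply_rigid,
    compose_flows,
    invert_flow,
    read_flow,
    rigid_to_flow,
    scale_flow,
    warp_image,
    warp_labels,
    warp_validity_mask,
    write_flow,
)


def bilinear_oracle(image, flow, fill_zero=True):
    """Independent nested-loop backward bilinear interpolation."""
    rows, cols = image.shape
    out = np.zeros_like(image, dtype=float)
    for r in range(rows):
        for c in range(cols):
            y = r + flow.dy[r, c]
            x = c + flow.dx[r, c]
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            fy, fx = y - y0, x - x0
            acc = 0.0
            for dy_, wy in ((0, 1 - fy), (1, fy)):
                for dx_, wx in ((0, 1 - fx), (1, fx)):
                    yy, xx = y0 + dy_, x0 + dx_
                    if 0 <= yy < rows and 0 <= xx < cols:
                        v = image[yy, xx]
                    elif fill_zero:
                        v = 0.0
                    else:
                        v = image[min(max(yy, 0), rows - 1), min(max(xx, 0), cols - 1)]
                    acc += wy * wx * v
            out[r, c] = acc
    return out


def nearest_oracle(labels, flow):
    rows, cols = labels.shape
    out = np.zeros_like(labels)
    for r in range(rows):
        for c in range(cols):
            y = int(np.floor(r + flow.dy[r, c] + 0.5))
            x = int(np.floor(c + flow.dx[r, c] + 0.5))
            if 0 <= y < rows and 0 <= x < cols:
                out[r, c] = labels[y, x]
    return out


class TestWarpImage:
    def test_zero_flow_is_bitwise_identity(self, rng):
        img = rng.random((9, 9))
        out = warp_image(img, FlowField.zeros((9, 9)))
        assert np.array_equal(out, img)

    def test_integer_shift_backward_semantics(self):
        img = np.array([[0.0, 1.0, 2.0, 3.0]] * 4)
        out = warp_image(img, FlowField.constant((4, 4), 0.0, 1.0))
        assert np.allclose(out[:, :3], img[:, 1:])
        assert np.all(out[:, 3] == 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bilinear_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 10))
        img = rng.random((n, n))
        flow = FlowField(rng.uniform(-1.5, 1.5, (n, n)), rng.uniform(-1.5, 1.5, (n, n)))
        assert np.allclose(warp_image(img, flow), bilinear_oracle(img, flow), atol=1e-6)

    def test_edge_fill_matches_clamped_oracle(self, rng):
        img = rng.random((7, 7))
        flow = FlowField(rng.uniform(-2, 2, (7, 7)), rng.uniform(-2, 2, (7, 7)))
        out = warp_image(img, flow, fill="edge")
        assert np.allclose(out, bilinear_oracle(img, flow, fill_zero=False), atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            warp_image(rng.random((5, 5)), FlowField.zeros((6, 6)))

    def test_validity_mask_marks_outside_samples(self):
        flow = FlowField.constant((4, 4), 0.0, 2.0)
        mask = warp_validity_mask(flow)
        assert mask[:, :2].all() and not mask[:, 2:].any()


class TestWarpLabels:
    def test_zero_flow_identity(self, rng):
        lab = rng.integers(0, 5, (8, 8))
        assert np.array_equal(warp_labels(lab, FlowField.zeros((8, 8))), lab)

    def test_integer_shift_vacates_with_zero(self):
        lab = np.arange(16).reshape(4, 4)
        out = warp_labels(lab, FlowField.constant((4, 4), 1.0, 0.0))
        assert np.array_equal(out[:3], lab[1:])
        assert np.all(out[3] == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nearest_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = rng.integers(0, 7, (7, 7))
        flow = FlowField(rng.uniform(-2, 2, (7, 7)), rng.uniform(-2, 2, (7, 7)))
        assert np.array_equal(warp_labels(lab, flow), nearest_oracle(lab, flow))

    def test_float_labels_rejected(self):
        with pytest.raises(ValueError):
            warp_labels(np.zeros((4, 4)), FlowField.zeros((4, 4)))


class TestFlowAlgebra:
    def test_scale_endpoints(self, rng):
        f = FlowField(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)))
        assert np.array_equal(scale_flow(f, 1.0).dy, f.dy)
        assert np.all(scale_flow(f, 0.0).magnitude() == 0)
        half = scale_flow(FlowField.constant((5, 5), 2.0, 4.0), 0.5)
        assert np.allclose(half.dy, 1.0) and np.allclose(half.dx, 2.0)

    def test_compose_with_zero_is_identity(self, rng):
        g = FlowField(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)))
        comp = compose_flows(FlowField.zeros((6, 6)), g)
        assert np.allclose(comp.dy, g.dy) and np.allclose(comp.dx, g.dx)

    def test_compose_constant_flows_add(self):
        a = FlowField.constant((8, 8), 1.0, -2.0)
        b = FlowField.constant((8, 8), 0.5, 1.5)
        comp = compose_flows(a, b)
        assert np.allclose(comp.dy, 1.5) and np.allclose(comp.dx, -0.5)

    def test_compose_equals_two_warps_on_smooth_field(self):
        yy, xx = np.meshgrid(np.linspace(0, 2 * np.pi, 48), np.linspace(0, 2 * np.pi, 48), indexing="ij")
        img = 0.5 + 0.4 * np.sin(0.8 * yy) * np.cos(0.6 * xx)
        inner = FlowField(0.8 * np.sin(yy), 0.8 * np.cos(xx))
        outer = FlowField(0.5 * np.cos(yy + 1), 0.6 * np.sin(xx + 2))
        two_step = warp_image(warp_image(img, inner, fill="edge"), outer, fill="edge")
        one_step = warp_image(img, compose_flows(outer, inner), fill="edge")
        interior = (slice(4, -4), slice(4, -4))
        assert np.abs(two_step[interior] - one_step[interior]).mean() < 1e-3

    def test_invert_flow_roundtrip(self):
        yy, xx = np.meshgrid(np.linspace(0, np.pi, 32), np.linspace(0, np.pi, 32), indexing="ij")
        f = FlowField(1.2 * np.sin(yy), 0.9 * np.cos(xx))
        g = invert_flow(f)
        comp = compose_flows(g, f)
        assert comp.magnitude()[4:-4, 4:-4].mean() < 0.02


class TestRigid:
    def test_identity_gives_zero_flow(self):
        f = rigid_to_flow(RigidTransform(), (10, 10))
        assert np.all(f.magnitude() == 0)

    def test_pure_translation_constant_flow(self):
        f = rigid_to_flow(RigidTransform(0.0, (2.0, -3.0)), (8, 8))
        assert np.allclose(f.dy, -2.0) and np.allclose(f.dx, 3.0)

    def test_quarter_turn_matches_rotation_oracle(self):
        img = np.zeros((5, 5))
        img[0, 1] = 1.0
        img[2, 4] = 2.0  # asymmetric pattern
        out = apply_rigid(img, RigidTransform(np.pi / 2, (0.0, 0.0)))
        # direct coordinate rotation oracle: q = R(p - c) + c
        oracle = np.zeros((5, 5))
        c = np.array([2.0, 2.0])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        for r in range(5):
            for col in range(5):
                if img[r, col] != 0:
                    q = R @ (np.array([r, col]) - c) + c
                    oracle[int(round(q[0])), int(round(q[1]))] = img[r, col]
        assert np.allclose(out, oracle, atol=1e-9)

    def test_inverse_composes_to_near_identity(self):
        T = RigidTransform(np.deg2rad(17.0), (3.0, -2.0))
        f1 = rigid_to_flow(T, (32, 32))
        f2 = rigid_to_flow(T.inverse(), (32, 32))
        comp = compose_flows(f1, f2)
        assert comp.magnitude()[8:-8, 8:-8].mean() <= 0.05

    def test_theta_wraps_into_interval(self):
        assert RigidTransform(3 * np.pi / 2).theta == pytest.approx(-np.pi / 2)


def test_flow_hdf5_roundtrip(tmp_path, rng):
    f = FlowField(rng.normal(size=(12, 12)), rng.normal(size=(12, 12)))
    write_flow(f, tmp_path / "f.h5")
    g = read_flow(tmp_path / "f.h5")
    assert np.allclose(f.dy, g.dy, atol=1e-6) and np.allclose(f.dx, g.dx, atol=1e-6)
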