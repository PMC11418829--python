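"""Kinematic operators: closed forms, brute-force oracles, stack assembly."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiokin.flow import FlowField, FlowSequence
from cardiokin.kinematics import (acceleration_maps, build_kinematic_stack,
                                  divergence_map, vorticity_map)


def _coords(n=32):
    half = (n - 1) / 2
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    return cols - half, rows - half  # x, y about the image center


def _smooth_random_flow(seed, n=16):
    rng = np.random.default_rng(seed)
    return FlowField(u=ndi.gaussian_filter(rng.normal(size=(n, n)), 1.5),
                     v=ndi.gaussian_filter(rng.normal(size=(n, n)), 1.5))


def brute_force_derivative(f, axis):
    """Independent per-pixel loop: central interior, one-sided borders."""
    out = np.empty_like(f)
    n0, n1 = f.shape
    for i in range(n0):
        for j in range(n1):
            k = i if axis == 0 else j
            last = (n0 if axis == 0 else n1) - 1
            def at(m):
                return f[m, j] if axis == 0 else f[i, m]
            if k == 0:
                out[i, j] = at(1) - at(0)
            elif k == last:
                out[i, j] = at(last) - at(last - 1)
            else:
                out[i, j] = (at(k + 1) - at(k - 1)) / 2.0
    return out


class TestDivergence:
    def test_uniform_expansion_is_exact(self):
        x, y = _coords()
        div = divergence_map(FlowField(u=0.1 * x, v=0.1 * y))
        np.testing.assert_allclose(div[1:-1, 1:-1], 0.2, atol=1e-6)

    def test_rigid_rotation_is_divergence_free(self):
        x, y = _coords()
        div = divergence_map(FlowField(u=-0.05 * y, v=0.05 * x))
        np.testing.assert_allclose(div, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        f = _smooth_random_flow(seed)
        expected = brute_force_derivative(f.u, axis=1) + \
            brute_force_derivative(f.v, axis=0)
        np.testing.assert_array_equal(divergence_map(f), expected)


class TestVorticity:
    def test_rigid_rotation_gives_twice_omega(self):
        x, y = _coords()
        vor = vorticity_map(FlowField(u=-0.05 * y, v=0.05 * x))
        np.testing.assert_allclose(vor[1:-1, 1:-1], 0.10, atol=1e-6)

    def test_pure_expansion_is_irrotational(self):
        x, y = _coords()
        vor = vorticity_map(FlowField(u=0.3 * x, v=0.3 * y))
        np.testing.assert_allclose(vor, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_oracle(self, seed):
        f = _smooth_random_flow(seed)
        expected = brute_force_derivative(f.v, axis=1) - \
            brute_force_derivative(f.u, axis=0)
        np.testing.assert_array_equal(vorticity_map(f), expected)


class TestLinearity:
    @given(a=st.floats(-2, 2), b=st.floats(-2, 2))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_operators_are_linear(self, a, b):
        f, g = _smooth_random_flow(7), _smooth_random_flow(8)
        combo = FlowField(u=a * f.u + b * g.u, v=a * f.v + b * g.v)
        for op in (divergence_map, vorticity_map):
            np.testing.assert_allclose(op(combo), a * op(f) + b * op(g),
                                       atol=1e-9)

    def test_grid_rotation_rotates_divergence(self):
        # rotating the flow field by 90 deg rotates the divergence map
        f = _smooth_random_flow(9)
        # np.rot90 maps grid (x,y) -> (y, -x) in row-down coordinates,
        # so vector components transform as (u,v) -> (v, -u)
        fr = FlowField(u=np.rot90(f.v), v=-np.rot90(f.u))
        np.testing.assert_allclose(divergence_map(fr)[1:-1, 1:-1],
                                   np.rot90(divergence_map(f))[1:-1, 1:-1],
                                   atol=1e-6)


class TestAcceleration:
    def test_constant_velocity_has_zero_acceleration(self):
        f = _smooth_random_flow(10)
        a_t, a_n = acceleration_maps(f, f)
        np.testing.assert_array_equal(a_t, 0.0)
        np.testing.assert_array_equal(a_n, 0.0)

    def test_pure_speed_up_is_tangential(self):
        shape = (8, 8)
        f0 = FlowField(u=np.ones(shape), v=np.zeros(shape))
        f1 = FlowField(u=2 * np.ones(shape), v=np.zeros(shape))
        a_t, a_n = acceleration_maps(f0, f1)
        np.testing.assert_allclose(a_t, 1.0)
        np.testing.assert_allclose(a_n, 0.0)

    def test_direction_rotation_closed_form(self):
        s, theta = 2.0, 0.1
        shape = (8, 8)
        f0 = FlowField(u=s * np.ones(shape), v=np.zeros(shape))
        f1 = FlowField(u=s * np.cos(theta) * np.ones(shape),
                       v=s * np.sin(theta) * np.ones(shape))
        a_t, a_n = acceleration_maps(f0, f1)
        np.testing.assert_allclose(a_n, s * np.sin(theta), atol=1e-6)
        np.testing.assert_allclose(a_t, s * (np.cos(theta) - 1), atol=1e-6)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_decomposition_is_complete(self, seed):
        eps = 1e-3
        f0, f1 = _smooth_random_flow(seed), _smooth_random_flow(seed + 50)
        a_t, a_n = acceleration_maps(f0, f1, eps=eps)
        speed = np.hypot(f0.u, f0.v)
        accel_sq = (f1.u - f0.u) ** 2 + (f1.v - f0.v) ** 2
        moving = speed >= eps
        np.testing.assert_allclose((a_t ** 2 + a_n ** 2)[moving],
                                   accel_sq[moving], rtol=1e-9)
        assert np.all(a_n >= 0)

    def test_slow_pixels_are_zeroed(self):
        f0 = FlowField(u=np.full((4, 4), 1e-6), v=np.zeros((4, 4)))
        f1 = FlowField(u=np.ones((4, 4)), v=np.ones((4, 4)))
        a_t, a_n = acceleration_maps(f0, f1, eps=1e-3)
        np.testing.assert_array_equal(a_t, 0.0)
        np.testing.assert_array_equal(a_n, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            acceleration_maps(_smooth_random_flow(1, n=16),
                              _smooth_random_flow(1, n=8))


class TestStackAssembly:
    def _flow_seq(self, T=12, n=16):
        return FlowSequence(fields=[_smooth_random_flow(s, n=n)
                                    for s in range(T)], label="N")

    def test_three_kinematic_stack_shape_and_order(self):
        stack = build_kinematic_stack(self._flow_seq(), ("a_N", "div", "vor"))
        assert stack.shape == (12, 16, 16, 3)
        assert stack.channel_names == ("a_N", "div", "vor")

    def test_raw_flow_channels(self):
        stack = build_kinematic_stack(self._flow_seq(), ("u", "v"))
        assert stack.shape == (12, 16, 16, 2)

    def test_zero_flow_gives_zero_stack(self):
        z = FlowField(u=np.zeros((8, 8)), v=np.zeros((8, 8)))
        seq = FlowSequence(fields=[z] * 5)
        stack = build_kinematic_stack(seq, ("div", "vor", "a_N"))
        np.testing.assert_array_equal(stack.data, 0.0)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            build_kinematic_stack(self._flow_seq(), ("div", "strain"))

    def test_final_index_repeats_last_pair(self):
        seq = self._flow_seq(T=5)
        stack = build_kinematic_stack(seq, ("a_T",), standardize=False)
        expected_last, _ = acceleration_maps(seq[3], seq[4])
        np.testing.assert_array_equal(stack.data[4, :, :, 0], expected_last)
        np.testing.assert_array_equal(stack.data[3, :, :, 0], expected_last)

    def test_channels_are_standardized(self):
        stack = build_kinematic_stack(self._flow_seq(), ("div", "u"))
        for c in range(2):
            assert stack.data[..., c].mean() == pytest.approx(0.0, abs=1e-12)
            assert stack.data[..., c].std() == pytest.approx(1.0, rel=1e-12)

    def test_intensity_channel_requires_frames(self):
        with pytest.raises(ValueError, match="intensity"):
            build_kinematic_stack(self._flow_seq(), ("intensity",))


def test_stack_archive_roundtrip(tmp_path):
    from cardiokin import load_stack, save_stack
    from cardiokin.flow import FlowSequence

    seq = FlowSequence(fields=[_smooth_random_flow(s) for s in range(3)],
                       patient_id="p2", slice_index=1, label="HCM")
    stack = build_kinematic_stack(seq, ("div", "vor"))
    path = save_stack(stack, tmp_path / "stack")
    back = load_stack(path)
    np.testing.assert_array_equal(back.data, stack.data)
    assert back.channel_names == ("div", "vor")
    assert back.patient_id == "p2" and back.label == "HCM"
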