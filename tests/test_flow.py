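import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droptrap import flow
from droptrap.flow import (
    DomainError,
    FlowField,
    FlowPattern,
    VelocityGrid,
    classify_pattern,
    load_grid,
    polar_components,
    sample_grid,
    save_grid,
    velocity_at,
)

ALL_BOUNDED = [FlowPattern.ONE_CELL, FlowPattern.TWO_CELL, FlowPattern.FOUR_CELL_BOUNDED]


class TestVelocityAt:
    def test_pure_strain_is_literal_formula(self):
        f = FlowField(FlowPattern.PURE_STRAIN, strain_rate=1.0)
        assert velocity_at(f, 1.0, 1.0) == (1.0, -1.0)

    @pytest.mark.parametrize(
        "pattern",
        [FlowPattern.PURE_STRAIN, FlowPattern.ONE_CELL, FlowPattern.FOUR_CELL_BOUNDED],
    )
    def test_center_is_stagnant(self, pattern):
        # patterns with a symmetric cell arrangement stagnate at the centre;
        # the two-cell pattern instead carries through-flow between its cells
        f = FlowField(pattern, strain_rate=1.0, droplet_radius=1.0)
        u, v = velocity_at(f, 0.0, 0.0)
        assert u == pytest.approx(0.0, abs=1e-15)
        assert v == pytest.approx(0.0, abs=1e-15)

    def test_two_cell_center_through_flow(self):
        # psi = eps R y (1 - r^2/R^2): u(0,0) = eps R, between the two cells
        f = FlowField(FlowPattern.TWO_CELL, strain_rate=2.0, droplet_radius=0.5)
        u, v = velocity_at(f, 0.0, 0.0)
        assert u == pytest.approx(1.0)
        assert v == pytest.approx(0.0, abs=1e-15)

    def test_four_cell_hand_differentiated_streamfunction(self):
        # psi = x*y*(1 - r^2) gives (u, v) = (0, -0.375) at (0, 0.5)
        f = FlowField(FlowPattern.FOUR_CELL_BOUNDED, 1.0, 1.0)
        u, v = velocity_at(f, 0.0, 0.5)
        assert u == pytest.approx(0.0, abs=1e-15)
        assert v == pytest.approx(-0.375)

    def test_outside_droplet_raises(self):
        f = FlowField(FlowPattern.FOUR_CELL_BOUNDED, 1.0, 1.0)
        with pytest.raises(DomainError):
            velocity_at(f, 1.2, 0.0)

    @pytest.mark.parametrize("pattern", ALL_BOUNDED)
    def test_velocity_is_streamfunction_gradient(self, pattern):
        # finite-difference the analytic psi and compare to the velocities
        f = FlowField(pattern, strain_rate=0.7, droplet_radius=1.0)
        rng = np.random.default_rng(1)
        r = 0.8 * np.sqrt(rng.uniform(0, 1, 50))
        phi = rng.uniform(0, 2 * np.pi, 50)
        x, y = r * np.cos(phi), r * np.sin(phi)
        h = 1e-6
        u_fd = (flow.streamfunction_at(f, x, y + h) - flow.streamfunction_at(f, x, y - h)) / (2 * h)
        v_fd = -(flow.streamfunction_at(f, x + h, y) - flow.streamfunction_at(f, x - h, y)) / (2 * h)
        u, v = velocity_at(f, x, y)
        np.testing.assert_allclose(u, u_fd, atol=1e-8)
        np.testing.assert_allclose(v, v_fd, atol=1e-8)


class TestPolarComponents:
    @pytest.mark.parametrize(
        "uv,phi,expected",
        [((1.0, 0.0), 0.0, (1.0, 0.0)), ((1.0, 0.0), np.pi / 2, (0.0, -1.0))],
    )
    def test_rotation_examples(self, uv, phi, expected):
        u_r, u_t = polar_components(*uv, phi)
        assert u_r == pytest.approx(expected[0], abs=1e-15)
        assert u_t == pytest.approx(expected[1], abs=1e-15)

    def test_pure_strain_circumferential_component(self):
        # the torque integrand: u_theta = -eps * r * sin(2 phi)
        f = FlowField(FlowPattern.PURE_STRAIN, strain_rate=1.3)
        rng = np.random.default_rng(2)
        r = rng.uniform(0.1, 2.0, 100)
        phi = rng.uniform(0, 2 * np.pi, 100)
        u, v = velocity_at(f, r * np.cos(phi), r * np.sin(phi))
        _, u_t = polar_components(u, v, phi)
        np.testing.assert_allclose(u_t, -1.3 * r * np.sin(2 * phi), atol=1e-12)

    @given(
        u=st.floats(-1e3, 1e3),
        v=st.floats(-1e3, 1e3),
        phi=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_norm_preserved(self, u, v, phi):
        u_r, u_t = polar_components(u, v, phi)
        assert np.hypot(u_r, u_t) == pytest.approx(np.hypot(u, v), rel=1e-12, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("pattern", ALL_BOUNDED)
    def test_no_penetration_on_rim(self, pattern):
        # u . n vanishes to machine precision at analytic boundary points
        f = FlowField(pattern, strain_rate=1.0, droplet_radius=1.0)
        phi = np.linspace(0, 2 * np.pi, 73)
        x, y = np.cos(phi), np.sin(phi)
        u, v = velocity_at(f, x, y, check_domain=False)
        assert np.max(np.abs(u * x + v * y)) < 1e-14

    @pytest.mark.parametrize("pattern", ALL_BOUNDED)
    def test_incompressible_on_grid(self, pattern):
        # the fields are streamfunction-derived polynomials, so the central-
        # difference divergence cancels to rounding already at n = 64
        f = FlowField(pattern, strain_rate=1.0, droplet_radius=1.0)
        g = sample_grid(f, 64)
        du = np.gradient(g.u, g.x_coords, axis=1)
        dv = np.gradient(g.v, g.y_coords, axis=0)
        interior = (g.x_coords[None, :] ** 2 + g.y_coords[:, None] ** 2) < 0.8**2
        speed_scale = np.hypot(g.u, g.v).max()
        h = g.x_coords[1] - g.x_coords[0]
        assert np.max(np.abs((du + dv)[interior])) < 1e-10 * speed_scale / h

    def test_four_cell_limits_to_pure_strain_near_center(self):
        f = FlowField(FlowPattern.FOUR_CELL_BOUNDED, 1.0, 1.0)
        errs = []
        for r in (0.3, 0.1, 0.03):
            phi = np.linspace(0, 2 * np.pi, 37)
            x, y = r * np.cos(phi), r * np.sin(phi)
            u, v = velocity_at(f, x, y)
            err = np.hypot(u - x, v + y) / np.hypot(u, v).max()
            errs.append(np.max(err))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 5e-3

    def test_one_cell_vorticity_single_signed(self):
        g = sample_grid(FlowField(FlowPattern.ONE_CELL, 1.0, 1.0), 64)
        dv = np.gradient(g.v, g.x_coords, axis=1)
        du = np.gradient(g.u, g.y_coords, axis=0)
        interior = (g.x_coords[None, :] ** 2 + g.y_coords[:, None] ** 2) < 0.85**2
        curl = (dv - du)[interior]
        assert np.all(curl > 0)


class TestSampleGrid:
    def test_pure_strain_elementwise(self):
        g = sample_grid(FlowField(FlowPattern.PURE_STRAIN, 2.0, 1.0), 16)
        X, Y = np.meshgrid(g.x_coords, g.y_coords)
        np.testing.assert_allclose(g.u, 2.0 * X)
        np.testing.assert_allclose(g.v, -2.0 * Y)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            sample_grid(FlowField(FlowPattern.ONE_CELL, 1.0, 1.0), 4)

    def test_mask_matches_disk(self):
        g = sample_grid(FlowField(FlowPattern.ONE_CELL, 1.0, 2.0), 32)
        X, Y = np.meshgrid(g.x_coords, g.y_coords)
        np.testing.assert_array_equal(g.mask, X**2 + Y**2 <= 4.0)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "pattern,expected_label,expected_n",
        [
            (FlowPattern.ONE_CELL, "one_cell", 1),
            (FlowPattern.TWO_CELL, "two_cell", 2),
            (FlowPattern.FOUR_CELL_BOUNDED, "four_cell", 4),
        ],
    )
    @pytest.mark.parametrize("n", [64, 65])
    def test_known_patterns(self, pattern, expected_label, expected_n, n):
        g = sample_grid(FlowField(pattern, 1.0, 1.0), n)
        assert classify_pattern(g) == (expected_label, expected_n)

    def test_white_noise_is_random(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-1, 1, 64)
        g = VelocityGrid(
            x, x, rng.normal(size=(64, 64)), rng.normal(size=(64, 64)),
            np.ones((64, 64), bool),
        )
        label, n = classify_pattern(g)
        assert label == "random"
        assert n not in (1, 2, 4)

    def test_degenerate_field_is_random_zero(self):
        x = np.linspace(-1, 1, 64)
        z = np.zeros((64, 64))
        g = VelocityGrid(x, x, z, z.copy(), np.ones((64, 64), bool))
        assert classify_pattern(g) == ("random", 0)

    def test_small_grid_rejected(self):
        g = sample_grid(FlowField(FlowPattern.ONE_CELL, 1.0, 1.0), 16)
        with pytest.raises(ValueError):
            classify_pattern(g)


def test_grid_csv_roundtrip(tmp_path):
    g = sample_grid(FlowField(FlowPattern.TWO_CELL, 1.5, 2.0), 32)
    path = save_grid(g, tmp_path / "grid.csv")
    g2 = load_grid(path)
    np.testing.assert_allclose(g2.u, g.u)
    np.testing.assert_allclose(g2.v, g.v)
    np.testing.assert_array_equal(g2.mask, g.mask)
    assert g2.meta["pattern"] == "two_cell"
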