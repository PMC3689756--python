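"""Forward-model tests: exact vs ideal dipole potentials, boundary
rescaling, and the 3-D image-charge validation utilities."""

import numpy as np
import pytest

from dipoletrack import (
    DipoleState,
    ElectrodeArray,
    TankGeometry,
    boundary_scale,
    channel_response,
    image_series_potential,
    potential_exact,
    potential_ideal,
    vertical_electrode_potential,
)
from dipoletrack.field import SingularPointError, response_matrix


def two_monopole_oracle(dipole, point, d):
    """Independent re-derivation: superpose two line-source monopole
    potentials phi(q, r) = -q ln r with charges +/- c = moment/d."""
    c = dipole.moment / d
    u = dipole.heading
    p_plus = dipole.position + u * d / 2
    p_minus = dipole.position - u * d / 2
    r_plus = np.linalg.norm(np.asarray(point) - p_plus)
    r_minus = np.linalg.norm(np.asarray(point) - p_minus)
    return (-c * np.log(r_plus)) - (-c * np.log(r_minus))


class TestPotentialExact:
    def test_zero_on_perpendicular_bisector(self):
        for theta in (0.0, 30.0, 117.0):
            dip = DipoleState(0.0, 0.0, theta)
            # points on the line perpendicular to the axis through the center
            perp = np.radians(theta + 90.0)
            for dist in (3.0, 20.0):
                p = dist * np.array([np.cos(perp), np.sin(perp)])
                assert potential_exact(dip, p) == pytest.approx(0.0, abs=1e-12)

    def test_polarity_exchange_negates(self, rng):
        for _ in range(20):
            dip = DipoleState(*rng.uniform(-20, 20, 2), rng.uniform(0, 360))
            p = rng.uniform(-60, 60, 2)
            v = potential_exact(dip, p)
            assert potential_exact(dip.flipped(), p) == pytest.approx(-v, rel=1e-12)

    def test_matches_two_monopole_oracle(self, rng):
        for _ in range(50):
            dip = DipoleState(
                *rng.uniform(-20, 20, 2), rng.uniform(0, 360), moment=rng.uniform(0.5, 3)
            )
            p = rng.uniform(-70, 70, 2)
            d = rng.uniform(2, 15)
            if np.linalg.norm(p - dip.position) < d:
                continue
            assert potential_exact(dip, p, d=d) == pytest.approx(
                two_monopole_oracle(dip, p, d), rel=1e-12
            )

    def test_singular_point(self):
        dip = DipoleState(0, 0, 0)
        with pytest.raises(SingularPointError):
            potential_exact(dip, (5.0, 0.0), d=10.0)


class TestPotentialIdeal:
    def test_broadside_zero(self):
        dip = DipoleState(0, 0, 0)
        assert potential_ideal(dip, (0.0, 10.0)) == pytest.approx(0.0, abs=1e-15)

    def test_inverse_distance_scaling(self):
        dip = DipoleState(0, 0, 0)
        v1 = potential_ideal(dip, (10.0, 5.0))
        v2 = potential_ideal(dip, (20.0, 10.0))
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_linear_in_moment(self):
        p = (13.0, -4.0)
        v1 = potential_ideal(DipoleState(0, 0, 25, moment=1.0), p)
        v3 = potential_ideal(DipoleState(0, 0, 25, moment=3.0), p)
        assert v3 == pytest.approx(3 * v1, rel=1e-12)

    def test_far_field_convergence(self, rng):
        """Relative deviation from the exact form < 1% for R/d >= 20 and
        decreasing as (d/R)^2."""
        d = 10.0
        n = 1000
        theta = rng.uniform(0, 360, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        # avoid broadside directions where the ideal value crosses zero
        ratios = []
        for ratio in (20, 40, 80):
            R = ratio * d
            errs = []
            for i in range(n):
                dip = DipoleState(0, 0, theta[i])
                p = R * np.array([np.cos(phi[i]), np.sin(phi[i])])
                vi = potential_ideal(dip, p)
                ve = potential_exact(dip, p, d=d)
                if abs(vi) < 1e-4 / R:
                    continue
                errs.append(abs(vi - ve) / abs(ve))
            errs = np.array(errs)
            assert errs.max() < 0.01, f"R/d={ratio}"
            ratios.append(np.median(errs))
        # quadrupling R/d should reduce the error ~16x ((d/R)^2 scaling)
        assert ratios[2] < ratios[0] / 8


class TestBoundaryScale:
    def test_matched_wall_gives_zero(self):
        assert boundary_scale(TankGeometry(boundary_contrast=1.0)) == 0.0

    def test_sign_follows_contrast(self):
        assert boundary_scale(TankGeometry(boundary_contrast=4.0)) > 0
        assert boundary_scale(TankGeometry(boundary_contrast=0.25)) < 0

    def test_location_independent_image_ratio(self, rng):
        """The explicit circle-inversion image dipole contributes the same
        multiple k of the direct differential voltage at every dipole
        location (electrodes on the boundary)."""
        tank = TankGeometry(radius=75.0, boundary_contrast=5.0)
        k = boundary_scale(tank)
        d = 0.05  # near-ideal separation
        angles = np.radians([10.0, 150.0])
        electrodes = tank.radius * np.column_stack([np.cos(angles), np.sin(angles)])
        ratios = []
        for _ in range(100):
            pos = rng.uniform(-40, 40, 2)
            theta = rng.uniform(0, 360)
            u = np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
            srcs = [(pos + u * d / 2, 1.0), (pos - u * d / 2, -1.0)]
            direct, image = 0.0, 0.0
            for e_sign, e in ((1, electrodes[0]), (-1, electrodes[1])):
                for s, q in srcs:
                    direct += e_sign * (-q * np.log(np.linalg.norm(e - s)))
                    s_img = s * tank.radius**2 / (np.linalg.norm(s) ** 2)
                    image += e_sign * (-k * q * np.log(np.linalg.norm(e - s_img)))
            ratios.append(image / direct)
        assert np.allclose(ratios, k, rtol=1e-3)


class TestChannelResponse:
    def test_broadside_diametric_channel_is_zero(self, tank):
        arr = ElectrodeArray(
            channels=(((75.0, 0.0), (-75.0, 0.0)), ((0.0, 75.0), (0.0, -75.0)),
                      ((53.0, 53.0), (-53.0, -53.0)), ((53.0, -53.0), (-53.0, 53.0))),
            label="4P180-ish",
        )
        r = channel_response(DipoleState(0, 0, 90.0), arr, tank)
        assert r.values[0] == pytest.approx(0.0, abs=1e-15)

    def test_rotation_permutes_channels(self, tank, array8):
        base = channel_response(DipoleState(18.0, -7.0, 40.0), array8, tank).values
        rot = np.radians(45.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        p2 = R @ np.array([18.0, -7.0])
        rotated = channel_response(
            DipoleState(p2[0], p2[1], 40.0 + 45.0), array8, tank
        ).values
        # find the cyclic shift mapping rotated channels onto the originals
        shifts = [
            s
            for s in range(8)
            if np.allclose(np.roll(base, s), rotated, rtol=1e-9, atol=1e-12)
        ]
        assert len(shifts) == 1

    def test_linear_in_moment_and_unit_invariant(self, tank, array8):
        s1 = DipoleState(10, 10, 70, moment=1.0)
        s5 = DipoleState(10, 10, 70, moment=5.0)
        v1 = channel_response(s1, array8, tank).values
        v5 = channel_response(s5, array8, tank).values
        assert np.allclose(v5, 5 * v1)
        assert np.allclose(v5 / np.linalg.norm(v5), v1 / np.linalg.norm(v1))

    def test_zero_contrast_equals_plain_differencing(self, array8):
        t0 = TankGeometry(boundary_contrast=1.0)
        dip = DipoleState(25, -13, 200)
        v = channel_response(dip, array8, t0).values
        expected = np.array(
            [
                potential_ideal(dip, p) - potential_ideal(dip, n)
                for (p, n) in array8.channels
            ]
        )
        assert np.allclose(v, expected, rtol=0, atol=1e-15)

    def test_matches_explicit_image_construction(self, rng):
        """Unit-normalized responses agree with a brute-force model placing
        two discrete monopoles plus their explicit circle-inversion images
        outside the boundary (angular deviation < 1e-3 rad)."""
        tank = TankGeometry(radius=75.0, boundary_contrast=7.0)
        arr = ElectrodeArray(
            channels=tuple(
                (
                    (75 * np.cos(a), 75 * np.sin(a)),
                    (75 * np.cos(a + np.radians(67.5)), 75 * np.sin(a + np.radians(67.5))),
                )
                for a in np.radians(np.arange(0, 360, 45.0))
            ),
            label="test",
        )
        k = boundary_scale(tank)
        d = 0.02
        for _ in range(20):
            dip = DipoleState(*rng.uniform(-45, 45, 2), rng.uniform(0, 360))
            u = dip.heading
            srcs = [(dip.position + u * d / 2, 1.0 / d), (dip.position - u * d / 2, -1.0 / d)]
            brute = []
            for p_e, n_e in arr.channels:
                dv = 0.0
                for e_sign, e in ((1, np.array(p_e)), (-1, np.array(n_e))):
                    for s, q in srcs:
                        dv += e_sign * (-q * np.log(np.linalg.norm(e - s)))
                        s_img = s * tank.radius**2 / (np.linalg.norm(s) ** 2)
                        dv += e_sign * (-k * q * np.log(np.linalg.norm(e - s_img)))
                brute.append(dv)
            brute = np.array(brute) / np.linalg.norm(brute)
            model = channel_response(dip, arr, tank).values
            model = model / np.linalg.norm(model)
            cos = abs(float(brute @ model))
            assert np.arccos(min(cos, 1.0)) < 1e-3

    def test_response_matrix_matches_scalar_path(self, tank, array8, rng):
        states = np.column_stack(
            [rng.uniform(-40, 40, 10), rng.uniform(-40, 40, 10), rng.uniform(0, 360, 10)]
        )
        mat = response_matrix(states, array8, tank)
        for i, s in enumerate(states):
            v = channel_response(DipoleState(*s), array8, tank).values
            assert np.allclose(mat[i], v)


class TestImageSeries:
    def test_base_case_is_bare_monopole(self, tank):
        src = (0.0, 0.0, 5.0)
        p = (30.0, 0.0, 5.0)
        v0 = image_series_potential(src, tank, p, n_reflections=0)
        assert v0 == pytest.approx(1.0 / 30.0, rel=1e-12)

    def test_invalid_height(self, tank):
        with pytest.raises(ValueError):
            image_series_potential((0, 0, 20.0), tank, (30, 0, 5), 3)

    def test_partial_sums_converge(self, tank):
        src = (0.0, 0.0, 5.0)
        p = (10.0, 0.0, 5.0)  # r = depth
        vals = np.array(
            [image_series_potential(src, tank, p, n) for n in range(0, 121)]
        )
        inc = np.abs(np.diff(vals))
        above_floor = inc[inc > 1e-14 * abs(vals[-1])]
        assert np.all(np.diff(above_floor) < 0), "increments must strictly decrease"
        rel = inc / np.abs(vals[1:])
        assert rel[-1] < 1e-6, "series must converge to 1e-6 relative change"

    def test_vertical_electrode_far_field_linear_in_inverse_distance(self, tank):
        """Far field (R = 20-200 water depths, beyond the image stack's
        vertical extent): depth-averaged potential ~ C / R."""
        src = (0.0, 0.0, 5.0)
        R = np.geomspace(20 * tank.water_depth, 200 * tank.water_depth, 12)
        v = np.array(
            [
                vertical_electrode_potential(src, tank, (r, 0.0), n_reflections=150)
                for r in R
            ]
        )
        x = 1.0 / R
        coeffs = np.polyfit(x, v, 1)
        pred = np.polyval(coeffs, x)
        ss_res = np.sum((v - pred) ** 2)
        ss_tot = np.sum((v - v.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
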