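"""Frames, torsions and the sugar-center/C1' regressions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rnatrace.geometry import (
    CylindricalFrame,
    LocalSugarFrame,
    PhosphatePair,
    RegressionCoefficients,
    place_atom,
    place_c1prime,
    place_sugar_center,
    predict_rz,
    torsion,
)


class TestPredictRZ:
    def test_hand_evaluated_polynomials_at_reference_distance(self):
        r, z = predict_rz(5.9)
        assert r == pytest.approx(-0.186 * 5.9**2 + 1.623 * 5.9 - 0.124, abs=1e-12)
        assert r == pytest.approx(2.9770, abs=5e-5)
        assert z == pytest.approx(0.440 * 5.9 + 0.910, abs=1e-12)
        assert z == pytest.approx(3.5060, abs=5e-5)

    def test_zero_coefficients_give_zero(self):
        zero = RegressionCoefficients(a1=0, a2=0, a3=0, b1=0, b2=0)
        assert predict_rz(5.0, zero) == (0.0, 0.0)

    @pytest.mark.parametrize("bad_d", [0.0, -1.0, 10.5])
    def test_out_of_range_distance_rejected(self, bad_d):
        with pytest.raises(ValueError):
            predict_rz(bad_d)


class TestTorsion:
    def test_planar_cis_is_zero(self):
        assert torsion([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert torsion([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(180.0)

    def test_matches_atan2_oracle_on_random_points(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 3

            # independent oracle: project bond 1 and bond 3 onto the plane
            # normal to bond 2 and take the signed angle between them
            # (clockwise positive looking down the central bond)
            b2 = p[2] - p[1]
            b2h = b2 / np.linalg.norm(b2)
            back = p[0] - p[1]   # from the axis toward the near atom
            fwd = p[3] - p[2]    # from the axis toward the far atom
            u = back - (back @ b2h) * b2h
            v = fwd - (fwd @ b2h) * b2h
            expected = np.degrees(np.arctan2(np.cross(v, u) @ b2h, u @ v))
            assert torsion(*p) == pytest.approx(expected, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            torsion([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestPlaceAtom:
    def test_roundtrip_internal_coordinates(self):
        rng = np.random.default_rng(11)
        from rnatrace.geometry import angle

        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3)) * 2
            tor = rng.uniform(-179, 179)
            ang = rng.uniform(60, 150)
            bond = rng.uniform(1.2, 1.8)
            d = place_atom(a, b, c, bond, ang, tor)
            assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
            assert angle(b, c, d) == pytest.approx(ang, abs=1e-9)
            assert torsion(a, b, c, d) == pytest.approx(tor, abs=1e-9)


@settings(derandomize=True, max_examples=50)
@given(
    seed=st.integers(0, 10_000),
    bond=st.floats(1.2, 1.8),
    ang=st.floats(45.0, 160.0),
    tor=st.floats(-179.0, 179.0),
)
def test_internal_coordinate_placement_roundtrip_property(seed, bond, ang, tor):
    """For any reference geometry and internal coordinates, the placed atom
    reads back exactly the bond/angle/torsion it was built with."""
    from rnatrace.geometry import angle as angle_of

    rng = np.random.default_rng(seed)
    a, b, c = rng.normal(size=(3, 3)) * 2
    if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
        return  # degenerate reference frame
    d = place_atom(a, b, c, bond, ang, tor)
    assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
    assert angle_of(b, c, d) == pytest.approx(ang, abs=1e-8)
    assert torsion(a, b, c, d) == pytest.approx(tor, abs=1e-8)


class TestFrames:
    def test_cylindrical_roundtrip(self):
        pair = PhosphatePair(p5=np.array([1.0, 2, 3]), p3=np.array([4.0, 6, 3]))
        frame = CylindricalFrame.from_pair(pair)
        pt = np.array([2.5, 1.0, 5.0])
        r, xi, z = frame.to_cylindrical(pt)
        assert np.allclose(frame.to_cartesian(r, xi, z), pt, atol=1e-9)

    def test_local_frame_orthonormal_with_stated_handedness(self):
        f = LocalSugarFrame.from_points([0, 0, 0], [3, 1, 0.5], [3, -1, -0.5])
        for ax in (f.x_axis, f.y_axis, f.z_axis):
            assert np.linalg.norm(ax) == pytest.approx(1.0, abs=1e-9)
        assert abs(f.x_axis @ f.y_axis) < 1e-9
        assert abs(f.x_axis @ f.z_axis) < 1e-9
        # the defining relation of the empirical frame
        assert np.allclose(np.cross(f.y_axis, f.x_axis), f.z_axis, atol=1e-9)

    def test_local_frame_collinear_rejected(self):
        with pytest.raises(ValueError):
            LocalSugarFrame.from_points([0, 0, 0], [1, 0, 0], [-2, 0, 0])

    def test_frames_equivariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=3)
        p5 = g + rng.normal(size=3)
        p3 = g + rng.normal(size=3)
        local = np.array([-1.036, 0.202, -0.601])
        world = LocalSugarFrame.from_points(g, p5, p3).to_world(local)
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        world2 = LocalSugarFrame.from_points(
            rot @ g + shift, rot @ p5 + shift, rot @ p3 + shift
        ).to_world(local)
        assert np.allclose(world2, rot @ world + shift, atol=1e-9)


class TestC1Prime:
    def test_offset_magnitude(self):
        pair = PhosphatePair(p5=np.array([3.0, 1, 0.5]), p3=np.array([3.0, -1, -0.5]))
        c1p = place_c1prime(np.zeros(3), pair)
        expected = np.linalg.norm([-1.036, 0.202, -0.601])
        assert np.linalg.norm(c1p) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(1.2146, abs=5e-5)

    def test_swapping_phosphates_mirrors_c1prime(self):
        p5 = np.array([3.0, 1, 0.5])
        p3 = np.array([3.0, -1, -0.5])
        c1 = place_c1prime(np.zeros(3), PhosphatePair(p5=p5, p3=p3))
        c2 = place_c1prime(np.zeros(3), PhosphatePair(p5=p3, p3=p5))
        # x (bisector) component preserved, in-plane y flips with the frame
        f = LocalSugarFrame.from_points(np.zeros(3), p5, p3)
        l1, l2 = f.to_local(c1), f.to_local(c2)
        assert l1[0] == pytest.approx(l2[0], abs=1e-9)
        assert l1[1] == pytest.approx(-l2[1], abs=1e-9)

    def test_recovers_fixture_c1prime_from_true_sugar_center(self, helix12):
        _, model, _, _ = helix12
        errs = []
        for i in range(11):
            pair = PhosphatePair(p5=model.atom(i, "P"), p3=model.atom(i + 1, "P"))
            c1p = place_c1prime(model.sugar_center(i), pair)
            errs.append(np.linalg.norm(c1p - model.atom(i, "C1'")))
        assert max(errs) < 0.5


class TestSugarCenter:
    def test_fixture_recovery_within_half_angstrom(self, helix7):
        _, model, grid, _ = helix7
        errs = []
        for i in range(6):
            pair = PhosphatePair(p5=model.atom(i, "P"), p3=model.atom(i + 1, "P"))
            sc = place_sugar_center(pair, grid)
            errs.append(np.linalg.norm(sc.position - model.sugar_center(i)))
        assert np.mean(errs) < 0.5

    def test_azimuth_beats_random_probes(self, helix7):
        from rnatrace.density import sample_segment_density

        _, model, grid, _ = helix7
        pair = PhosphatePair(p5=model.atom(2, "P"), p3=model.atom(3, "P"))
        sc = place_sugar_center(pair, grid)

        def objective(xi):
            g = sc.frame.to_cartesian(sc.r, xi, sc.z)
            return sample_segment_density(grid, g, pair.p5, 10) + sample_segment_density(
                grid, g, pair.p3, 10
            )

        best = objective(sc.xi)
        rng = np.random.default_rng(13)
        for xi in rng.uniform(0, 360, size=36):
            assert objective(xi) <= best + 1e-9

    def test_symmetric_density_returns_first_scan_maximizer(self):
        from rnatrace.density import DensityGrid

        # radially symmetric field about the P-P axis (x axis)
        n = 33
        ax = np.linspace(-8, 8, n)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = np.exp(-(Y**2 + Z**2) / 20.0)
        grid = DensityGrid(origin=np.array([-8.0, -8.0, -8.0]),
                           voxel_spacing=np.full(3, ax[1] - ax[0]), values=vals)
        pair = PhosphatePair(p5=np.array([-2.9, 0, 0]), p3=np.array([2.9, 0, 0]))
        sc = place_sugar_center(pair, grid)
        assert sc.xi == pytest.approx(0.0, abs=2.0)  # first maximizer tie-break

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            PhosphatePair(p5=np.zeros(3), p3=np.zeros(3))
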