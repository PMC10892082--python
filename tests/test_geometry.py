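"""Geometric kernels: angles, circumradii, contacts, CDFs, length scales."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tangentchain import geometry
from tangentchain.conformation import CdfTable, Conformation
from tangentchain.geometry import (
    bond_bending_angle,
    circumradius_triplet,
    circumsphere_radius_quartet,
    contact_map,
    dihedral_angle,
    fit_loglog_slope,
    histogram_mode,
    inverse_radius_cdf,
    local_radius_from_theta,
    nearest_nonlocal_contact,
    nearest_nonlocal_distances,
    quartet_circumsphere_radii,
    scaled_profile,
    theta_mu_map,
    triplet_circumradii,
)

B = 3.81


def _isoceles(theta_deg, b=B):
    """Triplet with both bonds b and vertex angle theta at the middle point."""
    h = np.radians(theta_deg) / 2
    return (
        np.array([b * np.cos(h), b * np.sin(h), 0.0]),
        np.zeros(3),
        np.array([b * np.cos(h), -b * np.sin(h), 0.0]),
    )


class TestAngles:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0, 0), (1, 0, 0), (2, 0, 0)], 180.0),
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0)], 90.0),
            ([(0, 0, 0), (1, 0, 0), (0.5, np.sqrt(3) / 2, 0)], 60.0),
        ],
    )
    def test_bond_bending_examples(self, pts, expected):
        assert bond_bending_angle(*pts) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            bond_bending_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_dihedral_trans_zigzag_is_180(self):
        mu = dihedral_angle((0, 0, 0), (1, 0, 0), (1.5, 0.87, 0), (2.5, 0.87, 0))
        assert abs(mu) == pytest.approx(180.0, abs=1e-9)

    def test_dihedral_cis_fold_is_0(self):
        mu = dihedral_angle((0, 0, 0), (1, 0, 0), (1.5, 0.87, 0), (1.0, 1.6, 0))
        assert mu == pytest.approx(0.0, abs=1e-9)

    def test_dihedral_perpendicular_quartet(self):
        # 4th point rotated 90 deg out of plane about the p2-p3 axis;
        # oracle: the binormals n1 = b1 x b2 and n2 = b2 x b3 meet at 90 deg
        p1, p2, p3 = np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, 1.0, 0])
        p4 = p3 + np.array([0.0, 0.0, 1.0])
        n1 = np.cross(p2 - p1, p3 - p2)
        n2 = np.cross(p3 - p2, p4 - p3)
        oracle = np.degrees(
            np.arccos(np.dot(n1, n2) / np.linalg.norm(n1) / np.linalg.norm(n2))
        )
        assert abs(dihedral_angle(p1, p2, p3, p4)) == pytest.approx(oracle, abs=1e-9)
        assert oracle == pytest.approx(90.0, abs=1e-9)

    def test_dihedral_collinear_triplet_raises(self):
        with pytest.raises(ValueError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestCircumradius:
    def test_equilateral(self):
        s = circumradius_triplet((0, 0, 0), (1, 0, 0), (0.5, np.sqrt(3) / 2, 0))
        assert s.R == pytest.approx(1 / np.sqrt(3), rel=1e-12)
        assert s.order == 3

    def test_collinear_is_infinite(self):
        s = circumradius_triplet((0, 0, 0), (1, 0, 0), (2, 0, 0))
        assert np.isinf(s.R) and s.X == 0.0

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            circumradius_triplet((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(theta=st.floats(min_value=1.0, max_value=179.0))
    def test_isoceles_matches_local_radius_formula(self, theta):
        # oracle: R = b / (2 cos(theta/2)) for a both-bonds-b triplet
        s = circumradius_triplet(*_isoceles(theta))
        assert s.R == pytest.approx(local_radius_from_theta(theta, B), rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_rigid_motion_invariance_and_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 5
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.normal(size=3) * 20
        moved = pts @ R.T + t
        r0 = triplet_circumradii(pts[0], pts[1], pts[2])
        r1 = triplet_circumradii(moved[0], moved[1], moved[2])
        assert r1 == pytest.approx(r0, rel=1e-8)
        s0 = quartet_circumsphere_radii(*pts)
        s1 = quartet_circumsphere_radii(*moved)
        assert s1 == pytest.approx(s0, rel=1e-7)
        # uniform scaling scales both radii linearly
        assert triplet_circumradii(*(scale * pts[:3])) == pytest.approx(scale * r0, rel=1e-8)
        assert quartet_circumsphere_radii(*(scale * pts)) == pytest.approx(scale * s0, rel=1e-7)


class TestCircumsphere:
    def test_regular_tetrahedron(self):
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        edge = np.linalg.norm(tet[0] - tet[1])
        s = circumsphere_radius_quartet(*tet)
        assert s.R / edge == pytest.approx(np.sqrt(3 / 8), rel=1e-12)

    def test_coplanar_is_infinite(self):
        s = circumsphere_radius_quartet((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0))
        assert np.isinf(s.R) and s.X == 0.0

    def test_center_equidistant_residual(self, rng):
        pts = rng.normal(size=(200, 4, 3)) * 4
        R, centers = quartet_circumsphere_radii(
            pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3], return_centers=True
        )
        ok = np.isfinite(R)
        for k in range(4):
            d = np.linalg.norm(centers[ok] - pts[ok, k], axis=1)
            assert np.max(np.abs(d - R[ok]) / R[ok]) < 1e-9


class TestLocalRadius:
    def test_straight_is_infinite(self):
        assert np.isinf(local_radius_from_theta(180.0, B))

    def test_hard_sphere_minimum(self):
        assert local_radius_from_theta(60.0, B) == pytest.approx(B / np.sqrt(3), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            local_radius_from_theta(181.0, B)
        with pytest.raises(ValueError):
            local_radius_from_theta(0.0, B)


class TestThetaMuMap:
    def test_frame_count_and_n4(self):
        rng = np.random.default_rng(3)
        coords = np.cumsum(rng.normal(size=(10, 3)), axis=0)
        frames = theta_mu_map(Conformation(coords))
        assert len(frames) == 10 - 3
        assert len(theta_mu_map(Conformation(coords[:4]))) == 1

    def test_straight_chain_mu_undefined(self):
        coords = np.zeros((6, 3))
        coords[:, 0] = np.arange(6)
        frames = theta_mu_map(Conformation(coords))
        assert all(f.theta == pytest.approx(180.0) for f in frames)
        assert all(np.isnan(f.mu) for f in frames)

    def test_helix_frames_match_direct_angles(self, helix30):
        frames = theta_mu_map(helix30)
        thetas = geometry.chain_thetas(helix30.coords)
        mus = geometry.chain_mus(helix30.coords)
        for k, f in enumerate(frames):
            assert f.theta == pytest.approx(thetas[k], abs=1e-9)
            assert f.mu == pytest.approx(mus[k], abs=1e-9)
        # ideal helix: one tight (theta, mu) cluster
        assert np.ptp([f.theta for f in frames]) < 1e-6
        assert np.ptp([f.mu for f in frames]) < 1e-6


class TestContacts:
    def test_straight_chain_partner_at_sep3(self):
        coords = np.zeros((10, 3))
        coords[:, 0] = np.arange(10) * B
        records = nearest_nonlocal_contact(Conformation(coords, bond_length=B))
        for r in records:
            assert r.separation == 3
            assert r.distance == pytest.approx(3 * B, rel=1e-12)

    def test_n4_single_admissible_pair(self):
        rng = np.random.default_rng(0)
        coords = np.cumsum(rng.normal(size=(4, 3)), axis=0)
        records = nearest_nonlocal_contact(Conformation(coords), min_sep=3)
        # only the two end beads admit a partner at separation >= 3
        assert [(r.i, r.j) for r in records] == [(0, 3), (3, 0)]

    def test_too_short_chain_warns_empty(self):
        coords = np.zeros((3, 3))
        coords[:, 0] = np.arange(3)
        with pytest.warns(UserWarning):
            assert nearest_nonlocal_contact(Conformation(coords), min_sep=3) == []

    @pytest.mark.parametrize("n", [5, 8, 13, 20])
    def test_brute_force_oracle(self, n, rng):
        coords = np.cumsum(rng.normal(size=(n, 3)) * 2, axis=0)
        j, d = nearest_nonlocal_distances(coords, min_sep=3)
        for i in range(n):
            best_j, best_d = None, np.inf
            for jj in range(n):
                if abs(i - jj) < 3:
                    continue
                dd = np.linalg.norm(coords[i] - coords[jj])
                if dd < best_d:
                    best_j, best_d = jj, dd
            if best_j is None:  # interior bead of a very short chain
                assert not np.isfinite(d[i])
                continue
            assert j[i] == best_j
            assert d[i] == pytest.approx(best_d, rel=1e-12)

    def test_tie_breaks_to_smallest_j(self):
        # symmetric chain: bead 3 equidistant from 0 and 6
        coords = np.array(
            [[-3, 1, 0], [-2, 0, 0], [-1, 1, 0], [0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0]],
            dtype=float,
        )
        j, d = nearest_nonlocal_distances(coords, min_sep=3)
        assert j[3] == 0

    def test_contact_map_near_far(self, helix30):
        straight = np.zeros((10, 3))
        straight[:, 0] = np.arange(10) * B
        far = contact_map(Conformation(straight, bond_length=B))
        assert all(not r.near_flag for r in far)  # 11.43 A > 6 A
        near = contact_map(helix30)
        assert all(r.near_flag for r in near)  # ~5.05 A < 6 A

    def test_antiparallel_sheet_cross_diagonal(self, antiparallel_sheet):
        conf = antiparallel_sheet
        records = contact_map(conf)
        ij = [
            r.i + r.j
            for r in records
            if r.near_flag and conf.labels[r.i] == "beta" and conf.labels[r.j] == "beta"
        ]
        assert ij, "expected cross-strand near contacts"
        assert np.ptp(ij) <= 6  # i + j approximately constant across the hairpin


class TestCdf:
    def test_identical_samples_step_function(self):
        cdf = inverse_radius_cdf(np.full(50, 2.0))
        assert np.allclose(cdf.x, 0.5)
        assert cdf.p[-1] == 1.0

    def test_all_infinite_degenerate_at_zero(self):
        cdf = inverse_radius_cdf(np.full(10, np.inf))
        assert np.all(cdf.x == 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inverse_radius_cdf(np.array([]))

    def test_monotone_bounded(self, rng):
        cdf = inverse_radius_cdf(rng.uniform(0.5, 5.0, 1000))
        assert np.all(np.diff(cdf.p) >= 0)
        assert 0 < cdf.p[0] <= 1 and cdf.p[-1] == 1.0

    def test_fit_recovers_exact_power_law(self):
        # P = (x b / 2)^2: log-log slope exactly 2
        x = np.linspace(1e-3, 2 / B, 2000)
        cdf = CdfTable(x=x, p=(x * B / 2) ** 2, n_samples=2000, bond_length=B)
        assert fit_loglog_slope(cdf) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("exponent", [0.5, 1.0, 3.0])
    def test_fit_synthetic_exponents(self, exponent):
        x = np.linspace(1e-3, 2 / B, 5000)
        cdf = CdfTable(x=x, p=(x * B / 2) ** exponent, n_samples=5000, bond_length=B)
        assert fit_loglog_slope(cdf) == pytest.approx(exponent, abs=0.02)

    def test_too_few_points_rejected(self):
        cdf = CdfTable(x=np.array([0.1, 0.2]), p=np.array([0.5, 1.0]), n_samples=2, bond_length=B)
        with pytest.raises(ValueError):
            fit_loglog_slope(cdf)


class TestLengthScales:
    def test_histogram_mode_simple(self):
        v = np.concatenate([np.full(100, 2.21), np.full(10, 3.0)])
        assert histogram_mode(v, 0.02) == pytest.approx(2.21, abs=0.02)

    def test_ideal_helix_local_mode_matches_closed_form(self, rng):
        from tangentchain.synthetic import HelixParams, ideal_alpha_helix

        base = ideal_alpha_helix(HelixParams(n=40))
        theta = geometry.chain_thetas(base.coords)[0]
        expected = local_radius_from_theta(theta, base.bond_length)
        confs = []
        for _ in range(50):
            jittered = base.coords + rng.normal(0, 0.01, base.coords.shape)
            confs.append(Conformation(jittered, bond_length=base.bond_length))
        local_mode, _ = geometry.length_scale_modes(confs)
        assert local_mode == pytest.approx(expected, abs=0.05)

    def test_empty_class_error_names_class(self, helix30):
        with pytest.raises(ValueError, match="beta"):
            geometry.length_scale_modes([helix30], class_filter="beta")


class TestScaledProfile:
    def test_unit_scales_identity(self, helix30):
        loc, non = scaled_profile(helix30, 1.0, 1.0)
        thetas = geometry.chain_thetas(helix30.coords)
        assert loc[1] == pytest.approx(local_radius_from_theta(thetas[0], helix30.bond_length))
        assert np.isnan(loc[0]) and np.isnan(loc[-1])

    def test_helix_with_alpha_scales_near_one(self, helix30):
        # scaled by its own characteristic scales, the helix sits near 1
        thetas = geometry.chain_thetas(helix30.coords)
        local_scale = local_radius_from_theta(thetas[0], helix30.bond_length)
        _, d = nearest_nonlocal_distances(helix30.coords)
        loc, non = scaled_profile(
            helix30, {"alpha": local_scale}, {"alpha": np.median(d)}
        )
        assert np.nanmax(np.abs(loc - 1)) < 0.05
        assert np.nanmax(np.abs(non - 1)) < 0.15

    def test_straight_chain_scaled_local_infinite(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8) * B
        loc, _ = scaled_profile(Conformation(coords, bond_length=B), 2.0, 2.0)
        assert np.all(np.isinf(loc[1:-1]))

    def test_missing_class_scale_errors(self, helix30):
        with pytest.raises(KeyError):
            scaled_profile(helix30, {"beta": 1.0}, {"beta": 1.0})
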