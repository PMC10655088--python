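import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from picontact import (
    DegenerateGeometryError,
    VGCParams,
    fit_plane,
    projected_pair_distances,
    scan_pairs,
    vgc_test,
)
from picontact.synthetic import (
    GeometrySpec,
    make_dimer_geometry,
    ring_coords,
)
from .oracles import brute_force_contact, covariance_plane, random_dimer_coords


def hexagon():
    return ring_coords(6, 1.39)


class TestFitPlane:
    def test_flat_hexagon(self):
        plane = fit_plane(hexagon())
        assert abs(abs(plane.unit_normal[2]) - 1.0) < 1e-12
        assert plane.rms_deviation == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(plane.centroid, 0.0, atol=1e-12)

    def test_rotational_equivariance(self):
        rot = Rotation.from_euler("zyx", [31.0, -57.0, 113.0], degrees=True)
        plane = fit_plane(rot.apply(hexagon()))
        expected = rot.apply([0.0, 0.0, 1.0])
        assert min(
            np.linalg.norm(plane.unit_normal - expected),
            np.linalg.norm(plane.unit_normal + expected),
        ) < 1e-9

    def test_perturbed_hexagon_matches_covariance_oracle(self):
        coords = hexagon()
        coords[:, 2] += np.array([0.01, -0.01, 0.01, -0.01, 0.01, -0.01])
        plane = fit_plane(coords)
        angle = np.degrees(
            np.arccos(min(1.0, abs(plane.unit_normal[2])))
        )
        assert angle < 1.0
        _, oracle_normal, oracle_rms = covariance_plane(coords)
        assert abs(plane.rms_deviation - oracle_rms) < 1e-12
        assert abs(abs(np.dot(plane.unit_normal, oracle_normal)) - 1.0) < 1e-12

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
        with pytest.raises(DegenerateGeometryError):
            fit_plane(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([[0, 0, 0], [1, 0, 0]])


class TestProjectedDistances:
    @pytest.mark.parametrize(
        "separation,expected",
        [(3.4, 0.0), (5.0, 1.6)],
    )
    def test_cofacial_aligned(self, separation, expected):
        a, b = make_dimer_geometry(GeometrySpec(separation=separation))
        dmat = projected_pair_distances(a, b, 1.7)
        assert np.diag(dmat) == pytest.approx(np.full(6, expected), abs=1e-9)

    def test_coincident_planes_pass_through(self):
        from picontact.synthetic import _ring_group

        ga = _ring_group(hexagon(), "a", 1, [0, 0, 1])
        gb = _ring_group(hexagon(), "b", 2, [0, 0, 1])
        dmat = projected_pair_distances(ga, gb, 1.7)
        assert np.diag(dmat) == pytest.approx(np.full(6, 3.4), abs=1e-9)


class TestVGCTest:
    def test_cofacial_contact(self):
        a, b = make_dimer_geometry(GeometrySpec(separation=3.4))
        rec = vgc_test(a, b)
        assert rec.is_pi_contact
        assert rec.n_close_pairs >= 6
        assert rec.normal_dot == pytest.approx(1.0)

    def test_perpendicular_never_contacts(self):
        for sep in (2.0, 3.4, 5.0):
            a, b = make_dimer_geometry(GeometrySpec(motif="t_shaped", separation=sep))
            rec = vgc_test(a, b)
            assert rec.normal_dot == pytest.approx(0.0, abs=1e-9)
            assert not rec.is_pi_contact

    @pytest.mark.parametrize(
        "separation,expected", [(4.8, True), (5.0, False)]
    )
    def test_distance_threshold(self, separation, expected):
        """Aligned rings flip at separation 2 x 1.7 + 1.5 = 4.9 A."""
        a, b = make_dimer_geometry(GeometrySpec(separation=separation))
        assert vgc_test(a, b).is_pi_contact is expected

    @pytest.mark.parametrize("tilt,expected", [(35.0, True), (40.0, False)])
    def test_angle_threshold(self, tilt, expected):
        """cos 35 = 0.819 passes the 0.8 rule; cos 40 = 0.766 fails."""
        a, b = make_dimer_geometry(
            GeometrySpec(motif="tilted", tilt_deg=tilt, separation=3.4)
        )
        rec = vgc_test(a, b)
        assert rec.normal_dot == pytest.approx(np.cos(np.radians(tilt)), abs=1e-9)
        assert rec.is_pi_contact is expected

    def test_symmetry(self, rng):
        for seed in range(20):
            a, b = make_dimer_geometry(
                GeometrySpec(motif="random", separation=rng.uniform(2, 7), seed=seed)
            )
            r_ab = vgc_test(a, b)
            r_ba = vgc_test(b, a)
            assert r_ab.is_pi_contact == r_ba.is_pi_contact
            assert r_ab.n_close_pairs == r_ba.n_close_pairs
            assert r_ab.normal_dot == pytest.approx(r_ba.normal_dot, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        angles=st.tuples(
            st.floats(-180, 180), st.floats(-90, 90), st.floats(-180, 180)
        ),
        translation=st.tuples(
            st.floats(-40, 40), st.floats(-40, 40), st.floats(-40, 40)
        ),
        seed=st.integers(0, 50),
    )
    def test_rigid_body_invariance(self, angles, translation, seed):
        """A common rotation+translation changes no contact diagnostic."""
        from picontact.synthetic import _ring_group

        a, b = make_dimer_geometry(
            GeometrySpec(motif="random", separation=4.0, seed=seed)
        )
        before = vgc_test(a, b)
        rot = Rotation.from_euler("zyx", angles, degrees=True)
        t = np.asarray(translation)
        ga = _ring_group(rot.apply(a.coords) + t, "a", 1, [0, 0, 1])
        gb = _ring_group(rot.apply(b.coords) + t, "b", 2, [0, 0, 1])
        after = vgc_test(ga, gb)
        assert after.is_pi_contact == before.is_pi_contact
        assert after.n_close_pairs == before.n_close_pairs
        assert after.normal_dot == pytest.approx(before.normal_dot, abs=1e-9)
        assert after.min_projected_distance == pytest.approx(
            before.min_projected_distance, abs=1e-9
        )

    def test_monotonic_in_separation(self):
        """Pulling cofacial rings apart never creates a contact."""
        last_contact = True
        for sep in np.linspace(3.0, 8.0, 101):
            a, b = make_dimer_geometry(GeometrySpec(separation=float(sep)))
            now = vgc_test(a, b).is_pi_contact
            assert not (now and not last_contact)
            last_contact = now

    def test_cutoff_consistency(self):
        a, b = make_dimer_geometry(GeometrySpec(motif="random", separation=6.0, seed=9))
        everything = VGCParams(
            pair_distance_cutoff=1e6, normal_dot_cutoff=1e-9, min_pairs=1
        )
        assert vgc_test(a, b, everything).is_pi_contact
        nothing = VGCParams(min_pairs=6 * 6 + 1)
        assert not vgc_test(a, b, nothing).is_pi_contact

    def test_tie_at_cutoffs_passes(self):
        """The rules are <= and >=: exact ties count as contacts."""
        a, b = make_dimer_geometry(GeometrySpec(separation=5.0))
        tie = rec_min(a, b)  # 1.6 A for aligned rings at 5.0 A
        passing = vgc_test(a, b, VGCParams(pair_distance_cutoff=tie))
        failing = vgc_test(a, b, VGCParams(pair_distance_cutoff=tie - 1e-9))
        assert passing.is_pi_contact and not failing.is_pi_contact
        tilted = make_dimer_geometry(GeometrySpec(motif="tilted", tilt_deg=30.0))
        dot = vgc_test(*tilted).normal_dot
        assert vgc_test(*tilted, VGCParams(normal_dot_cutoff=dot)).is_pi_contact

    def test_brute_force_equivalence_sample(self, rng):
        """Detector decisions match the independent oracle exactly."""
        for _ in range(200):
            ca, cb = random_dimer_coords(rng)
            from picontact.synthetic import _ring_group

            rec = vgc_test(
                _ring_group(ca, "a", 1, [0, 0, 1]),
                _ring_group(cb, "b", 2, [0, 0, 1]),
            )
            expected, n_close, dot = brute_force_contact(ca, cb)
            assert rec.is_pi_contact == expected
            assert rec.n_close_pairs == n_close
            assert rec.normal_dot == pytest.approx(dot, abs=1e-9)


def rec_min(a, b):
    dmat = projected_pair_distances(a, b, 1.7)
    return float(dmat.min())


class TestScanPairs:
    def test_distant_groups_all_negative(self):
        from picontact.synthetic import _ring_group

        groups = [
            _ring_group(hexagon() + [40.0 * i, 0, 0], f"g{i}", i + 1, [0, 0, 1])
            for i in range(3)
        ]
        records = scan_pairs(groups)
        assert len(records) == 3
        assert not any(r.is_pi_contact for r in records)

    def test_self_pair_never_emitted(self):
        from picontact.synthetic import _ring_group

        g = _ring_group(hexagon(), "solo", 1, [0, 0, 1])
        assert scan_pairs([g, g]) == []

    def test_engineered_pair_among_decoys(self):
        """scan_pairs agrees with an exhaustive all-pairs oracle."""
        from picontact.synthetic import _ring_group

        rot = Rotation.from_euler("y", 70, degrees=True)
        blocks = [
            hexagon(),
            hexagon() + [0.5, 0.0, 3.5],  # planted partner of block 0
            rot.apply(hexagon()) + [30.0, 0, 0],
            hexagon() + [0, 40.0, 0],
            rot.apply(hexagon()) + [0, 0, 50.0],
        ]
        groups = [
            _ring_group(c, f"g{i}", i + 1, [0, 0, 1]) for i, c in enumerate(blocks)
        ]
        records = scan_pairs(groups)
        assert len(records) == 10
        hits = [(r.group_a, r.group_b) for r in records if r.is_pi_contact]
        oracle_hits = []
        for i in range(5):
            for j in range(i + 1, 5):
                ok, _, _ = brute_force_contact(blocks[i], blocks[j])
                if ok:
                    oracle_hits.append((f"g{i}", f"g{j}"))
        assert hits == oracle_hits == [("g0", "g1")]

    def test_adjacent_backbone_amides_excluded(self, tripeptide_atoms):
        from picontact import extract_planar_groups

        groups = extract_planar_groups(tripeptide_atoms)
        records = scan_pairs(groups)
        pairs = {(r.group_a, r.group_b) for r in records}
        # Amides 1-2 and 2-3 share residue 2: never evaluated.
        assert ("A:1-2:BB", "A:2-3:BB") not in pairs
        # The Phe side chain is never paired with its own amides.
        assert not any("A:2:PHE:SC" in p for p in pairs if "BB" in p[0] + p[1])
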