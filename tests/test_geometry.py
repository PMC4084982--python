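import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribofit.geometry import (ScrewMotion, gate_width, head_angle,
                              ratchet_angle, screw_decompose,
                              split_internal_external)
from ribofit.structure import RigidTransform, SelectionSpec
from test_structure import bead_model


def rotate_group(model, indices, axis, angle_deg, pivot):
    out = model.copy()
    R = Rotation.from_rotvec(np.radians(angle_deg)
                             * np.asarray(axis, float))
    out.coords[indices] = R.apply(model.coords[indices] - pivot) + pivot
    return out


@pytest.fixture(scope="module")
def two_body():
    """Large body at origin, small body above it along +z."""
    rng = np.random.default_rng(21)
    large = rng.uniform(-8, 8, (60, 3)) * [1.4, 1.1, 0.9]
    small = rng.uniform(-6, 6, (40, 3)) * [1.2, 0.9, 0.7] + [0, 0, 20.0]
    coords = np.vstack([large, small])
    m = bead_model(coords, masses=np.full(100, 15.0))
    m.groups = {"large": np.arange(60), "small": np.arange(60, 100)}
    return m


LARGE = SelectionSpec.group("large")
SMALL = SelectionSpec.group("small")


class TestRatchetAngle:
    def test_identity_pair_gives_zero(self, two_body):
        assert ratchet_angle(two_body, two_body, LARGE,
                             SMALL) == pytest.approx(0.0, abs=1e-9)

    def test_rotation_about_intersubunit_axis_recovered(self, two_body):
        # e_ratchet points small COM -> large COM = -z here
        e = np.array([0.0, 0.0, -1.0])
        pivot = two_body.coords[60:].mean(0)
        # rotate the small body so the model->reference fit reports +5 deg
        rotated = rotate_group(two_body, np.arange(60, 100), e, -5.0, pivot)
        angle = ratchet_angle(rotated, two_body, LARGE, SMALL)
        assert angle == pytest.approx(5.0, abs=0.1)

    def test_perpendicular_rotation_projects_to_zero(self, two_body):
        pivot = two_body.coords[60:].mean(0)
        rotated = rotate_group(two_body, np.arange(60, 100),
                               [1.0, 0, 0], 5.0, pivot)
        angle = ratchet_angle(rotated, two_body, LARGE, SMALL)
        assert abs(angle) < 0.5

    def test_antisymmetric_under_swap(self, two_body):
        e = np.array([0.0, 0.0, -1.0])
        pivot = two_body.coords[60:].mean(0)
        rotated = rotate_group(two_body, np.arange(60, 100), e, -4.0, pivot)
        a = ratchet_angle(rotated, two_body, LARGE, SMALL)
        b = ratchet_angle(two_body, rotated, LARGE, SMALL)
        assert a == pytest.approx(-b, abs=0.2)

    def test_invariant_under_global_motion_of_both(self, two_body):
        e = np.array([0.0, 0.0, -1.0])
        pivot = two_body.coords[60:].mean(0)
        rotated = rotate_group(two_body, np.arange(60, 100), e, -6.0, pivot)
        T = RigidTransform(Rotation.from_euler("xyz", [30, 10, -20],
                                               degrees=True).as_matrix(),
                           [5.0, -3.0, 8.0])
        a = ratchet_angle(rotated, two_body, LARGE, SMALL)
        b = ratchet_angle(rotated.transformed(T), two_body.transformed(T),
                          LARGE, SMALL)
        assert a == pytest.approx(b, abs=0.05)


class TestHeadAngle:
    @pytest.fixture()
    def head_system(self):
        rng = np.random.default_rng(30)
        # elongated head along x (the tRNA-travel direction)
        head = rng.uniform(-1, 1, (40, 3)) * [7.0, 3.0, 1.5]
        m = bead_model(head, masses=np.full(40, 14.0))
        m.groups = {"head": np.arange(40)}
        e_tRNA = np.array([1.0, 0.0, 0.0])
        e_ratchet = np.array([0.0, 1.0, 0.0])
        return m, e_tRNA, e_ratchet

    def test_identity_gives_zero(self, head_system):
        m, e_t, e_r = head_system
        sel = SelectionSpec.group("head")
        assert head_angle(m, m, sel, e_t, e_r) == pytest.approx(0.0,
                                                                abs=1e-9)

    def test_in_plane_rotation_recovered(self, head_system):
        m, e_t, e_r = head_system
        sel = SelectionSpec.group("head")
        n = np.cross(e_t, e_r)  # plane normal; clockwise-positive = -n spin
        rotated = rotate_group(m, np.arange(40), n, -10.0,
                               m.coords.mean(0))
        assert head_angle(rotated, m, sel, e_t, e_r) == pytest.approx(
            10.0, abs=0.2)

    def test_out_of_plane_rotation_projects_to_zero(self, head_system):
        # tipping the head axis out of the (e_tRNA, e_ratchet) plane by
        # rotating about the in-plane perpendicular leaves the projected
        # in-plane angle unchanged
        m, e_t, e_r = head_system
        sel = SelectionSpec.group("head")
        rotated = rotate_group(m, np.arange(40), e_r, 10.0,
                               m.coords.mean(0))
        assert abs(head_angle(rotated, m, sel, e_t, e_r)) < 0.5

    def test_antisymmetric_under_swap(self, head_system):
        m, e_t, e_r = head_system
        sel = SelectionSpec.group("head")
        n = np.cross(e_t, e_r)
        rotated = rotate_group(m, np.arange(40), n, -8.0, m.coords.mean(0))
        a = head_angle(rotated, m, sel, e_t, e_r)
        b = head_angle(m, rotated, sel, e_t, e_r)
        assert a == pytest.approx(-b, abs=0.2)


class TestGateWidth:
    def gate_model(self):
        coords = [[0.0, 0, 0], [3.0, 0, 0], [5.0, 0, 0]]
        m = bead_model(coords)
        m.groups = {"A790": np.array([0]), "loop": np.array([1, 2])}
        return m

    def test_arithmetic_example(self):
        m = self.gate_model()
        w = gate_width(m, SelectionSpec.group("A790"),
                       SelectionSpec.group("loop"))
        assert w == pytest.approx(4.0)

    def test_invariant_under_rigid_motion(self):
        m = self.gate_model()
        T = RigidTransform(Rotation.from_euler("zyx", [11, 22, 33],
                                               degrees=True).as_matrix(),
                           [1.0, 2.0, 3.0])
        w1 = gate_width(m, SelectionSpec.group("A790"),
                        SelectionSpec.group("loop"))
        w2 = gate_width(m.transformed(T), SelectionSpec.group("A790"),
                        SelectionSpec.group("loop"))
        assert w1 == pytest.approx(w2, abs=1e-9)

    def test_matches_brute_force_com_distance(self, rng):
        coords = rng.uniform(-5, 5, (10, 3))
        masses = rng.uniform(10, 30, 10)
        m = bead_model(coords, masses)
        m.groups = {"a": np.arange(4), "b": np.arange(4, 10)}
        ca = (masses[:4, None] * coords[:4]).sum(0) / masses[:4].sum()
        cb = (masses[4:, None] * coords[4:]).sum(0) / masses[4:].sum()
        w = gate_width(m, SelectionSpec.group("a"), SelectionSpec.group("b"))
        assert w == pytest.approx(np.linalg.norm(ca - cb), rel=1e-12)

    def test_missing_selection_raises(self):
        m = self.gate_model()
        with pytest.raises(ValueError, match="loop"):
            gate_width(m, SelectionSpec.group("A790"),
                       SelectionSpec.chain("Z"))


class TestScrewDecompose:
    def test_pure_rotation_about_z(self, rng):
        ref = rng.uniform(-5, 5, (30, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        disp = ref @ R.T
        s = screw_decompose(ref, disp)
        assert s.angle == pytest.approx(30.0, abs=1e-9)
        assert s.translation == pytest.approx(0.0, abs=1e-9)
        assert abs(s.axis @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)
        # axis passes through the origin line
        assert np.linalg.norm(s.point[:2] - (s.point[:2] @ np.array([0., 0]))
                              * 0) < 1e-6 or np.linalg.norm(
                                  s.point[:2]) < 1e-6

    def test_pure_translation_branch(self, rng):
        ref = rng.uniform(-5, 5, (30, 3))
        disp = ref + np.array([0.0, 0.0, 4.0])
        s = screw_decompose(ref, disp)
        assert s.angle == 0.0
        assert s.translation == pytest.approx(4.0, abs=1e-12)
        assert np.allclose(s.axis, [0, 0, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_on_random_screws(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(-6, 6, (25, 3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(1.0, 170.0)
        trans = rng.uniform(-5, 5)
        point = rng.uniform(-4, 4, 3)
        screw = ScrewMotion(point=point, axis=axis, angle=angle,
                            translation=trans)
        disp = screw.apply(ref)
        rec = screw_decompose(ref, disp)
        sign = np.sign(rec.axis @ axis)
        assert rec.angle == pytest.approx(angle, abs=1e-6)
        assert sign * rec.translation == pytest.approx(trans, abs=1e-6)
        assert np.allclose(sign * rec.axis, axis, atol=1e-8)
        # recovered axis point lies on the true axis line
        d = rec.point - point
        assert np.linalg.norm(d - (d @ axis) * axis) < 1e-6
        assert rec.residual_rmsd < 1e-9
        assert np.abs(rec.apply(ref) - disp).max() < 1e-6


class TestSplitInternalExternal:
    def make_pair(self, rng):
        a = bead_model(rng.uniform(-5, 5, (40, 3)))
        return a

    def test_rigid_copy_has_no_internal_motion(self, rng):
        a = self.make_pair(rng)
        T = RigidTransform(Rotation.from_euler("y", 25, degrees=True
                                               ).as_matrix(), [2.0, 1.0, 0])
        b = a.transformed(T)
        out = split_internal_external(a, b)
        assert np.abs(out.internal).max() < 1e-9
        assert np.allclose(out.external, out.total, atol=1e-9)

    def test_pure_deformation_has_no_external_motion(self, rng):
        a = self.make_pair(rng)
        b = a.copy()
        # radial breathing: no net rotation or translation component
        c = a.coords.mean(0)
        b.coords = c + 1.1 * (a.coords - c)
        out = split_internal_external(a, b)
        assert np.abs(out.external).max() < 1e-8

    def test_displacement_fields_sum_to_total(self, rng):
        a = self.make_pair(rng)
        b = a.copy()
        b.coords = a.coords + rng.normal(0, 1.0, a.coords.shape)
        out = split_internal_external(a, b)
        assert np.allclose(out.internal + out.external, out.total,
                           atol=1e-12)

    def test_subselection_ratios_reported(self, rng):
        a = self.make_pair(rng)
        a.groups = {"domainIV": np.arange(10)}
        b = a.transformed(RigidTransform(
            Rotation.from_euler("x", 10, degrees=True).as_matrix(),
            [1.0, 0, 0]))
        b.coords[:10] += 0.8  # extra internal motion in one domain
        out = split_internal_external(a, b,
                                      sub_selections={
                                          "domainIV":
                                          SelectionSpec.group("domainIV")})
        assert "domainIV" in out.report
        rep = out.report["domainIV"]
        assert rep["mean_internal"] > out.report["whole"]["mean_internal"]
        assert rep["ratio_internal_external"] > 0
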