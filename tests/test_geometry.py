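"""Ring centers, Watson-Crick face vectors, alignment, (rho, theta)."""

import numpy as np
import pytest

from stackpol import geometry as geo
from stackpol.geometry import MissingRingAtomError
from stackpol.sim import StackSimParams, generate_interface_trajectory, \
    ideal_stacked_step

RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _hexagon(radius=1.0, center=(0.0, 0.0, 0.0)):
    center = np.asarray(center, dtype=float)
    return {
        name: center + radius * np.array(
            [np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0.0])
        for k, name in enumerate(RING)
    }


def _rand_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()


class TestRingCenter:
    def test_regular_hexagon_centers_at_origin(self):
        assert np.allclose(geo.ring_center(_hexagon()), 0.0, atol=1e-12)

    def test_translation_linearity(self, rng):
        atoms = _hexagon()
        v = rng.normal(size=3)
        moved = {k: p + v for k, p in atoms.items()}
        assert np.allclose(geo.ring_center(moved),
                           geo.ring_center(atoms) + v, atol=1e-12)

    def test_matches_generator_analytic_centers(self):
        a5, a3 = ideal_stacked_step("G", "T")
        expect5 = np.mean([a5[n] for n in RING], axis=0)
        assert np.allclose(geo.ring_center(a5, "G"), expect5, atol=1e-9)

    def test_missing_atom_flagged(self):
        atoms = _hexagon()
        del atoms["C4"]
        with pytest.raises(MissingRingAtomError):
            geo.ring_center(atoms)


class TestWcFaceVector:
    def test_lies_in_ring_plane(self):
        v = geo.wc_face_vector(_hexagon(), "A")
        assert abs(v @ np.array([0.0, 0.0, 1.0])) < 1e-9

    def test_rotation_equivariance(self, rng):
        atoms = ideal_stacked_step("C", "G")[0]
        rot = _rand_rotation(rng)
        rotated = {k: rot @ p for k, p in atoms.items()}
        assert np.allclose(geo.wc_face_vector(rotated, "C"),
                           rot @ geo.wc_face_vector(atoms, "C"), atol=1e-9)

    def test_successive_residues_twist_by_helical_angle(self):
        """In an ideal A|A step the projected vectors differ by ~36 deg."""
        a5, a3 = ideal_stacked_step("A", "A")
        theta, degenerate = geo.projected_angle(
            geo.wc_face_vector(a5, "A"), geo.wc_face_vector(a3, "A"))
        assert not degenerate
        assert theta == pytest.approx(36.0, abs=2.0)


class TestAlignFrame:
    def _scene(self, rng, n=12):
        return rng.normal(size=(n, 3))

    def test_identity_on_self(self, rng):
        ref = self._scene(rng)
        out = geo.align_frame(ref, ref, np.arange(6))
        assert np.allclose(out, ref, atol=1e-9)

    def test_exact_recovery_of_rigid_motion(self, rng):
        ref = self._scene(rng)
        rot = _rand_rotation(rng)
        moved = ref @ rot.T + np.array([1.0, -2.0, 0.5])
        out = geo.align_frame(moved, ref, np.arange(6))
        assert np.sqrt(((out[:6] - ref[:6]) ** 2).sum(axis=1).mean()) < 1e-6

    def test_noise_bounded_anchor_rmsd(self, rng):
        ref = self._scene(rng, n=30)
        sigma = 0.01
        noisy = ref + rng.normal(0.0, sigma, size=ref.shape)
        out = geo.align_frame(noisy, ref, np.arange(30))
        rmsd = np.sqrt(((out - ref) ** 2).sum(axis=1).mean())
        assert rmsd <= sigma * np.sqrt(3) * 1.5

    def test_collinear_anchors_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            geo.align_frame(line, line, np.arange(5))


class TestProjectRhoTheta:
    def test_superposed_rings_give_zero_rho(self):
        atoms = _hexagon()
        rho, _, _ = geo.rho_theta_frame(atoms, dict(atoms), "A", "A")
        assert rho == pytest.approx(0.0, abs=1e-12)

    def test_pure_z_translation(self):
        a = _hexagon()
        b = {k: p + np.array([0.0, 0.0, 0.5]) for k, p in a.items()}
        rho, theta, degenerate = geo.rho_theta_frame(b, a, "A", "A")
        assert rho == pytest.approx(0.5, abs=1e-12)
        assert theta == pytest.approx(0.0, abs=1e-9)
        assert not degenerate

    def test_z_translation_plus_rotation(self):
        from scipy.spatial.transform import Rotation

        a = _hexagon()
        rot = Rotation.from_euler("z", 36.0, degrees=True).as_matrix()
        b = {k: rot @ p + np.array([0.0, 0.0, 0.5]) for k, p in a.items()}
        _, theta, _ = geo.rho_theta_frame(b, a, "A", "A")
        assert theta == pytest.approx(36.0, abs=1e-6)

    def test_theta_symmetric_under_residue_swap(self):
        a5, a3 = ideal_stacked_step("G", "C")
        _, t_fwd, _ = geo.rho_theta_frame(a5, a3, "G", "C")
        _, t_rev, _ = geo.rho_theta_frame(a3, a5, "C", "G")
        assert t_fwd == pytest.approx(t_rev, abs=1e-9)

    def test_perpendicular_base_flagged_degenerate(self):
        from scipy.spatial.transform import Rotation

        a = _hexagon()
        # rotate so the face vector points along z: undefined in-plane angle
        b = {}
        vec = geo.wc_face_vector(a, "A")
        align = Rotation.align_vectors([[0, 0, 1.0]], [vec])[0].as_matrix()
        for k, p in a.items():
            b[k] = align @ p
        _, theta, degenerate = geo.rho_theta_frame(b, a, "A", "A")
        assert degenerate and np.isnan(theta)


class TestRigidInvariance:
    def test_series_invariant_under_global_rigid_transform(self):
        """(rho, theta) unchanged to < 1e-6 by any rigid motion of frames."""
        params = StackSimParams(delta_g=-1.5, n_frames=300, seed=9)
        base = generate_interface_trajectory(params)
        reference = base.coords[0]
        plain = geo.project_rho_theta(base, reference=reference)

        rng = np.random.default_rng(4)
        moved = base.coords.copy()
        for i in range(moved.shape[0]):
            rot = _rand_rotation(rng)
            moved[i] = moved[i] @ rot.T + rng.uniform(-2, 2, size=3)
        jittered = generate_interface_trajectory(params)
        jittered.coords = moved
        out = geo.project_rho_theta(jittered, reference=reference)

        assert np.max(np.abs(out.data["rho_nm"] - plain.data["rho_nm"])) \
            < 1e-6
        assert np.max(np.abs(out.data["theta_deg"] - plain.data["theta_deg"])) \
            < 1e-6
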