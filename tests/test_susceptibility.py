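import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lnshift.susceptibility import (
    CGS_MOLAR,
    SI_MOLECULE,
    BleaneyParams,
    ChiTensor,
    convert_chi_units,
    decompose_chi,
    load_chi_series,
    pcs_bleaney,
    pcs_full_tensor,
    pcs_trajectory,
    save_chi_series,
)
from lnshift.trajectory_io import Trajectory

MAGIC_ANGLE = math.degrees(math.acos(1.0 / math.sqrt(3.0)))


def axial_tensor(dchi_ax, units=SI_MOLECULE):
    """Traceless axial tensor with the given Δχ_ax."""
    return ChiTensor(np.diag([-1 / 3, -1 / 3, 2 / 3]) * dchi_ax, units)


def random_sym(rng, scale=1.0):
    a = rng.normal(size=(3, 3)) * scale
    return 0.5 * (a + a.T)


class TestUnits:
    def test_cgs_to_si_per_molecule(self):
        chi = ChiTensor(np.eye(3) * 0.05, CGS_MOLAR)
        out = convert_chi_units(chi, SI_MOLECULE)
        # 0.05 · 4π×10⁻⁶ / 6.02214×10²³
        assert out.matrix[0, 0] == pytest.approx(1.0433e-30, rel=1e-4)

    def test_round_trip_identity(self, rng):
        chi = ChiTensor(random_sym(rng, 0.1), CGS_MOLAR, temperature=250.0)
        back = convert_chi_units(convert_chi_units(chi, SI_MOLECULE), CGS_MOLAR)
        np.testing.assert_allclose(back.matrix, chi.matrix, rtol=1e-12)
        assert back.temperature == 250.0

    def test_zero_tensor(self):
        out = convert_chi_units(ChiTensor(np.zeros((3, 3))), SI_MOLECULE)
        assert not out.matrix.any()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            ChiTensor(np.array([[1.0, 0.5, 0], [0, 1, 0], [0, 0, 1]]))


class TestDecomposition:
    def test_easy_axis_diagonal(self):
        c = 0.02
        dec = decompose_chi(ChiTensor(np.diag([c, c, 2 * c])))
        assert dec.iso == pytest.approx(4 * c / 3)
        assert dec.dchi_ax == pytest.approx(c)
        assert dec.dchi_rh == pytest.approx(0.0, abs=1e-15)
        assert dec.anisotropy_class == "easy-axis"

    def test_easy_plane_diagonal(self):
        c = 0.02
        dec = decompose_chi(ChiTensor(np.diag([2 * c, 2 * c, c])))
        # traceless eigenvalues (c/3, c/3, −2c/3): z is the lone small axis
        assert dec.dchi_ax == pytest.approx(-c)
        assert dec.anisotropy_class == "easy-plane"
        np.testing.assert_allclose(np.abs(dec.axes[:, 2]), [0, 0, 1], atol=1e-12)

    def test_rotation_invariance_of_invariants(self, rng):
        for _ in range(10):
            chi = ChiTensor(random_sym(rng, 0.05))
            dec = decompose_chi(chi)
            rot = Rotation.random(rng=rng).as_matrix()
            dec_r = decompose_chi(ChiTensor(rot @ chi.matrix @ rot.T))
            assert dec_r.iso == pytest.approx(dec.iso, abs=1e-12)
            assert dec_r.dchi_ax == pytest.approx(dec.dchi_ax, rel=1e-9, abs=1e-14)
            assert abs(dec_r.dchi_rh) == pytest.approx(abs(dec.dchi_rh), rel=1e-9, abs=1e-14)
            assert dec_r.anisotropy_class == dec.anisotropy_class

    def test_reconstruction_and_conventions(self, rng):
        for _ in range(10):
            chi = ChiTensor(random_sym(rng, 0.05))
            dec = decompose_chi(chi)
            rebuilt = dec.axes @ np.diag(dec.eigenvalues) @ dec.axes.T
            np.testing.assert_allclose(rebuilt, chi.matrix, atol=1e-12)
            assert abs(dec.dchi_rh) <= (2 / 3) * abs(dec.dchi_ax) + 1e-12
            assert np.linalg.det(dec.axes) == pytest.approx(1.0, abs=1e-9)


class TestFullTensorPCS:
    def test_on_axis_closed_form(self):
        delta = pcs_full_tensor(axial_tensor(1e-32), (0, 0, 0), (0, 0, 4.0))
        assert delta == pytest.approx(8.29, abs=0.005)  # Δχ/(6πr³)·10⁶

    def test_magic_angle_null(self):
        th = math.radians(MAGIC_ANGLE)
        for r in (3.0, 5.0, 8.0):
            for phi in (0.0, 1.0, 2.5):
                pos = r * np.array(
                    [math.sin(th) * math.cos(phi), math.sin(th) * math.sin(phi), math.cos(th)]
                )
                assert abs(pcs_full_tensor(axial_tensor(1e-32), (0, 0, 0), pos)) < 1e-10

    def test_coordinate_free_equals_pas_form(self, rng):
        """Dual-formula oracle: rᵀχ̃r/(4πr⁵) against the Δχ_ax/Δχ_rh PAS form."""
        for _ in range(50):
            chi = ChiTensor(random_sym(rng, 1e-32), SI_MOLECULE)
            pos = rng.normal(size=3) * 5
            if np.linalg.norm(pos) < 1.0:
                continue
            dec = decompose_chi(chi)
            x, y, z = dec.axes.T @ (pos * 1e-10)
            r = np.linalg.norm(pos) * 1e-10
            pas = (
                1e6
                / (12 * math.pi * r**5)
                * (dec.dchi_ax * (3 * z**2 - r**2) + 1.5 * dec.dchi_rh * (x**2 - y**2))
            )
            got = pcs_full_tensor(chi, (0, 0, 0), pos)
            assert got == pytest.approx(pas, rel=1e-10, abs=1e-12)

    def test_linearity_and_iso_null(self, rng):
        pos = np.array([2.0, -3.0, 1.5])
        a = ChiTensor(random_sym(rng, 1e-32), SI_MOLECULE)
        b = ChiTensor(random_sym(rng, 1e-32), SI_MOLECULE)
        s = ChiTensor(a.matrix + 2 * b.matrix, SI_MOLECULE)
        da, db, ds = (pcs_full_tensor(c, (0, 0, 0), pos) for c in (a, b, s))
        assert ds == pytest.approx(da + 2 * db, rel=1e-9)
        assert pcs_full_tensor(ChiTensor(np.eye(3) * 3e-32, SI_MOLECULE), (0, 0, 0), pos) == pytest.approx(0.0, abs=1e-12)

    def test_sphere_average_null(self, rng):
        """⟨δ_pc⟩ over uniformly random orientations vanishes within MC error."""
        chi = ChiTensor(random_sym(rng, 1e-32), SI_MOLECULE)
        n = 20000
        v = rng.normal(size=(n, 3))
        v = 4.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        shifts = np.array([pcs_full_tensor(chi, (0, 0, 0), p) for p in v])
        assert abs(shifts.mean()) < 3.0 * shifts.std() / math.sqrt(n)

    def test_joint_rotation_invariance(self, rng):
        chi = ChiTensor(random_sym(rng, 1e-32), SI_MOLECULE)
        pos = np.array([1.0, 2.0, 3.0])
        ref = pcs_full_tensor(chi, (0, 0, 0), pos)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            got = pcs_full_tensor(
                ChiTensor(rot @ chi.matrix @ rot.T, SI_MOLECULE), (0, 0, 0), rot @ pos
            )
            assert got == pytest.approx(ref, rel=1e-10)

    def test_too_close_nucleus_rejected(self):
        with pytest.raises(ValueError):
            pcs_full_tensor(axial_tensor(1e-32), (0, 0, 0), (0.1, 0, 0))


class TestBleaney:
    def test_axial_vs_equatorial_ratio(self):
        p = BleaneyParams(b20=-1.0)
        assert pcs_bleaney(p, 0.0, 4.0) / pcs_bleaney(p, 90.0, 4.0) == pytest.approx(-2.0)

    def test_magic_angle_null(self):
        assert pcs_bleaney(BleaneyParams(b20=-1.0), MAGIC_ANGLE, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_cube_scaling(self):
        p = BleaneyParams(b20=2.0)
        assert pcs_bleaney(p, 30.0, 8.0) == pytest.approx(pcs_bleaney(p, 30.0, 4.0) / 8.0)

    def test_axial_profile_matches_full_tensor(self):
        """Axial full-tensor PCS follows the same (3cos²θ−1)/r³ profile."""
        p = BleaneyParams(b20=-1.0)
        thetas = np.linspace(5, 175, 25)
        bleaney = np.array([pcs_bleaney(p, t, 4.0) for t in thetas])
        chi = axial_tensor(1e-32)
        full = np.array(
            [
                pcs_full_tensor(
                    chi, (0, 0, 0), 4.0 * np.array([math.sin(math.radians(t)), 0, math.cos(math.radians(t))])
                )
                for t in thetas
            ]
        )
        r = np.corrcoef(bleaney, full)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            pcs_bleaney(BleaneyParams(b20=1.0), 10.0, 0.0)


class TestTrajectoryShifts:
    def test_c3_symmetric_frame_gives_equal_triplet_members(self, template):
        frame, donors = template
        traj = Trajectory([frame])
        chi = ChiTensor(np.diag([0.04, 0.04, 0.07]))  # axial along the C3 axis
        shifts = pcs_trajectory(traj, [chi], donors)
        for name in ("H1", "H2", "H3"):
            members = shifts.per_atom[[f"{name}_{s}" for s in "abc"]].iloc[0]
            assert members.max() - members.min() < 1e-10
            assert shifts.triplet[name].iloc[0] == pytest.approx(members.iloc[0])

    def test_triplet_average_is_member_mean(self, template, rng):
        frame, donors = template
        frames = 3
        traj = Trajectory(
            [
                type(frame)(i, frame.elements, frame.coords + rng.normal(scale=0.05, size=frame.coords.shape), float(i))
                for i in range(frames)
            ]
        )
        chis = [ChiTensor(random_sym(rng, 0.02) + np.eye(3) * 0.05) for _ in range(frames)]
        shifts = pcs_trajectory(traj, chis, donors)
        for name in ("H1", "H2", "H3"):
            manual = shifts.per_atom[[f"{name}_{s}" for s in "abc"]].mean(axis=1)
            np.testing.assert_allclose(shifts.triplet[name], manual, rtol=1e-12)
            assert shifts.time_average[name] == pytest.approx(shifts.triplet[name].mean())

    def test_constant_trajectory_time_average(self, template):
        frame, donors = template
        traj = Trajectory([type(frame)(i, frame.elements, frame.coords.copy(), float(i)) for i in range(5)])
        chi = ChiTensor(np.diag([0.03, 0.05, 0.07]))
        shifts = pcs_trajectory(traj, [chi] * 5, donors)
        single = pcs_trajectory(Trajectory([frame]), [chi], donors)
        for name in ("H1", "H2", "H3"):
            assert shifts.time_average[name] == pytest.approx(single.triplet[name].iloc[0])

    def test_length_mismatch_rejected(self, template):
        frame, donors = template
        with pytest.raises(ValueError):
            pcs_trajectory(Trajectory([frame]), [], donors)


def test_chi_series_json_round_trip(tmp_path, rng):
    series = [ChiTensor(random_sym(rng, 0.03) + np.eye(3) * 0.05, CGS_MOLAR, 298.0) for _ in range(3)]
    p = tmp_path / "chi.json"
    save_chi_series(series, p)
    back = load_chi_series(p)
    assert len(back) == 3
    for a, b in zip(series, back):
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-15)
        assert b.units == CGS_MOLAR
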