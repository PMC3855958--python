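import numpy as np
import pytest

from myomech.constitutive import MaterialParams, reference_pressure
from myomech.errors import (
    ConfigError,
    InvalidKinematicsError,
    NonlinearDivergenceError,
)
from myomech.mechanics3d import (
    BoundaryProtocol,
    assemble_system,
    build_cube_mesh,
    dirichlet_map,
    end_face_nominal_stress,
    gauss_point_kinematics,
    newton_solve,
    uniaxial_oracle,
)

MP = MaterialParams()


@pytest.fixture()
def mesh1():
    return build_cube_mesh(1, 1, 1, 2.0)


def solve_stretch(mesh, lam, mp=MP, steps=4):
    """Ramp the axial end face to stretch lam and solve quasi-statically."""
    u, p = mesh.zero_fields()
    p[:] = reference_pressure(mp)
    Lx = mesh.dims[0]
    for s in range(1, steps + 1):
        d = (lam - 1.0) * Lx * s / steps
        u, p = newton_solve(mesh, u, p, mp, dirichlet_map(mesh, d))
    return u, p


class TestMeshConstruction:
    def test_counts_8_elements(self):
        m = build_cube_mesh(2, 2, 2, 2.0)
        assert m.n_elements == 8
        assert m.n_geom_nodes == 125
        assert m.n_pnodes == 27

    def test_counts_1_element(self, mesh1):
        assert mesh1.n_elements == 1
        assert mesh1.n_geom_nodes == 27
        assert mesh1.n_pnodes == 8

    def test_reference_volume(self, mesh1):
        assert mesh1.reference_volume() == pytest.approx(8.0, rel=1e-12)
        m = build_cube_mesh(2, 1, 1, (3.0, 1.0, 2.0))
        assert m.reference_volume() == pytest.approx(6.0, rel=1e-12)

    def test_27_gauss_points(self, mesh1):
        assert mesh1.gp_xi.shape == (27, 3)
        assert mesh1.gp_w.sum() == pytest.approx(8.0)

    def test_fiber_direction_unit(self):
        m = build_cube_mesh(1, 1, 1, 2.0, fiber_dir=(2.0, 0, 0))
        assert np.allclose(m.a0, [[1.0, 0, 0]])

    def test_validation(self):
        with pytest.raises(ConfigError):
            build_cube_mesh(0, 1, 1, 2.0)
        with pytest.raises(ConfigError):
            build_cube_mesh(1, 1, 1, -1.0)


class TestAssembly:
    def test_stress_free_reference(self, mesh1):
        u, p = mesh1.zero_fields()
        p[:] = reference_pressure(MP)
        R, _ = assemble_system(mesh1, u, p, MP, want_tangent=False)
        assert np.linalg.norm(R) < 1e-10

    def test_tangent_matches_finite_difference(self, mesh1):
        rng = np.random.default_rng(1)
        u, p = mesh1.zero_fields()
        u += 0.01 * rng.standard_normal(u.shape)
        p[:] = reference_pressure(MP) + 0.1 * rng.standard_normal(p.shape)
        R, K = assemble_system(mesh1, u, p, MP)
        d = 1e-7 * rng.standard_normal(mesh1.n_dofs)
        ng = mesh1.n_geom_nodes
        R2, _ = assemble_system(mesh1, u + d[:3 * ng].reshape(-1, 3),
                                p + d[3 * ng:], MP, want_tangent=False)
        lin = K @ d
        assert np.linalg.norm(R2 - R - lin) < 1e-5 * np.linalg.norm(lin)

    def test_translation_invariance(self, mesh1):
        rng = np.random.default_rng(2)
        u, p = mesh1.zero_fields()
        u += 0.01 * rng.standard_normal(u.shape)
        p[:] = reference_pressure(MP)
        R1, _ = assemble_system(mesh1, u, p, MP, want_tangent=False)
        R2, _ = assemble_system(mesh1, u + np.array([0.3, -0.1, 0.7]), p, MP,
                                want_tangent=False)
        assert np.allclose(R1, R2, atol=1e-9)

    def test_element_inversion_detected(self, mesh1):
        u, p = mesh1.zero_fields()
        u[:, 0] = -1.1 * mesh1.X[:, 0]  # fold the element through itself
        with pytest.raises(InvalidKinematicsError):
            assemble_system(mesh1, u, p, MP, want_tangent=False)


class TestNewton:
    def test_zero_motion_zero_solution(self, mesh1):
        u, p = mesh1.zero_fields()
        u, p = newton_solve(mesh1, u, p, MP, dirichlet_map(mesh1, 0.0))
        assert np.allclose(u, 0.0, atol=1e-10)
        assert np.allclose(p, reference_pressure(MP), atol=1e-8)

    def test_20pct_stretch_homogeneous(self, mesh1):
        u, p = solve_stretch(mesh1, 1.2)
        kin = gauss_point_kinematics(mesh1, u)
        lam = kin["lambda_f"]
        assert lam.shape == (1, 27)
        assert np.allclose(lam, 1.2, atol=1e-9)
        assert np.abs(kin["J"] - 1.0).max() < 1e-6

    @pytest.mark.parametrize("lam", [1.1, 1.2])
    def test_stress_matches_oracle(self, mesh1, lam):
        u, p = solve_stretch(mesh1, lam)
        fe = end_face_nominal_stress(mesh1, u, p, MP)
        assert fe == pytest.approx(uniaxial_oracle(lam, 0.0, 0.0, MP),
                                   rel=1e-4)

    def test_passive_sweep_oracle_1el(self, mesh1):
        for lam in (0.9, 1.0, 1.1, 1.2, 1.3):
            u, p = solve_stretch(mesh1, lam)
            fe = end_face_nominal_stress(mesh1, u, p, MP)
            assert fe == pytest.approx(uniaxial_oracle(lam, 0.0, 0.0, MP),
                                       rel=1e-4, abs=1e-10)

    def test_8_element_agrees_with_1_element(self):
        m8 = build_cube_mesh(2, 2, 2, 2.0)
        u, p = solve_stretch(m8, 1.2)
        kin = gauss_point_kinematics(m8, u)
        assert kin["lambda_f"].size == 216
        assert np.allclose(kin["lambda_f"], 1.2, atol=1e-8)
        fe = end_face_nominal_stress(m8, u, p, MP)
        assert fe == pytest.approx(uniaxial_oracle(1.2, 0.0, 0.0, MP),
                                   rel=1e-4)

    def test_active_stress_adds_pmax_at_optimum(self, mesh1):
        u, p = solve_stretch(mesh1, 1.2)
        mesh1.gamma_bar[:] = 1.0
        u, p = newton_solve(mesh1, u, p, MP,
                            dirichlet_map(mesh1, 0.2 * 2.0))
        fe = end_face_nominal_stress(mesh1, u, p, MP)
        passive = uniaxial_oracle(1.2, 0.0, 0.0, MP)
        assert fe == pytest.approx(passive + 73.0, rel=1e-4)
        mesh1.gamma_bar[:] = 0.0

    def test_divergence_reported(self, mesh1):
        u, p = mesh1.zero_fields()
        with pytest.raises(NonlinearDivergenceError):
            # one giant unramped step with a tiny iteration budget
            newton_solve(mesh1, u, p, MP, dirichlet_map(mesh1, 1.2),
                         max_iter=2)


class TestKinematics:
    def test_zero_displacement_identity(self, mesh1):
        u, _ = mesh1.zero_fields()
        kin = gauss_point_kinematics(mesh1, u)
        assert np.allclose(kin["F"], np.eye(3))
        assert np.allclose(kin["lambda_f"], 1.0)

    def test_affine_field_reproduced_exactly(self, mesh1):
        A = np.array([[1.1, 0.02, 0.0], [0.01, 0.95, 0.03], [0.0, 0.0, 1.02]])
        u = mesh1.X @ (A - np.eye(3)).T
        kin = gauss_point_kinematics(mesh1, u)
        assert np.allclose(kin["F"], A, atol=1e-12)


class TestObjectivity:
    def test_rotated_problem_same_invariants(self):
        """Fully prescribed homogeneous end faces, original vs rotated frame."""
        lam = 1.15
        lat = lam ** -0.5
        Fh = np.diag([lam, lat, lat])
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1

        def solve(rot):
            m = build_cube_mesh(1, 1, 1, 2.0)
            m.X = m.X @ rot.T
            m.a0 = m.a0 @ rot.T
            m = type(m)(X=m.X, conn=m.conn, pconn=m.pconn,
                        n_pnodes=m.n_pnodes, a0=m.a0, dims=m.dims,
                        shape=m.shape)
            Fr = rot @ Fh @ rot.T
            tolg = 1e-9
            bc = {}
            Xb = m.X @ rot  # back-rotated coords to find the end faces
            for n in range(m.n_geom_nodes):
                if abs(Xb[n, 0]) < tolg or abs(Xb[n, 0] - 2.0) < tolg:
                    target = (Fr - np.eye(3)) @ m.X[n]
                    for i in range(3):
                        bc[3 * n + i] = target[i]
            u, p = m.zero_fields()
            p[:] = reference_pressure(MP)
            u, p = newton_solve(m, u, p, MP, bc)
            return m, u, p

        m1, u1, p1 = solve(np.eye(3))
        m2, u2, p2 = solve(Q)
        k1 = gauss_point_kinematics(m1, u1)
        k2 = gauss_point_kinematics(m2, u2)
        assert np.allclose(k1["lambda_f"], k2["lambda_f"], atol=1e-8)
        ev1 = np.sort(np.linalg.eigvalsh(k1["C"]), axis=-1)
        ev2 = np.sort(np.linalg.eigvalsh(k2["C"]), axis=-1)
        assert np.allclose(ev1, ev2, atol=1e-8)
        # pressure fields agree (scalar, frame-indifferent)
        assert np.allclose(np.sort(p1), np.sort(p2), atol=1e-6)


class TestUniaxialOracle:
    def test_reference_zero(self):
        assert uniaxial_oracle(1.0, 0.0, 0.0, MP) == pytest.approx(0.0)

    def test_lambda_1p1_passive(self):
        # frozen symbolic value: c10, c01 and fiber-term contributions
        assert uniaxial_oracle(1.1, 0.0, 0.0, MP) == pytest.approx(
            1.805501288999, rel=1e-10)

    def test_active_at_optimum(self):
        passive = uniaxial_oracle(1.2, 0.0, 0.0, MP)
        total = uniaxial_oracle(1.2, 1.0, 0.0, MP)
        assert total - passive == pytest.approx(73.0)

    def test_sympy_cross_validation(self):
        sympy = pytest.importorskip("sympy")
        lam_s = sympy.symbols("lam", positive=True)
        I1 = lam_s ** 2 + 2 / lam_s
        I2 = 2 * lam_s + lam_s ** -2
        W = (MP.c10 * (I1 - 3) + MP.c01 * (I2 - 3)
             + MP.b1 / MP.d1 * (lam_s ** MP.d1 - 1)
             - MP.b1 * sympy.log(lam_s))
        dW = sympy.diff(W, lam_s)
        for lam in (1.05, 1.1, 1.25, 1.3):
            expect = float(dW.subs(lam_s, lam))
            assert uniaxial_oracle(lam, 0.0, 0.0, MP) == pytest.approx(
                expect, rel=1e-10)


class TestBoundaryProtocol:
    def test_isometric_hold(self):
        bp = BoundaryProtocol(prestretch=0.2, mode="isometric_hold")
        assert bp.end_displacement(0.0, 2.0, 0.02) == pytest.approx(0.4)
        assert bp.end_displacement(50.0, 2.0, 0.02) == pytest.approx(0.4)

    def test_constant_velocity(self):
        bp = BoundaryProtocol(prestretch=0.2,
                              mode="constant_velocity_shortening",
                              speed_fraction=0.1)
        # end face moves inward at 0.1 * vmax
        assert bp.end_displacement(10.0, 2.0, 0.02) == pytest.approx(
            0.4 - 0.1 * 0.02 * 10.0)

    def test_validation(self):
        with pytest.raises(ConfigError):
            BoundaryProtocol(speed_fraction=1.5)
        with pytest.raises(ConfigError):
            BoundaryProtocol(prestretch=-1.5)
        with pytest.raises(ConfigError):
            BoundaryProtocol(mode="wiggle")
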