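import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myomech.constitutive import (
    Kinematics,
    MaterialParams,
    cauchy_from_pk2,
    force_length,
    gamma_scale,
    invariants_of_C,
    pk2_active,
    pk2_ani,
    pk2_iso,
    pk2_total,
    reference_pressure,
    strain_energy,
    velocity_factor,
)
from myomech.errors import ConfigError, InvalidKinematicsError

MP = MaterialParams()
EX = np.array([1.0, 0.0, 0.0])


def random_spd(rng, lam_lo=0.8, lam_hi=1.4):
    """Random SPD C with controlled eigenvalue range (J not necessarily 1)."""
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    ev = rng.uniform(lam_lo, lam_hi, 3) ** 2
    return Q @ np.diag(ev) @ Q.T


class TestMaterialParams:
    def test_defaults_table_values(self):
        assert MP.c10 == pytest.approx(6.352e-10)
        assert MP.c01 == pytest.approx(3.627)
        assert MP.b1 == pytest.approx(2.756e-5)
        assert MP.d1 == pytest.approx(43.373)
        assert MP.Pmax == pytest.approx(73.0)

    @pytest.mark.parametrize("bad", [
        {"c10": -1.0}, {"c01": 0.0}, {"d1": 1.5}, {"Am": -5.0},
        {"a_rel": 0.0}, {"Cm_fast": -1.0},
    ])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ConfigError):
            MaterialParams(**bad)

    def test_capacitance_by_fiber_type(self):
        assert MP.Cm("slow") == pytest.approx(0.58)
        assert MP.Cm("fast") == pytest.approx(1.0)
        with pytest.raises(ConfigError):
            MP.Cm("medium")


class TestInvariants:
    def test_identity(self):
        assert invariants_of_C(np.eye(3), EX) == pytest.approx((3, 3, 1, 1, 1))

    def test_uniaxial_diag(self):
        C = np.diag([1.44, 1 / 1.2, 1 / 1.2])
        I1, I2, I3, I4, I5 = invariants_of_C(C, EX)
        assert I3 == pytest.approx(1.0)
        assert I4 == pytest.approx(1.44)
        assert I5 == pytest.approx(2.0736)

    def test_against_minor_expansion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            C = random_spd(rng)
            a0 = rng.standard_normal(3)
            a0 /= np.linalg.norm(a0)
            I1, I2, I3, I4, I5 = invariants_of_C(C, a0)
            # brute-force cofactor expansion for det
            det = (C[0, 0] * (C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1])
                   - C[0, 1] * (C[1, 0] * C[2, 2] - C[1, 2] * C[2, 0])
                   + C[0, 2] * (C[1, 0] * C[2, 1] - C[1, 1] * C[2, 0]))
            # sum of 2x2 principal minors
            minors = sum(
                C[i, i] * C[j, j] - C[i, j] * C[j, i]
                for i in range(3) for j in range(i + 1, 3))
            assert I3 == pytest.approx(det, rel=1e-12)
            assert I2 == pytest.approx(minors, rel=1e-12)
            assert I4 == pytest.approx(a0 @ C @ a0, rel=1e-12)

    def test_non_spd_rejected(self):
        with pytest.raises(InvalidKinematicsError):
            invariants_of_C(-np.eye(3), EX)
        with pytest.raises(InvalidKinematicsError):
            invariants_of_C(np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]]), EX)

    def test_non_unit_direction_strict(self):
        with pytest.raises(InvalidKinematicsError):
            invariants_of_C(np.eye(3), 2 * EX, strict=True)
        with pytest.warns(UserWarning):
            invariants_of_C(np.eye(3), 2 * EX)


def uniaxial_kin(lam):
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    return Kinematics(F=F, a0=EX)


class TestStrainEnergy:
    def test_reference_zero(self):
        assert strain_energy(uniaxial_kin(1.0), MP) == pytest.approx(0.0)

    def test_compression_has_no_aniso_term(self):
        kin = uniaxial_kin(0.9)
        W = strain_energy(kin, MP)
        W_iso = MP.c10 * (kin.I1 - 3) + MP.c01 * (kin.I2 - 3)
        assert W == pytest.approx(W_iso, rel=1e-14)

    def test_uniaxial_1p1_symbolic_oracle(self):
        # frozen from sympy: c10(I1-3)+c01(I2-3)+b1/d1(l^d1-1)-b1 ln(l)
        assert strain_energy(uniaxial_kin(1.1), MP) == pytest.approx(
            0.0959570619280585, rel=1e-12)


class TestPassiveStress:
    def test_pk2_iso_identity(self):
        S = pk2_iso(np.eye(3), MP)
        assert np.allclose(S, (2 * MP.c10 + 4 * MP.c01) * np.eye(3))
        assert S[0, 0] == pytest.approx(14.508, rel=1e-4)

    def test_pk2_ani_zero_at_unity_and_compression(self):
        assert np.allclose(pk2_ani(1.0, EX, MP), 0.0)
        assert np.allclose(pk2_ani(0.8, EX, MP), 0.0)

    def test_pk2_ani_coefficient_1p1(self):
        S = pk2_ani(1.1, EX, MP)
        assert S[0, 0] == pytest.approx(1.3989585e-3, rel=1e-6)
        assert np.allclose(S[1:, :], 0.0)


class TestForceLength:
    def test_vertex(self):
        assert force_length(1.2, 1.2) == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [0.6, 1.4])
    def test_support_endpoints(self, r):
        assert force_length(r * 1.2, 1.2) == pytest.approx(0.0, abs=1e-12)

    def test_r_1p1(self):
        assert force_length(1.32, 1.2) == pytest.approx(0.9375)

    def test_outside_support_zero(self):
        assert force_length(0.5, 1.2) == 0.0
        assert force_length(2.0, 1.2) == 0.0

    @given(st.floats(0.01, 3.0))
    def test_bounded_and_continuous(self, lam):
        v = force_length(lam, 1.2)
        assert 0.0 <= v <= 1.0
        eps = 1e-9
        assert abs(force_length(lam + eps, 1.2) - v) < 1e-6


class TestVelocityFactor:
    def test_isometric_limit(self):
        assert velocity_factor(0.0, MP) == pytest.approx(MP.Fiso)

    def test_zero_crossing_at_u1_when_arel_eq_brel(self):
        assert velocity_factor(1.0, MP) == pytest.approx(0.0, abs=1e-14)

    def test_u_0p1(self):
        assert velocity_factor(0.1, MP) == pytest.approx(0.642857142857, rel=1e-10)

    def test_strictly_decreasing(self):
        u = np.linspace(0, 1, 101)
        v = velocity_factor(u, MP)
        assert np.all(np.diff(v) < 0)

    def test_lengthening_clamped(self):
        assert velocity_factor(-0.5, MP) == pytest.approx(MP.Fiso)


class TestGammaScale:
    def test_zero_a2(self):
        assert gamma_scale(0.0, 0.3, MP) == 0.0

    def test_isometric_full(self):
        assert gamma_scale(1.0, 0.0, MP) == pytest.approx(1.0)

    def test_half_a2_u_0p1(self):
        assert gamma_scale(0.5, 0.1, MP) == pytest.approx(0.321428571429, rel=1e-10)

    def test_overshoot_clamped(self):
        assert gamma_scale(1.0005, 0.0, MP) == pytest.approx(1.0)


class TestActiveStress:
    def test_zero_gamma(self):
        assert np.allclose(pk2_active(1.2, 0.0, EX, MP), 0.0)

    def test_nominal_pmax_at_optimum(self):
        S = pk2_active(1.2, 1.0, EX, MP)
        # nominal P_act = lambda_f * S_ff = Pmax
        assert 1.2 * S[0, 0] == pytest.approx(73.0)

    def test_outside_support(self):
        assert np.allclose(pk2_active(1.2 * 1.4, 5.0, EX, MP), 0.0)


class TestTotalStress:
    def test_stress_free_reference(self):
        kin = uniaxial_kin(1.0)
        S = pk2_total(kin, reference_pressure(MP), 0.0, 0.0, MP)
        assert np.allclose(S, 0.0, atol=1e-12)

    def test_cauchy_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            kin = Kinematics(F=F, a0=EX)
            S = pk2_total(kin, 5.0, 0.4, 0.0, MP)
            T = cauchy_from_pk2(S, F)
            assert np.allclose(T, T.T, atol=1e-10 * max(1, abs(T).max()))

    def test_finite_difference_of_energy(self):
        """S_iso + S_ani == 2 dW/dC - p C^-1 by central differences."""
        rng = np.random.default_rng(7)
        a0 = EX
        for _ in range(20):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.3:
                continue
            kin = Kinematics(F=F, a0=a0)
            if not (1.0 + 1e-3 < kin.lambda_f < 1.4):
                continue
            S = pk2_iso(kin.C, MP) + pk2_ani(kin.lambda_f, a0, MP)
            h = 1e-6

            def W_of_C(C):
                I1 = np.trace(C)
                I2 = 0.5 * (I1 ** 2 - np.trace(C @ C))
                lam = np.sqrt(a0 @ C @ a0)
                W = MP.c10 * (I1 - 3) + MP.c01 * (I2 - 3)
                if lam > 1:
                    W += MP.b1 / MP.d1 * (lam ** MP.d1 - 1) - MP.b1 * np.log(lam)
                return W

            S_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    dC = np.zeros((3, 3))
                    dC[i, j] += 0.5 * h
                    dC[j, i] += 0.5 * h  # symmetric perturbation
                    S_fd[i, j] = (W_of_C(kin.C + dC)
                                  - W_of_C(kin.C - dC)) / (2 * h)
            S_fd *= 2.0  # S = 2 dW/dC
            assert np.allclose(S, S_fd, rtol=2e-5, atol=1e-8)


class TestFrameIndifference:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_invariants_under_rotation(self, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.2:
            return
        A = rng.standard_normal((3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        a0 = rng.standard_normal(3)
        a0 /= np.linalg.norm(a0)
        k1 = Kinematics(F=F, a0=a0)
        k2 = Kinematics(F=Q @ F, a0=a0)
        for name in ("I1", "I2", "I3", "I4", "I5", "lambda_f", "J"):
            assert getattr(k1, name) == pytest.approx(getattr(k2, name),
                                                      rel=1e-9)
        S1 = pk2_total(k1, 3.0, 0.5, 0.0, MP)
        S2 = pk2_total(k2, 3.0, 0.5, 0.0, MP)
        assert np.allclose(S1, S2, atol=1e-9 * max(1, abs(S1).max()))


def test_small_strain_anisotropy_negligible():
    """At lambda_f = 1.05 the fiber-term nominal stress is <1% of isotropic."""
    lam = 1.05
    P_ani = MP.b1 * (lam ** (MP.d1 - 1) - 1 / lam)
    P_iso = MP.c10 * (2 * lam - 2 * lam ** -2) + MP.c01 * (2 - 2 * lam ** -3)
    assert P_ani < 0.01 * P_iso
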