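"""Transversely isotropic, incompressible muscle constitutive model.

Passive behavior: Mooney-Rivlin ground matrix plus a polynomial fiber-stretch
term that is active only in tension.  Active behavior: a nominal active stress
``P_act = Pmax * f_len(lambda_f) * gamma_bar`` acting along the fiber
direction, where ``gamma_bar`` combines the normalized post-power-stroke
crossbridge concentration with a hyperbolic force-velocity factor.

Unit system used throughout the package: cm / ms / mV / kPa / uA/cm^2 /
uF/cm^2 / mS/cm.  With these units 7.3 N/cm^2 is stored as 73 kPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import ConfigError, InvalidKinematicsError

__all__ = [
    "MaterialParams",
    "Kinematics",
    "invariants_of_C",
    "strain_energy",
    "pk2_iso",
    "pk2_ani",
    "force_length",
    "velocity_factor",
    "gamma_scale",
    "pk2_active",
    "pk2_total",
    "cauchy_from_pk2",
    "reference_pressure",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class MaterialParams:
    """All constitutive, Hill, and membrane constants in one validated record.

    Defaults are the shipped passive parameter set (fitted Mooney-Rivlin +
    one-term fiber polynomial) together with the standard active/membrane
    constants.  Stresses in kPa, conductivity in mS/cm, capacitance in
    uF/cm^2, velocities in cm/ms.
    """

    c10: float = 6.352e-10      # kPa
    c01: float = 3.627          # kPa
    b1: float = 2.756e-5        # kPa
    d1: float = 43.373          # dimensionless exponent
    Pmax: float = 73.0          # kPa  (== 7.3 N/cm^2)
    lambda_opt: float = 1.2     # optimal fiber stretch
    a_rel: float = 0.25         # a / F_iso
    b_rel: float = 0.25         # b / lambda_dot_max
    vmax: float = 0.02          # cm/ms (== 200 mm/s) max shortening velocity
    sigma: float = 3.8          # mS/cm effective fiber conductivity
    Am: float = 500.0           # 1/cm surface-to-volume ratio
    Cm_slow: float = 0.58       # uF/cm^2
    Cm_fast: float = 1.0        # uF/cm^2
    Fiso: float = 1.0           # dimensionless isometric force scale

    def __post_init__(self) -> None:
        positive = (
            "c10", "c01", "b1", "Pmax", "lambda_opt", "a_rel", "b_rel",
            "vmax", "sigma", "Am", "Cm_slow", "Cm_fast", "Fiso",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"MaterialParams.{name} must be > 0, "
                                  f"got {getattr(self, name)!r}")
        if not self.d1 > 2:
            raise ConfigError(
                f"MaterialParams.d1 must exceed 2 so the anisotropic stress "
                f"vanishes at lambda_f = 1; got {self.d1!r}")

    def Cm(self, fiber_type: str) -> float:
        """Membrane capacitance for a fiber type ('slow' or 'fast')."""
        if fiber_type == "slow":
            return self.Cm_slow
        if fiber_type == "fast":
            return self.Cm_fast
        raise ConfigError(f"unknown fiber type {fiber_type!r}")

    def replace(self, **kw) -> "MaterialParams":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kw)
        return MaterialParams(**current)


def _check_spd(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3):
        raise InvalidKinematicsError(f"C must be 3x3, got shape {C.shape}")
    if not np.allclose(C, C.T, rtol=0, atol=1e-10 * max(1.0, abs(C).max())):
        raise InvalidKinematicsError("C is not symmetric")
    # cheap SPD test via Cholesky
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise InvalidKinematicsError("C is not positive definite") from exc
    return C


def _unit(a0: np.ndarray, strict: bool) -> np.ndarray:
    a0 = np.asarray(a0, dtype=float).reshape(3)
    norm = float(np.linalg.norm(a0))
    if norm == 0.0:
        raise InvalidKinematicsError("fiber direction is the zero vector")
    if abs(norm - 1.0) > 1e-8:
        if strict:
            raise InvalidKinematicsError(
                f"fiber direction not unit length (|a0| = {norm:.6g})")
        warnings.warn("normalizing non-unit fiber direction", stacklevel=3)
        a0 = a0 / norm
    return a0


def invariants_of_C(C: np.ndarray, a0: np.ndarray, *, strict: bool = False):
    """Principal and mixed invariants (I1..I5) of C for fiber direction a0.

    I1 = tr C, I2 = ((tr C)^2 - tr C^2)/2, I3 = det C, I4 = a0.C.a0,
    I5 = a0.C^2.a0.
    """
    C = _check_spd(C)
    a0 = _unit(a0, strict)
    trC = float(np.trace(C))
    I1 = trC
    I2 = 0.5 * (trC * trC - float(np.trace(C @ C)))
    I3 = float(np.linalg.det(C))
    I4 = float(a0 @ C @ a0)
    I5 = float(a0 @ (C @ C) @ a0)
    return I1, I2, I3, I4, I5


@dataclass(frozen=True)
class Kinematics:
    """Per-evaluation-point deformation state derived from F and a0."""

    F: np.ndarray
    a0: np.ndarray
    C: np.ndarray = field(init=False)
    E: np.ndarray = field(init=False)
    J: float = field(init=False)
    lambda_f: float = field(init=False)
    I1: float = field(init=False)
    I2: float = field(init=False)
    I3: float = field(init=False)
    I4: float = field(init=False)
    I5: float = field(init=False)

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise InvalidKinematicsError(f"F must be 3x3, got {F.shape}")
        J = float(np.linalg.det(F))
        if J <= 0:
            raise InvalidKinematicsError(f"det F = {J:.6g} <= 0")
        a0 = _unit(self.a0, strict=False)
        C = F.T @ F
        I1, I2, I3, I4, I5 = invariants_of_C(C, a0)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "a0", a0)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "E", 0.5 * (C - _I3))
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "lambda_f", float(np.sqrt(I4)))
        for name, val in zip(("I1", "I2", "I3", "I4", "I5"),
                             (I1, I2, I3, I4, I5)):
            object.__setattr__(self, name, val)


def strain_energy(kin: Kinematics, mp: MaterialParams,
                  gamma_bar: float = 0.0) -> float:
    """Passive strain-energy density W_iso + W_ani (kPa).

    The anisotropic term applies only in tension (lambda_f > 1).  The active
    contribution is not an energy here; active stress is specified directly
    (see :func:`pk2_active`).  ``gamma_bar`` is accepted for signature
    symmetry but does not enter the returned value.
    """
    lam = kin.lambda_f
    if lam <= 0:
        raise InvalidKinematicsError("lambda_f <= 0")
    W = mp.c10 * (kin.I1 - 3.0) + mp.c01 * (kin.I2 - 3.0)
    if lam > 1.0:
        W += mp.b1 / mp.d1 * (lam ** mp.d1 - 1.0) - mp.b1 * np.log(lam)
    return float(W)


def pk2_iso(C: np.ndarray, mp: MaterialParams) -> np.ndarray:
    """Isotropic (Mooney-Rivlin) part of the 2nd Piola-Kirchhoff stress."""
    C = _check_spd(C)
    I1 = float(np.trace(C))
    return 2.0 * mp.c10 * _I3 + 2.0 * mp.c01 * (I1 * _I3 - C)


def pk2_ani(lambda_f: float, a0: np.ndarray, mp: MaterialParams) -> np.ndarray:
    """Tension-only anisotropic fiber stress; zero tensor for lambda_f <= 1."""
    if lambda_f <= 0:
        raise InvalidKinematicsError("lambda_f <= 0")
    a0 = _unit(a0, strict=False)
    if lambda_f <= 1.0:
        return np.zeros((3, 3))
    coeff = mp.b1 * (lambda_f ** (mp.d1 - 2.0) - lambda_f ** (-2.0))
    return coeff * np.outer(a0, a0)


def force_length(lambda_f: float, lambda_opt: float) -> float:
    """Piecewise-quadratic force-length factor in [0, 1], maximal at lambda_opt."""
    if lambda_f <= 0:
        raise InvalidKinematicsError("lambda_f <= 0")
    r = lambda_f / lambda_opt
    if r < 0.6 or r > 1.4:
        return 0.0
    return -25.0 / 4.0 * r * r + 25.0 / 2.0 * r - 5.25


def velocity_factor(u, mp: MaterialParams):
    """Hyperbolic force-velocity factor as a function of normalized speed u.

    ``u = (-lambda_dot_f)/lambda_dot_max`` clamped to [0, 1] (shortening
    only).  Returns ``Fiso * ((1 + a_rel) * b_rel / (b_rel + u) - a_rel)``,
    which equals Fiso at u = 0 and decreases monotonically.  Accepts scalars
    or arrays.
    """
    u = np.clip(u, 0.0, 1.0)
    out = mp.Fiso * ((1.0 + mp.a_rel) * mp.b_rel / (mp.b_rel + u) - mp.a_rel)
    if np.ndim(out) == 0:
        return float(out)
    return out


def gamma_scale(A2_norm, u, mp: MaterialParams):
    """Activation scale gamma = A2_norm * velocity_factor(u).

    ``A2_norm`` is clamped to [0, 1] (overshoot up to 1e-3 tolerated
    silently; it originates from calibration noise).
    """
    A2_norm = np.clip(A2_norm, 0.0, 1.0)
    out = A2_norm * velocity_factor(u, mp)
    if np.ndim(out) == 0:
        return float(out)
    return out


def pk2_active(lambda_f: float, gamma_bar: float, a0: np.ndarray,
               mp: MaterialParams) -> np.ndarray:
    """Active 2nd Piola-Kirchhoff stress along the fiber direction.

    S_act = lambda_f^-1 * Pmax * f_len(lambda_f) * gamma_bar * a0 (x) a0.
    """
    if lambda_f <= 0:
        raise InvalidKinematicsError("lambda_f <= 0")
    if gamma_bar < 0:
        raise ConfigError(f"gamma_bar must be >= 0, got {gamma_bar!r}")
    a0 = _unit(a0, strict=False)
    p_act = mp.Pmax * force_length(lambda_f, mp.lambda_opt) * gamma_bar
    return (p_act / lambda_f) * np.outer(a0, a0)


def pk2_total(kin: Kinematics, p: float, gamma_bar: float, u: float,
              mp: MaterialParams) -> np.ndarray:
    """Total 2nd Piola-Kirchhoff stress S = S_iso + S_ani + S_act - p C^-1.

    ``gamma_bar`` here is the homogenized activation before velocity
    scaling at this point; the Hill factor for normalized speed ``u`` is
    applied via :func:`gamma_scale` upstream when ``u`` is folded into the
    nodal gamma.  Passing u explicitly multiplies gamma_bar by the velocity
    factor (set u=0 if gamma_bar already includes it).
    """
    gbar = gamma_bar * velocity_factor(u, mp) / mp.Fiso if u else gamma_bar
    try:
        Cinv = np.linalg.inv(kin.C)
    except np.linalg.LinAlgError as exc:
        raise InvalidKinematicsError("singular C") from exc
    S = (pk2_iso(kin.C, mp)
         + pk2_ani(kin.lambda_f, kin.a0, mp)
         + pk2_active(kin.lambda_f, gbar, kin.a0, mp)
         - p * Cinv)
    return S


def cauchy_from_pk2(S: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Push-forward T = J^-1 F S F^T."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidKinematicsError(f"det F = {J:.6g} <= 0")
    return (F @ S @ F.T) / J


def reference_pressure(mp: MaterialParams) -> float:
    """Pressure that renders the reference configuration stress-free."""
    return 2.0 * mp.c10 + 4.0 * mp.c01
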