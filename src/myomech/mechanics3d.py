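"""Quasi-static incompressible finite elasticity on Taylor-Hood hexahedra.

Triquadratic (27-node) displacement with trilinear (8-node) continuous
pressure, 3x3x3 Gauss quadrature, total-Lagrangian weak form of div T = 0
with the transversely isotropic muscle material, and a Newton solver with
backtracking line search.  The consistent tangent is obtained per element
by complex-step differentiation of the residual (machine-precision, no
hand-derived material tangent to maintain).

A closed-form incompressible uniaxial oracle is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .constitutive import MaterialParams, force_length, velocity_factor
from .errors import ConfigError, InvalidKinematicsError, NonlinearDivergenceError

__all__ = [
    "MechMesh", "BoundaryProtocol", "build_cube_mesh", "assemble_system",
    "newton_solve", "gauss_point_kinematics", "uniaxial_oracle",
    "end_face_nominal_stress",
]

_EYE = np.eye(3)

# 3-point Gauss rule on [-1, 1]
_GP1 = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GW1 = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def _shape_q2_1d(x):
    N = np.array([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])
    dN = np.array([x - 0.5, -2.0 * x, x + 0.5])
    return N, dN


def _shape_q1_1d(x):
    return np.array([0.5 * (1 - x), 0.5 * (1 + x)]), np.array([-0.5, 0.5])


def shape_q2(xi):
    """27 triquadratic shape functions and gradients at natural coords xi."""
    Nx, dNx = _shape_q2_1d(xi[0])
    Ny, dNy = _shape_q2_1d(xi[1])
    Nz, dNz = _shape_q2_1d(xi[2])
    N = np.empty(27)
    dN = np.empty((27, 3))
    for iz in range(3):
        for iy in range(3):
            for ix in range(3):
                a = ix + 3 * iy + 9 * iz
                N[a] = Nx[ix] * Ny[iy] * Nz[iz]
                dN[a] = (dNx[ix] * Ny[iy] * Nz[iz],
                         Nx[ix] * dNy[iy] * Nz[iz],
                         Nx[ix] * Ny[iy] * dNz[iz])
    return N, dN


def shape_q1(xi):
    """8 trilinear shape functions at natural coords xi."""
    Nx, _ = _shape_q1_1d(xi[0])
    Ny, _ = _shape_q1_1d(xi[1])
    Nz, _ = _shape_q1_1d(xi[2])
    N = np.empty(8)
    for iz in range(2):
        for iy in range(2):
            for ix in range(2):
                N[ix + 2 * iy + 4 * iz] = Nx[ix] * Ny[iy] * Nz[iz]
    return N


def _gauss_points():
    pts = np.array([(x, y, z) for z in _GP1 for y in _GP1 for x in _GP1])
    wts = np.array([wx * wy * wz
                    for wz in _GW1 for wy in _GW1 for wx in _GW1])
    return pts, wts  # ordered x fastest, matching shape-node ordering


@dataclass
class MechMesh:
    """Structured Taylor-Hood hexahedral mesh with per-Gauss-point caches."""

    X: np.ndarray            # (n_geom, 3) reference geometry nodes (cm)
    conn: np.ndarray         # (ne, 27) triquadratic connectivity
    pconn: np.ndarray        # (ne, 8) trilinear pressure connectivity
    n_pnodes: int
    a0: np.ndarray           # (ne, 3) reference fiber direction per element
    dims: tuple              # (Lx, Ly, Lz)
    shape: tuple             # (nx, ny, nz) element counts
    gp_xi: np.ndarray = field(default=None)     # (27, 3) natural coords
    gp_w: np.ndarray = field(default=None)
    N: np.ndarray = field(default=None)         # (27 gp, 27 nodes)
    dNdxi: np.ndarray = field(default=None)     # (27 gp, 27 nodes, 3)
    Np: np.ndarray = field(default=None)        # (27 gp, 8)
    dNdX: np.ndarray = field(default=None)      # (ne, 27 gp, 27, 3)
    wdetJ0: np.ndarray = field(default=None)    # (ne, 27 gp)
    gamma_bar: np.ndarray = field(default=None)  # (ne, 27) activation cache
    u_gp: np.ndarray = field(default=None)       # (ne, 27) velocity cache
    lamf_prev: np.ndarray = field(default=None)  # (ne, 27) stretch at t - dt
    vel_coupling: tuple = None                   # (dt_cmm, lam_dot_max)

    def __post_init__(self):
        self.gp_xi, self.gp_w = _gauss_points()
        self.N = np.array([shape_q2(xi)[0] for xi in self.gp_xi])
        self.dNdxi = np.array([shape_q2(xi)[1] for xi in self.gp_xi])
        self.Np = np.array([shape_q1(xi) for xi in self.gp_xi])
        ne = self.conn.shape[0]
        self.dNdX = np.empty((ne, 27, 27, 3))
        self.wdetJ0 = np.empty((ne, 27))
        for e in range(ne):
            Xe = self.X[self.conn[e]]                       # (27, 3)
            for g in range(27):
                J0 = self.dNdxi[g].T @ Xe                   # dX/dxi (3,3)^T?
                # J0[i, j] = sum_a dN_a/dxi_i * X_a_j  -> dX_j/dxi_i
                det = np.linalg.det(J0)
                if det <= 0:
                    raise InvalidKinematicsError(
                        f"non-positive reference Jacobian in element {e}")
                self.dNdX[e, g] = self.dNdxi[g] @ np.linalg.inv(J0.T)
                self.wdetJ0[e, g] = self.gp_w[g] * det
        self.gamma_bar = np.zeros((ne, 27))
        self.u_gp = np.zeros((ne, 27))

    @property
    def n_elements(self) -> int:
        return self.conn.shape[0]

    @property
    def n_geom_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_geom_nodes + self.n_pnodes

    def reference_volume(self) -> float:
        return float(self.wdetJ0.sum())

    def zero_fields(self):
        return (np.zeros((self.n_geom_nodes, 3)), np.zeros(self.n_pnodes))


def build_cube_mesh(nx: int, ny: int, nz: int, L,
                    fiber_dir=(1.0, 0.0, 0.0)) -> MechMesh:
    """Structured Taylor-Hood box mesh with a uniform fiber direction.

    ``L`` is the edge length (scalar cube) or an (Lx, Ly, Lz) triple.
    """
    if min(nx, ny, nz) < 1:
        raise ConfigError("element counts must be >= 1")
    dims = tuple(float(v) for v in (np.broadcast_to(np.asarray(L, float),
                                                    (3,))))
    if min(dims) <= 0:
        raise ConfigError("edge lengths must be > 0")
    gdims = (2 * nx + 1, 2 * ny + 1, 2 * nz + 1)
    xs = [np.linspace(0.0, dims[k], gdims[k]) for k in range(3)]
    gz, gy, gx = np.meshgrid(xs[2], xs[1], xs[0], indexing="ij")
    X = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def gid(i, j, k):
        return i + gdims[0] * (j + gdims[1] * k)

    pdims = (nx + 1, ny + 1, nz + 1)

    def pid(i, j, k):
        return i + pdims[0] * (j + pdims[1] * k)

    conn = []
    pconn = []
    for ez in range(nz):
        for ey in range(ny):
            for ex in range(nx):
                nodes = [gid(2 * ex + ix, 2 * ey + iy, 2 * ez + iz)
                         for iz in range(3) for iy in range(3)
                         for ix in range(3)]
                pnodes = [pid(ex + ix, ey + iy, ez + iz)
                          for iz in range(2) for iy in range(2)
                          for ix in range(2)]
                conn.append(nodes)
                pconn.append(pnodes)
    a0 = np.asarray(fiber_dir, dtype=float)
    a0 = a0 / np.linalg.norm(a0)
    ne = nx * ny * nz
    return MechMesh(X=X, conn=np.array(conn), pconn=np.array(pconn),
                    n_pnodes=pdims[0] * pdims[1] * pdims[2],
                    a0=np.tile(a0, (ne, 1)), dims=dims, shape=(nx, ny, nz))


# ---------------------------------------------------------------------------
# element-level residual (batched; complex-safe for complex-step tangents)

def _force_length_cplx(lam, lambda_opt):
    r = lam / lambda_opt
    val = -6.25 * r * r + 12.5 * r - 5.25
    mask = (np.real(r) >= 0.6) & (np.real(r) <= 1.4)
    return np.where(mask, val, 0.0 * val)


def _element_residual(mesh: MechMesh, e: int, ue, pe, mp: MaterialParams):
    """Residual of element e for a batch of nodal fields.

    ue: (B, 27, 3), pe: (B, 8) -> (B, 89) residual [81 disp | 8 pressure].
    Works in complex arithmetic for tangent computation.
    """
    dN = mesh.dNdX[e]                     # (27 gp, 27, 3)
    wd = mesh.wdetJ0[e]                   # (27 gp,)
    a0 = mesh.a0[e]
    gam = mesh.gamma_bar[e]               # (27 gp,)
    F = np.einsum("bai,gaJ->bgiJ", ue, dN)
    F = F + _EYE[None, None, :, :]
    Jdet = np.linalg.det(F)
    if np.any(np.real(Jdet) <= 0):
        raise InvalidKinematicsError(
            f"element inversion (J <= 0) in element {e}")
    C = np.einsum("bgkI,bgkJ->bgIJ", F, F)
    Cinv = np.linalg.inv(C)
    I1 = np.einsum("bgII->bg", C)
    lam2 = np.einsum("I,bgIJ,J->bg", a0, C, a0)
    lam = np.sqrt(lam2)
    M = np.outer(a0, a0)

    S = (2.0 * mp.c10) * _EYE[None, None] \
        + 2.0 * mp.c01 * (I1[..., None, None] * _EYE[None, None] - C)
    coeff_ani = mp.b1 * (lam ** (mp.d1 - 2.0) - lam ** (-2.0))
    coeff_ani = np.where(np.real(lam) > 1.0, coeff_ani, 0.0 * coeff_ani)
    fl = _force_length_cplx(lam, mp.lambda_opt)
    coeff_act = mp.Pmax * fl * gam[None, :] / lam
    if mesh.vel_coupling is not None and mesh.lamf_prev is not None:
        # Hill force-velocity factor evaluated implicitly on the current
        # iterate's fiber stretch rate; the complex-step tangent then
        # carries the (stabilizing) d S_act / d lambda_dot contribution.
        dt_cmm, lam_dot_max = mesh.vel_coupling
        u_raw = (mesh.lamf_prev[e][None, :] - lam) / (dt_cmm * lam_dot_max)
        # smooth clamps to [0, 1] (C^1, width 1e-3) keep Newton well-behaved
        eps = 1e-3
        u_eff = 0.5 * (u_raw + np.sqrt(u_raw * u_raw + eps * eps))
        ex = 1.0 - u_eff
        u_eff = 1.0 - 0.5 * (ex + np.sqrt(ex * ex + eps * eps))
        vf = mp.Fiso * ((1.0 + mp.a_rel) * mp.b_rel / (mp.b_rel + u_eff)
                        - mp.a_rel)
        coeff_act = coeff_act * vf
    p_gp = np.einsum("bc,gc->bg", pe, mesh.Np)
    S = S + (coeff_ani + coeff_act)[..., None, None] * M[None, None]
    S = S - p_gp[..., None, None] * Cinv

    P = np.einsum("bgiK,bgKJ->bgiJ", F, S)
    Ru = np.einsum("bgiJ,gaJ,g->bai", P, dN, wd)
    Rp = np.einsum("bg,gc,g->bc", Jdet - 1.0, mesh.Np, wd)
    B = ue.shape[0]
    return np.concatenate([Ru.reshape(B, 81), Rp], axis=1)


def _element_dof_map(mesh: MechMesh, e: int) -> np.ndarray:
    gd = (3 * mesh.conn[e][:, None] + np.arange(3)[None, :]).ravel()
    pd = 3 * mesh.n_geom_nodes + mesh.pconn[e]
    return np.concatenate([gd, pd])


def assemble_system(mesh: MechMesh, u_field: np.ndarray, p_field: np.ndarray,
                    mp: MaterialParams, *, want_tangent: bool = True):
    """Global residual (and complex-step consistent tangent) of the weak form.

    Momentum balance without inertia or body forces plus the weak
    incompressibility constraint int (J - 1) dp dV.  Activation enters via
    the per-Gauss-point ``mesh.gamma_bar`` cache (zero for passive runs).
    """
    ndof = mesh.n_dofs
    R = np.zeros(ndof)
    rows, cols, vals = [], [], []
    h = 1e-30
    for e in range(mesh.n_elements):
        ue = u_field[mesh.conn[e]][None]            # (1, 27, 3)
        pe = p_field[mesh.pconn[e]][None]           # (1, 8)
        dofs = _element_dof_map(mesh, e)
        Re = _element_residual(mesh, e, ue, pe, mp)[0].real
        R[dofs] += Re
        if not want_tangent:
            continue
        nd = dofs.size                              # 89
        ue_b = np.repeat(ue.astype(complex), nd, axis=0)
        pe_b = np.repeat(pe.astype(complex), nd, axis=0)
        flat_u = ue_b.reshape(nd, 81)
        for j in range(81):
            flat_u[j, j] += 1j * h
        for j in range(8):
            pe_b[81 + j, j] += 1j * h
        Rb = _element_residual(mesh, e, ue_b, pe_b, mp)
        Ke = (Rb.imag / h).T                        # (89 rows, 89 cols)
        rows.append(np.repeat(dofs, nd))
        cols.append(np.tile(dofs, nd))
        vals.append(Ke.ravel())
    if not want_tangent:
        return R, None
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    return R, K


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryProtocol:
    """Axial end-face displacement protocol with symmetry rollers.

    The X=0 face is held (u_x = 0), the X=Lx face carries the prescribed
    axial displacement; u_y = 0 on Y=0 and u_z = 0 on Z=0 remove rigid-body
    modes while leaving homogeneous states exactly representable (the far
    lateral faces are traction-free).
    """

    prestretch: float = 0.2
    mode: str = "isometric_hold"        # or "constant_velocity_shortening"
    speed_fraction: float = 0.0         # fraction of vmax
    prestretch_steps: int = 4

    def __post_init__(self):
        if self.prestretch <= -1:
            raise ConfigError("prestretch must exceed -1")
        if not 0.0 <= self.speed_fraction <= 1.0:
            raise ConfigError("speed_fraction must lie in [0, 1]")
        if self.mode not in ("isometric_hold",
                            "constant_velocity_shortening"):
            raise ConfigError(f"unknown protocol mode {self.mode!r}")

    def end_displacement(self, t: float, Lx: float, vmax: float) -> float:
        """Axial displacement of the X=Lx face at simulation time t (ms)."""
        d0 = self.prestretch * Lx
        if self.mode == "isometric_hold":
            return d0
        return d0 - self.speed_fraction * vmax * t


def dirichlet_map(mesh: MechMesh, end_disp: float) -> dict:
    """Dof -> value map for the roller + axial-stretch boundary conditions."""
    Lx = mesh.dims[0]
    tol = 1e-9 * max(mesh.dims)
    bc = {}
    for n, Xn in enumerate(mesh.X):
        if abs(Xn[0]) < tol:
            bc[3 * n] = 0.0
        if abs(Xn[0] - Lx) < tol:
            bc[3 * n] = end_disp
        if abs(Xn[1]) < tol:
            bc[3 * n + 1] = 0.0
        if abs(Xn[2]) < tol:
            bc[3 * n + 2] = 0.0
    return bc


def newton_solve(mesh: MechMesh, u_field, p_field, mp: MaterialParams,
                 dirichlet: dict, *, tol: float = 1e-8, max_iter: int = 20,
                 pressure_datum: bool = False):
    """Solve the quasi-static problem for given Dirichlet data.

    Returns updated (u_field, p_field).  Initial guesses are taken from the
    passed-in fields; prescribed dofs are overwritten with their target
    values before iterating.
    """
    u = u_field.copy()
    p = p_field.copy()
    ndof = mesh.n_dofs
    fixed = np.fromiter(dirichlet.keys(), dtype=int)
    if pressure_datum:
        fixed = np.append(fixed, 3 * mesh.n_geom_nodes)
    free = np.setdiff1d(np.arange(ndof), fixed)
    uflat = u.reshape(-1)
    for dof, val in dirichlet.items():
        uflat[dof] = val

    def residual_norm(Rvec):
        return float(np.linalg.norm(Rvec[free]))

    R, K = assemble_system(mesh, u, p, mp)
    norm0 = residual_norm(R)
    ref = max(1.0, norm0)
    for it in range(max_iter + 1):
        if residual_norm(R) < tol * ref:
            return u, p
        if it == max_iter:
            break
        Kff = K[free][:, free]
        dx = spsolve(Kff.tocsc(), -R[free])
        if not np.all(np.isfinite(dx)):
            raise NonlinearDivergenceError("singular tangent")
        # backtracking line search: accept the best decrease found
        base = residual_norm(R)
        alpha = 1.0
        best = None
        for _ in range(12):
            u_try = u.copy()
            p_try = p.copy()
            du = np.zeros(ndof)
            du[free] = alpha * dx
            u_try.reshape(-1)[:] += du[: 3 * mesh.n_geom_nodes]
            p_try += du[3 * mesh.n_geom_nodes:]
            try:
                R_try, K_try = assemble_system(mesh, u_try, p_try, mp)
            except InvalidKinematicsError:
                alpha *= 0.5
                continue
            n_try = residual_norm(R_try)
            if best is None or n_try < best[0]:
                best = (n_try, u_try, p_try, R_try, K_try)
            if n_try < (1.0 - 1e-4 * alpha) * base:
                break
            alpha *= 0.5
        if best is None or best[0] >= base:
            raise NonlinearDivergenceError(
                f"line search stalled at residual {base:.3e}")
        _, u, p, R, K = best
    raise NonlinearDivergenceError(
        f"no convergence in {max_iter} iterations "
        f"(residual {residual_norm(R):.3e}, tol {tol * ref:.3e})")


def gauss_point_kinematics(mesh: MechMesh, u_field: np.ndarray):
    """F, J, C, lambda_f at every Gauss point of every element."""
    ne = mesh.n_elements
    F = np.empty((ne, 27, 3, 3))
    for e in range(ne):
        ue = u_field[mesh.conn[e]]
        F[e] = np.einsum("ai,gaJ->giJ", ue, mesh.dNdX[e]) + _EYE
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidKinematicsError("element inversion in deformed state")
    C = np.einsum("egkI,egkJ->egIJ", F, F)
    lam = np.sqrt(np.einsum("eI,egIJ,eJ->eg", mesh.a0, C, mesh.a0))
    return {"F": F, "J": J, "C": C, "lambda_f": lam}


def uniaxial_oracle(lam: float, gamma_bar: float, u: float,
                    mp: MaterialParams) -> float:
    """Closed-form nominal stress for incompressible uniaxial stretch.

    Kinematics lambda_1 = lam, lambda_2 = lambda_3 = lam^-1/2; the lateral
    faces are traction-free, which fixes the pressure.  Returns the nominal
    (1st Piola-Kirchhoff) axial stress in kPa.
    """
    if lam <= 0:
        raise InvalidKinematicsError("stretch must be positive")
    P = (mp.c10 * (2.0 * lam - 2.0 * lam ** -2)
         + mp.c01 * (2.0 - 2.0 * lam ** -3))
    if lam > 1.0:
        P += mp.b1 * (lam ** (mp.d1 - 1.0) - lam ** -1.0)
    P += (mp.Pmax * force_length(lam, mp.lambda_opt) * gamma_bar
          * velocity_factor(u, mp) / mp.Fiso)
    return float(P)


def end_face_nominal_stress(mesh: MechMesh, u_field, p_field,
                            mp: MaterialParams) -> float:
    """Axial nominal stress on the X=Lx face from discrete reactions (kPa).

    Sums the unconstrained residual's axial entries over the end-face nodes
    (the discrete reaction forces) and divides by the reference face area.
    """
    R, _ = assemble_system(mesh, u_field, p_field, mp, want_tangent=False)
    Lx, Ly, Lz = mesh.dims
    tol = 1e-9 * max(mesh.dims)
    nodes = np.where(np.abs(mesh.X[:, 0] - Lx) < tol)[0]
    force = R[3 * nodes].sum()
    return float(force / (Ly * Lz))
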