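"""Transfer operators between the 3D continuum mesh and embedded 1D fibers.

Fibers are stored in the local element coordinates of their host hexahedra
(xi in [0,1]^3), so their deformed positions follow from the triquadratic
basis; velocities are estimated from internode distances by backward
differences, smoothed over a seven-node patch; nodal activation values are
homogenized onto Gauss points by nearest-Gauss-point arithmetic means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmbeddingError
from .mechanics3d import MechMesh, shape_q2

__all__ = ["FiberMesh", "seed_fibers", "interpolate_positions",
           "fiber_velocity", "homogenize_gamma"]


@dataclass
class FiberMesh:
    """One embedded fiber: host elements, local coords, positions, history."""

    host: np.ndarray          # (n,) host element index per node
    xi: np.ndarray            # (n, 3) local coords in [0, 1]^3
    positions: np.ndarray     # (n, 3) current positions (cm)
    eta_ref: np.ndarray       # (n-1,) reference internode distances (cm)
    L_ref: float              # reference fiber length (cm)
    motor_unit: int = 0
    prev_positions: np.ndarray | None = None
    u: np.ndarray = field(default=None)        # (n,) normalized speed
    gamma: np.ndarray = field(default=None)    # (n,) nodal activation

    def __post_init__(self):
        n = self.host.shape[0]
        if self.xi.shape != (n, 3) or self.positions.shape != (n, 3):
            raise ConfigError("inconsistent fiber arrays")
        if np.any(self.xi < -1e-12) or np.any(self.xi > 1 + 1e-12):
            raise EmbeddingError("fiber local coordinates outside [0,1]^3")
        if np.any(self.eta_ref <= 0):
            raise ConfigError("reference internode spacing must be > 0")
        if self.u is None:
            self.u = np.zeros(n)
        if self.gamma is None:
            self.gamma = np.zeros(n)

    @property
    def n_nodes(self) -> int:
        return self.host.shape[0]


def seed_fibers(mesh: MechMesh, n_fibers: int, nodes_per_fiber: int,
                direction=(1.0, 0.0, 0.0)) -> list:
    """Seed straight fibers on a uniform transverse lattice.

    The direction must be parallel to the x parametric axis of the
    structured mesh (curved seeding is out of scope).  If ``n_fibers`` is
    not a perfect square a warning is raised and the nearest square lattice
    is used.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if not np.allclose(d, [1.0, 0.0, 0.0], atol=1e-12):
        raise ConfigError("fiber seeding requires direction along +x")
    if n_fibers < 1 or nodes_per_fiber < 2:
        raise ConfigError("need n_fibers >= 1 and nodes_per_fiber >= 2")
    k = int(round(np.sqrt(n_fibers)))
    if k * k != n_fibers:
        warnings.warn(
            f"{n_fibers} fibers is not a square lattice; using {k}x{k}")
    Lx, Ly, Lz = mesh.dims
    nx, ny, nz = mesh.shape
    hx, hy, hz = Lx / nx, Ly / ny, Lz / nz
    xs = np.linspace(0.0, Lx, nodes_per_fiber)
    ex = np.minimum((xs / hx).astype(int), nx - 1)
    xi_x = xs / hx - ex
    eta = np.diff(xs)
    fibers = []
    for jz in range(k):
        z = (jz + 0.5) * Lz / k
        ez = min(int(z / hz), nz - 1)
        for jy in range(k):
            y = (jy + 0.5) * Ly / k
            ey = min(int(y / hy), ny - 1)
            host = ex + nx * (ey + ny * ez)
            xi = np.column_stack([xi_x,
                                  np.full_like(xs, y / hy - ey),
                                  np.full_like(xs, z / hz - ez)])
            pos = np.column_stack([xs, np.full_like(xs, y),
                                   np.full_like(xs, z)])
            fibers.append(FiberMesh(host=host.copy(), xi=xi, positions=pos,
                                    eta_ref=eta.copy(), L_ref=float(Lx)))
    return fibers


def interpolate_positions(mesh: MechMesh, u_field: np.ndarray,
                          fibers) -> None:
    """Update fiber node positions from the deformed 3D geometry, in place.

    Stores the previous positions for the backward-difference velocity.
    """
    x_def = mesh.X + u_field
    for f in fibers:
        if np.any(f.xi < -1e-9) or np.any(f.xi > 1 + 1e-9):
            raise EmbeddingError("fiber embedding corrupted")
        new = np.empty_like(f.positions)
        for i in range(f.n_nodes):
            N, _ = shape_q2(2.0 * f.xi[i] - 1.0)
            new[i] = N @ x_def[mesh.conn[f.host[i]]]
        f.prev_positions = f.positions
        f.positions = new


def _patch_average(vals: np.ndarray, patch: int) -> np.ndarray:
    """Centered moving average, window shrinking symmetrically at the ends."""
    half = patch // 2
    n = vals.size
    out = np.empty(n)
    for i in range(n):
        w = min(half, i, n - 1 - i)
        out[i] = vals[i - w:i + w + 1].mean()
    return out


def fiber_velocity(fibers, dt_cmm: float, vmax: float,
                   patch: int = 7) -> None:
    """Normalized shortening speed u per node, in place on each fiber.

    Per-segment stretch rates from backward differences of internode
    distances, mapped to nodes, patch-averaged, normalized by
    lambda_dot_max = vmax / L_ref and clamped to shortening (u in [0,1]).
    Fibers with no position history get u = 0.
    """
    if dt_cmm <= 0:
        raise ConfigError("dt_cmm must be > 0")
    for f in fibers:
        if f.prev_positions is None:
            f.u = np.zeros(f.n_nodes)
            continue
        eta_new = np.linalg.norm(np.diff(f.positions, axis=0), axis=1)
        eta_old = np.linalg.norm(np.diff(f.prev_positions, axis=0), axis=1)
        seg_rate = (eta_new - eta_old) / (dt_cmm * f.eta_ref)  # 1/ms
        node_rate = np.empty(f.n_nodes)
        node_rate[0] = seg_rate[0]
        node_rate[-1] = seg_rate[-1]
        node_rate[1:-1] = 0.5 * (seg_rate[:-1] + seg_rate[1:])
        node_rate = _patch_average(node_rate, patch)
        lam_dot_max = vmax / f.L_ref
        f.u = np.clip(-node_rate / lam_dot_max, 0.0, 1.0)


def homogenize_gamma(fibers, mesh: MechMesh) -> np.ndarray:
    """Arithmetic-mean homogenization of nodal gamma onto Gauss points.

    Each fiber node is assigned to the nearest Gauss point of its host
    element (distance in local coordinates; ties go to the lowest Gauss
    index).  Gauss points with no assigned nodes fall back to the host
    element's mean; elements without any fiber nodes fall back to the
    global mean with a warning.  Returns (and stores) the (ne, 27) field.
    """
    ne = mesh.n_elements
    sums = np.zeros((ne, 27))
    counts = np.zeros((ne, 27), dtype=int)
    esums = np.zeros(ne)
    ecounts = np.zeros(ne, dtype=int)
    total, ntotal = 0.0, 0
    for f in fibers:
        xin = 2.0 * f.xi - 1.0  # natural coords of the host element
        d2 = ((xin[:, None, :] - mesh.gp_xi[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)  # lowest index wins ties
        for i in range(f.n_nodes):
            e = f.host[i]
            g = f.gamma[i]
            sums[e, nearest[i]] += g
            counts[e, nearest[i]] += 1
            esums[e] += g
            ecounts[e] += 1
            total += g
            ntotal += 1
    if ntotal == 0:
        raise ConfigError("no fiber nodes to homogenize")
    gbar = np.empty((ne, 27))
    gmean = total / ntotal
    for e in range(ne):
        if ecounts[e] == 0:
            warnings.warn(f"element {e} contains no fiber nodes; "
                          "using global mean activation")
            gbar[e, :] = gmean
            continue
        emean = esums[e] / ecounts[e]
        has = counts[e] > 0
        gbar[e, has] = sums[e, has] / counts[e, has]
        gbar[e, ~has] = emean
    mesh.gamma_bar[:] = gbar
    return gbar
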