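"""1D finite-element monodomain propagation along a (deforming) fiber.

The cable equation is split Godunov-style into a pointwise reaction part
(the half-sarcomere ODEs, subcycled with a smaller step) and a linear
diffusion part advanced with backward Euler on linear Lagrange elements
over the current arclength mesh.  Zero-flux (natural) boundary conditions
hold at both fiber ends, so the mass-weighted mean of Vm is conserved
exactly by the diffusion solve.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigError, DegenerateElementError, SolverDivergenceError
from .halfsarcomere import IV, ReducedCellModel

__all__ = ["fiber_matrices", "FiberSystem"]


def fiber_matrices(s: np.ndarray, sigma: float, lumped: bool = False):
    """Mass and stiffness matrices for linear elements on arclength grid s.

    Returns sparse (M, K) with natural boundary conditions (nothing to
    impose).  ``s`` must be strictly increasing.
    """
    s = np.asarray(s, dtype=float)
    h = np.diff(s)
    if np.any(h <= 0):
        raise DegenerateElementError(
            f"non-positive element length (min h = {h.min():.3g} cm)")
    n = s.size
    main = np.zeros(n)
    off = np.zeros(n - 1)
    # stiffness: sigma/h * [[1,-1],[-1,1]]
    main[:-1] += sigma / h
    main[1:] += sigma / h
    off[:] = -sigma / h
    K = sp.diags([off, main, off], [-1, 0, 1], format="csc")
    mmain = np.zeros(n)
    if lumped:
        mmain[:-1] += h / 2
        mmain[1:] += h / 2
        M = sp.diags([mmain], [0], format="csc")
    else:
        moff = h / 6.0
        mmain[:-1] += h / 3
        mmain[1:] += h / 3
        M = sp.diags([moff, mmain, moff], [-1, 0, 1], format="csc")
    return M, K


class FiberSystem:
    """One embedded fiber: arclength mesh, per-node cell states, matrices.

    Node order follows the fiber path.  The neuromuscular junction sits at
    node ``n // 2`` (the exact middle for an odd node count).  Cell states
    are stored as one (n_nodes, n_states) block; ``Vm`` is a view of its
    voltage column, so the operator-splitting voltage transfers (cell ->
    diffusion -> cell) are plain reads/writes of that column.
    """

    def __init__(self, positions: np.ndarray, model: ReducedCellModel,
                 sigma: float, Am: float, Cm: float, dt_deq: float,
                 fiber_type: str = "fast", lumped_mass: bool = False,
                 states: np.ndarray | None = None):
        for name, val in (("sigma", sigma), ("Am", Am), ("Cm", Cm),
                          ("dt_deq", dt_deq)):
            if not val > 0:
                raise ConfigError(f"{name} must be > 0, got {val!r}")
        positions = np.asarray(positions, dtype=float)
        if positions.ndim == 1:
            positions = positions[:, None]
        if positions.shape[0] < 2:
            raise ConfigError("a fiber needs at least 2 nodes")
        self.model = model
        self.sigma = float(sigma)
        self.Am = float(Am)
        self.Cm = float(Cm)
        self.dt_deq = float(dt_deq)
        self.fiber_type = fiber_type
        self.lumped_mass = lumped_mass
        self.positions = positions.copy()
        n = positions.shape[0]
        self.junction = n // 2
        if states is None:
            rest = model.rest_state(fiber_type)
            self.states = np.tile(rest.y, (n, 1))
        else:
            states = np.asarray(states, dtype=float)
            if states.shape != (n, model.n_states):
                raise ConfigError("states block has wrong shape")
            self.states = states.copy()
        self.assemble()

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def Vm(self) -> np.ndarray:
        """Membrane voltage vector (view into the cell-state block)."""
        return self.states[:, IV]

    @property
    def arclength(self) -> np.ndarray:
        return self._s

    def assemble(self) -> None:
        """(Re)build mass/stiffness and the backward-Euler factorization."""
        d = np.diff(self.positions, axis=0)
        self._s = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(d, axis=1))])
        self.M, self.K = fiber_matrices(self._s, self.sigma,
                                        self.lumped_mass)
        A = (self.M + (self.dt_deq / (self.Am * self.Cm)) * self.K).tocsc()
        self._solver = splu(A)

    # ------------------------------------------------------------------
    def reaction_substep(self, dt_hsm: float, n_steps: int,
                         I_junction: float = 0.0) -> None:
        """Advance every node's cell model; stimulus only at the junction.

        This is the reaction half-step of the splitting: no spatial
        coupling, the voltage column is simply overwritten by the cell
        states (V* of the split).
        """
        if dt_hsm <= 0 or n_steps < 1:
            raise ConfigError("dt_hsm must be > 0 and n_steps >= 1")
        stim = np.zeros(self.n_nodes)
        stim[self.junction] = I_junction
        self.model.advance_block(self.states, dt_hsm, n_steps, stim, self.Cm)
        if not np.all(np.isfinite(self.states)):
            bad = np.argwhere(~np.isfinite(self.states))[0]
            raise SolverDivergenceError(
                f"cell state diverged at fiber node {bad[0]} "
                f"(state '{self.model.names[bad[1]]}')")

    def diffusion_step(self) -> np.ndarray:
        """Backward-Euler diffusion solve; updates Vm in place, returns it."""
        rhs = self.M @ self.Vm
        v_new = self._solver.solve(rhs)
        if not np.all(np.isfinite(v_new)):
            raise SolverDivergenceError("diffusion solve produced non-finite "
                                        "voltage (assembly-order bug?)")
        self.states[:, IV] = v_new
        return v_new

    def update_geometry(self, new_positions: np.ndarray) -> None:
        """Adopt deformed node positions; Vm and cell states ride along."""
        new_positions = np.asarray(new_positions, dtype=float)
        if new_positions.ndim == 1:
            new_positions = new_positions[:, None]
        if new_positions.shape != self.positions.shape:
            raise ConfigError("node count must not change")
        self.positions = new_positions.copy()
        self.assemble()

    # ------------------------------------------------------------------
    def mass_weighted_mean(self) -> float:
        w = np.asarray(self.M.sum(axis=1)).ravel()
        return float(w @ self.Vm / w.sum())
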