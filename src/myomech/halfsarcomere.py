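"""0D half-sarcomere layer: cell-model interface plus a reduced default.

The default model chains three submodels:

* a Hodgkin-Huxley-type sarcolemma (Na, K, leak) producing ~2-4 ms action
  potentials,
* a voltage-gated calcium release variable with first-order reuptake,
* a three-pool crossbridge chain D -> A1 <-> A2 with cooperative
  calcium-dependent attachment; the post-power-stroke pool A2, normalized by
  its tetanic plateau, drives the continuum active stress.

Only the qualitative behaviors (quiescence, threshold, tetanic fusion,
nonnegative concentrations) are contractual; all rate constants are
configuration values.  State vectors are advanced with a fixed-step
semi-implicit scheme (exponential Rush-Larsen gates, implicit-Euler voltage
and calcium) that is vectorized across cells; an explicit reference
integration via ``rhs`` + scipy is used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import CalibrationError, ConfigError, SolverDivergenceError
from .stimulus import StimulusProtocol

__all__ = [
    "STATE_NAMES", "CellState", "ReducedCellModel",
    "advance_reaction", "a2_normalized", "calibrate_a2max",
]

STATE_NAMES = ("Vm", "m", "h", "n", "ca", "D", "A1", "A2")
IV, IM, IH, IN, ICA, ID, IA1, IA2 = range(8)

_GATES = (IM, IH, IN)
_CONCS = (ICA, ID, IA1, IA2)


@dataclass
class CellState:
    """One half-sarcomere's full state vector plus its fiber type."""

    y: np.ndarray
    fiber_type: str = "fast"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).reshape(len(STATE_NAMES))
        if self.fiber_type not in ("slow", "fast"):
            raise ConfigError(f"unknown fiber type {self.fiber_type!r}")

    @property
    def Vm(self) -> float:
        return float(self.y[IV])

    @property
    def A1(self) -> float:
        return float(self.y[IA1])

    @property
    def A2(self) -> float:
        return float(self.y[IA2])

    @property
    def ca(self) -> float:
        return float(self.y[ICA])

    def __getitem__(self, name: str) -> float:
        return float(self.y[STATE_NAMES.index(name)])

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.fiber_type)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gate kinetics (1/ms, voltages in mV)

def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    xr = np.clip(x / y, -50.0, 50.0)
    small = np.abs(xr) < 1e-6
    denom = np.expm1(np.where(small, 1.0, xr))
    return np.where(small, y * (1.0 - xr / 2.0), x / denom)


def _gate_rates(V):
    am = 0.1 * _vtrap(-(V + 40.0), 10.0)
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(V + 55.0), 10.0)
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@dataclass(frozen=True)
class ReducedCellModel:
    """Reduced biophysical half-sarcomere model (see module docstring).

    Conductances in mS/cm^2, potentials mV, rates 1/ms.  Calcium is tracked
    in arbitrary concentration units; the crossbridge pools are fractions of
    a conserved total (D + A1 + A2 = 1).
    """

    g_na: float = 120.0
    e_na: float = 50.0
    g_k: float = 36.0
    e_k: float = -77.0
    g_l: float = 0.3
    e_l: float = -54.387
    cm_slow: float = 0.58     # uF/cm^2
    cm_fast: float = 1.0
    k_rel: float = 5.0        # Ca release rate at open channels
    k_up: float = 0.05        # Ca reuptake rate (1/ms)
    v_ca: float = -20.0       # release activation midpoint (mV)
    kslope_ca: float = 5.0    # release activation slope (mV)
    k_ca: float = 1.0         # Ca half-activation of attachment
    ca_thresh: float = 0.02   # attachment dead zone (no cycling at rest)
    f0: float = 0.5           # D -> A1 max attachment rate (1/ms)
    fp: float = 0.10          # A1 -> D detachment (1/ms)
    hp: float = 0.12          # A1 -> A2 power stroke (1/ms)
    hm: float = 0.03          # A2 -> A1 reverse stroke (1/ms)
    g0: float = 0.04          # A2 -> D detachment (1/ms)

    n_states: int = field(default=len(STATE_NAMES), init=False)
    names: tuple = field(default=STATE_NAMES, init=False)

    def __post_init__(self):
        for f in fields(self):
            if f.init and f.name not in ("e_na", "e_k", "e_l", "v_ca"):
                if not getattr(self, f.name) > 0:
                    raise ConfigError(
                        f"cell parameter {f.name} must be > 0")
        object.__setattr__(self, "_pvec", np.array([
            self.g_na, self.e_na, self.g_k, self.e_k, self.g_l, self.e_l,
            self.k_rel, self.k_up, self.v_ca, self.kslope_ca, self.k_ca,
            self.f0, self.fp, self.hp, self.hm, self.g0, self.ca_thresh,
        ]))

    def Cm(self, fiber_type: str) -> float:
        if fiber_type == "slow":
            return self.cm_slow
        if fiber_type == "fast":
            return self.cm_fast
        raise ConfigError(f"unknown fiber type {fiber_type!r}")

    # -- pieces ------------------------------------------------------------
    def ionic_current(self, state) -> float:
        """Outward membrane current I_ion (uA/cm^2)."""
        y = state.y if isinstance(state, CellState) else np.asarray(state)
        V, m, h, n = y[IV], y[IM], y[IH], y[IN]
        return float(self.g_na * m ** 3 * h * (V - self.e_na)
                     + self.g_k * n ** 4 * (V - self.e_k)
                     + self.g_l * (V - self.e_l))

    def _release_open(self, V):
        return 1.0 / (1.0 + np.exp(-(V - self.v_ca) / self.kslope_ca))

    def _attach_rate(self, ca):
        cc = np.maximum(ca - self.ca_thresh, 0.0)
        cc2 = cc * cc
        return self.f0 * cc2 / (cc2 + self.k_ca ** 2)

    def a2_of(self, state) -> float:
        y = state.y if isinstance(state, CellState) else np.asarray(state)
        return float(y[IA2])

    # -- full right-hand side (reference path, scipy-compatible) -----------
    def rhs(self, y, I_stim: float = 0.0, fiber_type: str = "fast"):
        """d(state)/dt for one cell; used by reference integrators."""
        y = np.asarray(y, dtype=float)
        V = y[IV]
        cm = self.Cm(fiber_type)
        am, bm, ah, bh, an, bn = _gate_rates(V)
        dy = np.empty_like(y)
        dy[IV] = (I_stim - self.ionic_current(y)) / cm
        dy[IM] = am * (1.0 - y[IM]) - bm * y[IM]
        dy[IH] = ah * (1.0 - y[IH]) - bh * y[IH]
        dy[IN] = an * (1.0 - y[IN]) - bn * y[IN]
        dy[ICA] = self.k_rel * self._release_open(V) - self.k_up * y[ICA]
        f = self._attach_rate(y[ICA])
        dy[ID] = -f * y[ID] + self.fp * y[IA1] + self.g0 * y[IA2]
        dy[IA1] = f * y[ID] - (self.fp + self.hp) * y[IA1] + self.hm * y[IA2]
        dy[IA2] = self.hp * y[IA1] - (self.hm + self.g0) * y[IA2]
        return dy

    # -- vectorized fixed-step integrator (production path) ----------------
    def step_array(self, Y: np.ndarray, dt: float, I_stim: np.ndarray,
                   cm) -> None:
        """Advance a (n_cells, n_states) state block by one step, in place.

        Gates use the exact exponential (Rush-Larsen) update; Vm and Ca use
        implicit Euler with conductances frozen at the updated gates, which
        keeps the scheme stable for stiff depolarization currents.
        """
        V = Y[:, IV]
        am, bm, ah, bh, an, bn = _gate_rates(V)
        for idx, (a, b) in zip(_GATES, ((am, bm), (ah, bh), (an, bn))):
            tau = 1.0 / (a + b)
            inf = a * tau
            Y[:, idx] = inf + (Y[:, idx] - inf) * np.exp(-dt / tau)
        gna = self.g_na * Y[:, IM] ** 3 * Y[:, IH]
        gk = self.g_k * Y[:, IN] ** 4
        gtot = gna + gk + self.g_l
        erev = gna * self.e_na + gk * self.e_k + self.g_l * self.e_l
        # implicit Euler: cm (V+ - V)/dt = I_stim - gtot V+ + erev
        Y[:, IV] = (V + dt / cm * (I_stim + erev)) / (1.0 + dt / cm * gtot)
        # calcium: implicit in c, release evaluated at updated V
        rel = self.k_rel * self._release_open(Y[:, IV])
        Y[:, ICA] = (Y[:, ICA] + dt * rel) / (1.0 + dt * self.k_up)
        # crossbridge pools: explicit Euler (rates << 1/dt)
        f = self._attach_rate(Y[:, ICA])
        D, A1, A2 = Y[:, ID], Y[:, IA1], Y[:, IA2]
        dD = -f * D + self.fp * A1 + self.g0 * A2
        dA1 = f * D - (self.fp + self.hp) * A1 + self.hm * A2
        dA2 = self.hp * A1 - (self.hm + self.g0) * A2
        Y[:, ID] = D + dt * dD
        Y[:, IA1] = A1 + dt * dA1
        Y[:, IA2] = A2 + dt * dA2

    def advance_block(self, Y: np.ndarray, dt: float, n_steps: int,
                      I_stim: np.ndarray, cm: float) -> None:
        """Advance a state block ``n_steps`` with constant stimulus, in place.

        Uses the compiled kernel when numba is available; otherwise loops
        :meth:`step_array`.  Both paths implement the same scheme.
        """
        from . import _kernels

        stim = np.ascontiguousarray(np.broadcast_to(
            np.asarray(I_stim, dtype=float), (Y.shape[0],)))
        if _kernels.HAVE_NUMBA:
            _kernels.advance_cells(Y, float(dt), int(n_steps), stim,
                                   float(cm), self._pvec)
        else:  # pragma: no cover - numba present in CI image
            _kernels.advance_cells_numpy(self, Y, float(dt), int(n_steps),
                                         stim, float(cm))

    # -- rest state --------------------------------------------------------
    def rest_state(self, fiber_type: str = "fast") -> CellState:
        """Quiescent equilibrium: |rhs| ~ 0 at zero stimulus."""
        from scipy.optimize import brentq

        def inet(V):
            am, bm, ah, bh, an, bn = _gate_rates(V)
            m = am / (am + bm)
            h = ah / (ah + bh)
            n = an / (an + bn)
            return (self.g_na * m ** 3 * h * (V - self.e_na)
                    + self.g_k * n ** 4 * (V - self.e_k)
                    + self.g_l * (V - self.e_l))

        V = brentq(inet, -90.0, -40.0, xtol=1e-12)
        am, bm, ah, bh, an, bn = _gate_rates(V)
        ca = self.k_rel * self._release_open(V) / self.k_up
        f = self._attach_rate(ca)
        # steady crossbridge pools under conservation D + A1 + A2 = 1
        A = np.array([
            [-f, self.fp, self.g0],
            [f, -(self.fp + self.hp), self.hm],
            [1.0, 1.0, 1.0],
        ])
        D, A1, A2 = np.linalg.solve(A, np.array([0.0, 0.0, 1.0]))
        y = np.zeros(len(STATE_NAMES))
        y[IV] = V
        y[IM] = am / (am + bm)
        y[IH] = ah / (ah + bh)
        y[IN] = an / (an + bn)
        y[ICA] = ca
        y[ID], y[IA1], y[IA2] = D, A1, A2
        return CellState(y, fiber_type)


def advance_reaction(state: CellState, model: ReducedCellModel,
                     dt_hsm: float, n_steps: int,
                     I_stim: float = 0.0) -> CellState:
    """Advance one cell by ``n_steps`` fixed steps of ``dt_hsm`` (ms)."""
    if dt_hsm <= 0 or n_steps < 1:
        raise ConfigError("dt_hsm must be > 0 and n_steps >= 1")
    Y = state.y.copy().reshape(1, -1)
    cm = model.Cm(state.fiber_type)
    model.advance_block(Y, dt_hsm, n_steps, np.full(1, float(I_stim)), cm)
    if not np.all(np.isfinite(Y)):
        raise SolverDivergenceError("cell state became non-finite")
    return CellState(Y[0], state.fiber_type)


def a2_normalized(state, A2max: float) -> float:
    """A2 normalized by its tetanic plateau, clamped to [0, 1]."""
    if not A2max > 0:
        raise CalibrationError(f"A2max must be > 0 (got {A2max!r}); "
                               "run calibrate_a2max first")
    a2 = state.A2 if isinstance(state, CellState) else float(state)
    return float(np.clip(a2 / A2max, 0.0, 1.0))


def calibrate_a2max(model: ReducedCellModel, fiber_type: str = "fast",
                    protocol: StimulusProtocol | None = None,
                    dt_hsm: float = 0.001, max_horizon: float = 2000.0,
                    drift_tol: float = 1e-3) -> float:
    """Plateau A2 under maximal tetanic (default 100 Hz) 0D stimulation.

    Runs a single cell with no diffusion until the relative drift of the
    100 ms window-mean of A2 falls below ``drift_tol`` per 100 ms, then
    returns the mean over the last 10% of the elapsed run.
    """
    if protocol is None:
        protocol = StimulusProtocol(frequency_hz=100.0)
    state = model.rest_state(fiber_type)
    Y = state.y.reshape(1, -1)
    cm = model.Cm(fiber_type)
    window = 100.0  # ms
    # advance in chunks over which the stimulus is constant (pulse grid)
    chunk = protocol.width
    steps_per_chunk = max(1, int(round(chunk / dt_hsm)))
    chunks_per_window = max(1, int(round(window / chunk)))
    a2_means = []
    t = 0.0
    stim = np.zeros(1)
    n_windows = int(np.ceil(max_horizon / window))
    for _ in range(n_windows):
        acc = 0.0
        for _ in range(chunks_per_window):
            stim[0] = protocol.current(0, t)
            model.advance_block(Y, dt_hsm, steps_per_chunk, stim, cm)
            t += steps_per_chunk * dt_hsm
            acc += Y[0, IA2]
        if not np.all(np.isfinite(Y)):
            raise SolverDivergenceError("calibration run diverged")
        mean = acc / chunks_per_window
        a2_means.append(mean)
        if len(a2_means) >= 2 and a2_means[-2] > 0:
            drift = abs(a2_means[-1] - a2_means[-2]) / a2_means[-2]
            if drift < drift_tol:
                n_tail = max(1, int(np.ceil(0.1 * len(a2_means))))
                a2max = float(np.mean(a2_means[-n_tail:]))
                if a2max <= 0:
                    raise CalibrationError("tetanic A2 plateau is zero")
                return a2max
    raise CalibrationError(
        f"no A2 plateau within {max_horizon} ms (last drift window mean "
        f"{a2_means[-1]:.4g})")
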