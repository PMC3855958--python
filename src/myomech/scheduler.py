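"""Three-rate staggered time integration and the benchmark experiments.

One continuum step of size dt_cmm contains n_deq_per_cmm diffusion steps;
each diffusion step contains n_hsm_per_deq cell-model substeps.  Per
continuum step the loop runs: (A) reaction subcycling with junction
stimulus, (B/D) voltage transfer between cell states and the diffusion
vector, (C) backward-Euler diffusion, (E) nearest-Gauss-point
homogenization of the activation, (F) the quasi-static Newton solve with
the protocol's boundary data, (G) fiber position interpolation, velocity
estimation, and monodomain geometry update.  Runs are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig, make_fixture
from .constitutive import MaterialParams, force_length, reference_pressure
from .coupling import (fiber_velocity, homogenize_gamma,
                       interpolate_positions, seed_fibers)
from .errors import ConfigError
from .halfsarcomere import IA2, ReducedCellModel, calibrate_a2max
from .mechanics3d import (BoundaryProtocol, build_cube_mesh, dirichlet_map,
                          end_face_nominal_stress, gauss_point_kinematics,
                          newton_solve)
from .monodomain1d import FiberSystem
from .stimulus import StimulusProtocol

__all__ = ["Schedule", "StimulusProtocol", "SimulationResult", "run",
           "experiment_isometric_tetanus", "experiment_shortening",
           "timestep_study", "plateau_value", "oscillation_index"]


@dataclass(frozen=True)
class Schedule:
    """Exactly nested three-rate step sizes (all in ms)."""

    dt_hsm: float = 0.001
    n_hsm_per_deq: int = 10
    n_deq_per_cmm: int = 50
    t_end: float = 100.0

    def __post_init__(self):
        if not self.dt_hsm > 0:
            raise ConfigError("dt_hsm must be > 0")
        if self.n_hsm_per_deq < 1 or self.n_deq_per_cmm < 1:
            raise ConfigError("step ratios must be integers >= 1")
        if self.t_end < 0:
            raise ConfigError("t_end must be >= 0")

    @property
    def dt_deq(self) -> float:
        return self.dt_hsm * self.n_hsm_per_deq

    @property
    def dt_cmm(self) -> float:
        return self.dt_deq * self.n_deq_per_cmm

    @property
    def n_cmm_steps(self) -> int:
        return int(round(self.t_end / self.dt_cmm))

    @classmethod
    def paper_ratios(cls, dt_hsm: float = 1e-5, t_end: float = 100.0):
        """The literal 50:1 and 1000:1 nesting ratios as a preset."""
        return cls(dt_hsm=dt_hsm, n_hsm_per_deq=50, n_deq_per_cmm=1000,
                   t_end=t_end)


@dataclass
class SimulationResult:
    """Scalar traces per continuum step plus final field state."""

    times: np.ndarray
    nominal_stress: np.ndarray
    active_stress: np.ndarray
    length: np.ndarray
    mean_vm: np.ndarray
    mean_a2norm: np.ndarray
    mean_gamma: np.ndarray
    mesh: object = None
    fibers: list = field(default_factory=list)
    u_field: np.ndarray = None
    p_field: np.ndarray = None
    a2max: float = None
    cell_substeps: int = 0

    def table(self) -> dict:
        return {
            "time_ms": self.times,
            "nominal_stress_kPa": self.nominal_stress,
            "active_stress_kPa": self.active_stress,
            "length_cm": self.length,
            "mean_Vm_mV": self.mean_vm,
            "mean_A2norm": self.mean_a2norm,
            "mean_gamma": self.mean_gamma,
        }


_A2MAX_CACHE: dict = {}


def _calibrated_a2max(model: ReducedCellModel, fiber_type: str,
                      dt_hsm: float) -> float:
    key = (model._pvec.tobytes(), fiber_type, dt_hsm)
    if key not in _A2MAX_CACHE:
        _A2MAX_CACHE[key] = calibrate_a2max(model, fiber_type,
                                            dt_hsm=dt_hsm)
    return _A2MAX_CACHE[key]


def _effective_gamma(mesh, kin, mp: MaterialParams) -> np.ndarray:
    """Per-GP activation including the implicit Hill velocity factor."""
    if mesh.vel_coupling is None or mesh.lamf_prev is None:
        return mesh.gamma_bar
    dt_cmm, lam_dot_max = mesh.vel_coupling
    u_raw = (mesh.lamf_prev - kin["lambda_f"]) / (dt_cmm * lam_dot_max)
    eps = 1e-3  # same smooth clamp as the element residual
    u_gp = 0.5 * (u_raw + np.sqrt(u_raw * u_raw + eps * eps))
    ex = 1.0 - u_gp
    u_gp = 1.0 - 0.5 * (ex + np.sqrt(ex * ex + eps * eps))
    mesh.u_gp = u_gp
    vf = mp.Fiso * ((1.0 + mp.a_rel) * mp.b_rel / (mp.b_rel + u_gp)
                    - mp.a_rel)
    return mesh.gamma_bar * vf


def _mean_active_stress(mesh, kin, mp: MaterialParams) -> float:
    lam = kin["lambda_f"]
    fl = np.vectorize(force_length)(lam, mp.lambda_opt)
    return float(np.mean(mp.Pmax * fl * _effective_gamma(mesh, kin, mp)))


def run(config: SimConfig, *, stimulated: bool = True) -> SimulationResult:
    """Execute the configured experiment end to end (see module docstring)."""
    config.validate()
    mp = config.material
    sched = Schedule(dt_hsm=config.schedule.dt_hsm,
                     n_hsm_per_deq=config.schedule.n_hsm_per_deq,
                     n_deq_per_cmm=config.schedule.n_deq_per_cmm,
                     t_end=config.schedule.t_end)
    geo = config.geometry
    mesh = build_cube_mesh(geo.nx, geo.ny, geo.nz, geo.L,
                           config.fibers.direction)
    fibers = seed_fibers(mesh, config.fibers.n_fibers,
                         config.fibers.elements_per_fiber + 1,
                         config.fibers.direction)
    model = ReducedCellModel(**config.cellmodel.params)
    ftype = config.fibers.fiber_type
    cm = model.Cm(ftype)
    a2max = _calibrated_a2max(model, ftype, sched.dt_hsm)
    exp = config.experiment
    mode = ("constant_velocity_shortening"
            if exp.preset == "shortening" else "isometric_hold")
    protocol = BoundaryProtocol(prestretch=exp.prestretch, mode=mode,
                                speed_fraction=exp.speed_fraction,
                                prestretch_steps=exp.prestretch_steps)
    stim = StimulusProtocol(frequency_hz=config.stimulus.frequency_hz,
                            amplitude=config.stimulus.amplitude,
                            width=config.stimulus.width,
                            start=config.stimulus.start)
    if exp.preset == "passive":
        stimulated = False

    # --- static prestretch ramp (passive) ---------------------------------
    u, p = mesh.zero_fields()
    p[:] = reference_pressure(mp)
    Lx = mesh.dims[0]
    d_target = protocol.end_displacement(0.0, Lx, mp.vmax)
    steps = max(1, protocol.prestretch_steps)
    for s in range(1, steps + 1):
        u, p = newton_solve(mesh, u, p, mp,
                            dirichlet_map(mesh, d_target * s / steps))
    interpolate_positions(mesh, u, fibers)
    for f in fibers:
        f.prev_positions = None  # no velocity history at t = 0
        f.u = np.zeros(f.n_nodes)

    # --- embedded monodomain systems on the prestretched geometry ---------
    systems = [FiberSystem(f.positions, model, mp.sigma, mp.Am, cm,
                           sched.dt_deq, ftype) for f in fibers]

    # the Hill force-velocity factor is evaluated implicitly inside the
    # mechanics solve from the Gauss-point stretch rate (stabilizes the
    # staggered loop; equals vf(q) exactly for homogeneous protocols)
    mesh.vel_coupling = (sched.dt_cmm, mp.vmax / Lx)
    mesh.lamf_prev = gauss_point_kinematics(mesh, u)["lambda_f"]

    rows = []
    cell_substeps = 0

    def record(t):
        kin = gauss_point_kinematics(mesh, u)
        rows.append((
            t,
            end_face_nominal_stress(mesh, u, p, mp),
            _mean_active_stress(mesh, kin, mp),
            Lx + protocol.end_displacement(t, Lx, mp.vmax),
            float(np.mean([fs.Vm.mean() for fs in systems])),
            float(np.mean([np.clip(fs.states[:, IA2] / a2max, 0, 1).mean()
                           for fs in systems])),
            float(_effective_gamma(mesh, kin, mp).mean()),
        ))
        return kin

    record(0.0)
    t = 0.0
    for _k in range(sched.n_cmm_steps):
        # (A-D) reaction subcycling + diffusion, n_deq_per_cmm times
        for _j in range(sched.n_deq_per_cmm):
            for fi, fs in enumerate(systems):
                amp = (stim.current(stim.mu_for(fi), t)
                       if stimulated else 0.0)
                fs.reaction_substep(sched.dt_hsm, sched.n_hsm_per_deq, amp)
                fs.diffusion_step()
                cell_substeps += fs.n_nodes * sched.n_hsm_per_deq
            t += sched.dt_deq
        # (E) nodal activation -> Gauss-point homogenization.  The nodal
        # field carries the normalized crossbridge concentration; the Hill
        # velocity factor is folded in implicitly during the mechanics
        # solve (see _effective_gamma / MechMesh.vel_coupling).
        for f, fs in zip(fibers, systems):
            f.gamma = np.clip(fs.states[:, IA2] / a2max, 0.0, 1.0)
        homogenize_gamma(fibers, mesh)
        # (F) quasi-static mechanics at the new boundary position; on a
        # hard step (steep implicit Hill damping) fall back to boundary
        # continuation within the step
        d = protocol.end_displacement(t, Lx, mp.vmax)
        d_old = protocol.end_displacement(t - sched.dt_cmm, Lx, mp.vmax)
        try:
            u, p = newton_solve(mesh, u, p, mp, dirichlet_map(mesh, d),
                                max_iter=30)
        except NonlinearDivergenceError:
            for frac in (0.25, 0.5, 0.75, 1.0):
                di = d_old + frac * (d - d_old)
                u, p = newton_solve(mesh, u, p, mp, dirichlet_map(mesh, di),
                                    max_iter=60)
        # (G) fiber positions, nodal velocities (diagnostic, available to
        # velocity-sensitive cell models), monodomain geometry
        interpolate_positions(mesh, u, fibers)
        fiber_velocity(fibers, sched.dt_cmm, mp.vmax)
        for f, fs in zip(fibers, systems):
            fs.update_geometry(f.positions)
        kin = record(t)
        mesh.lamf_prev = kin["lambda_f"]

    cols = list(zip(*rows)) if rows else [[]] * 7
    return SimulationResult(
        times=np.array(cols[0]), nominal_stress=np.array(cols[1]),
        active_stress=np.array(cols[2]), length=np.array(cols[3]),
        mean_vm=np.array(cols[4]), mean_a2norm=np.array(cols[5]),
        mean_gamma=np.array(cols[6]), mesh=mesh, fibers=fibers,
        u_field=u, p_field=p, a2max=a2max, cell_substeps=cell_substeps)


# ---------------------------------------------------------------------------
# analysis helpers

def plateau_value(times, series, *, window: float = 20.0,
                  drift_window: float = 100.0, drift_tol: float = 1e-3):
    """Mean over the last ``window`` ms once the drift per 100 ms is small.

    Returns (value, reached) where ``reached`` reports whether the drift
    criterion was met before the end of the trace.
    """
    times = np.asarray(times)
    series = np.asarray(series)
    tail = series[times >= times[-1] - window]
    value = float(tail.mean())
    mask_a = (times >= times[-1] - drift_window) & \
             (times < times[-1] - drift_window / 2)
    mask_b = times >= times[-1] - drift_window / 2
    if mask_a.any() and mask_b.any():
        a, b = series[mask_a].mean(), series[mask_b].mean()
        reached = abs(b - a) <= drift_tol * max(abs(a), 1e-12) * \
            (drift_window / 100.0)
    else:
        reached = False
    return value, bool(reached)


def oscillation_index(series) -> float:
    """Density of sign changes of the discrete second difference in (0,1]."""
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        return 0.0
    d2 = np.diff(series, 2)
    signs = np.sign(d2)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0.0
    return float(np.count_nonzero(np.diff(signs) != 0) / (series.size - 2))


# ---------------------------------------------------------------------------
# experiment presets

def experiment_isometric_tetanus(reduced: bool = True, *, t_end: float = 250.0,
                                 stimulated: bool = True) -> SimulationResult:
    """100 Hz tetanus of the cube held at the optimal stretch."""
    cfg = make_fixture("cube1_4" if reduced else "cube8_400")
    cfg.stimulus.frequency_hz = 100.0
    cfg.schedule.t_end = t_end
    cfg.experiment.preset = "isometric"
    return run(cfg, stimulated=stimulated)


def experiment_shortening(speed_fraction: float, reduced: bool = True, *,
                          t_end: float = 100.0,
                          frequency_hz: float = 50.0) -> SimulationResult:
    """Prestretch to optimum, stimulate, shorten at a fraction of vmax."""
    cfg = make_fixture("cube1_4" if reduced else "cube8_400")
    cfg.stimulus.frequency_hz = frequency_hz
    cfg.schedule.t_end = t_end
    if speed_fraction > 0:
        cfg.experiment.preset = "shortening"
        cfg.experiment.speed_fraction = speed_fraction
    else:
        cfg.experiment.preset = "isometric"
    return run(cfg)


def timestep_study(dt_cmm_list=(0.1, 0.5, 2.0), *, t_end: float = 80.0,
                   speed_fraction: float = 0.1) -> dict:
    """Shortening at 0.1 vmax, 50 Hz, for several continuum step sizes.

    The reaction/diffusion steps are held fixed; only the number of
    diffusion steps per continuum step changes.  Returns a dict
    dt_cmm -> SimulationResult.
    """
    out = {}
    for dt_cmm in dt_cmm_list:
        cfg = make_fixture("cube1_4")
        n_deq = int(round(dt_cmm / (cfg.schedule.dt_hsm
                                    * cfg.schedule.n_hsm_per_deq)))
        if abs(n_deq * cfg.schedule.dt_hsm * cfg.schedule.n_hsm_per_deq
               - dt_cmm) > 1e-12:
            raise ConfigError(f"dt_cmm {dt_cmm} not a multiple of dt_deq")
        cfg.schedule.n_deq_per_cmm = n_deq
        cfg.schedule.t_end = t_end
        cfg.stimulus.frequency_hz = 50.0
        cfg.experiment.preset = "shortening"
        cfg.experiment.speed_fraction = speed_fraction
        out[dt_cmm] = run(cfg)
    return out
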