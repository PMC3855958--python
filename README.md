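# myomech

Desk-scale multiscale chemoelectromechanical skeletal-muscle simulator:

* **0D half-sarcomere models** — a pluggable cell-model interface with a
  shipped reduced biophysical default (Hodgkin–Huxley-type sarcolemma,
  voltage-gated calcium release with first-order reuptake, and a three-pool
  crossbridge chain D → A1 ⇄ A2 whose normalized post-power-stroke pool A2
  drives the active stress),
* **1D monodomain propagation** — linear finite elements on the deforming
  fiber arclength, first-order Godunov reaction/diffusion splitting with
  backward-Euler diffusion and zero-flux ends, junction stimulation at the
  fiber midpoint,
* **3D incompressible finite elasticity** — transversely isotropic
  Mooney–Rivlin + tension-only fiber-polynomial material with a Hill
  force–velocity-scaled active stress, Taylor–Hood (Q2/Q1) hexahedra with
  3×3×3 Gauss quadrature, Newton solver with complex-step consistent
  tangents and backtracking line search,
* **transfer operators** — fibers embedded in element-local coordinates,
  triquadratic position interpolation, seven-node-patch backward-difference
  velocity estimates, and nearest-Gauss-point arithmetic-mean
  homogenization of the activation,
* **a three-rate staggered scheduler** — cell substeps nested in diffusion
  steps nested in quasi-static continuum steps, fully deterministic.

Units: cm / ms / mV / kPa / µA·cm⁻² / µF·cm⁻² / mS·cm⁻¹ (7.3 N/cm² ≡ 73 kPa).

## CLI

```bash
myomech run config.toml             # run a TOML/JSON config
myomech calibrate                   # tetanic A2 plateau of the cell model
myomech experiment isometric        # 100 Hz tetanus of the reduced cube
myomech experiment shortening --speed 0.1
myomech experiment dtstudy          # continuum time-step comparison
myomech sweep --speeds 0,0.01,0.1,0.25
myomech fixture cube8_400 cfg.json  # write a benchmark config
```

Fixtures: `cube8_400` (2 cm cube, 8 Taylor–Hood elements, 400 fibers of 60
elements), `cube8_36`, the reduced `cube1_4` (1 element, 4 fibers × 16
elements, used by CI), and `fiber_only`.

Outputs: a CSV time series (time, nominal/active stress, length, mean Vm,
mean normalized A2, mean activation), plain-XML VTU field snapshots, and
legacy-VTK fiber polylines.

## Layout

```
src/myomech/
  constitutive.py   material law: invariants, energies, passive/active PK2
  halfsarcomere.py  cell-model interface + reduced default, calibration
  _kernels.py       compiled (numba) cell-stepping inner loop
  stimulus.py       motor-unit firing schedules and pulse shapes
  monodomain1d.py   1D FEM cable equation with operator splitting
  mechanics3d.py    Taylor-Hood mixed FEM, Newton solver, uniaxial oracle
  coupling.py       fiber embedding, interpolation, velocity, homogenization
  scheduler.py      three-rate staggered loop and experiment presets
  config.py         validated config schema, TOML/JSON I/O, fixtures
  io.py             CSV / VTU / fiber-VTK writers
  cli.py            click entry point (`myomech`)
```
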