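# leukotransit

Simulation and neural-network surrogate modeling of **leukocyte
transmigration through a sub-cellular vascular pore**.

A key bottleneck of immune-cell infiltration is the passage of a
leukocyte through gaps narrower than its own diameter — microvascular
stenoses and endothelial pores.  This package models that event as a
passive fluid–structure interaction: a deformable cell (a linearly
elastic membrane filled with cytosol) is driven by pressure-controlled
plasma flow through a stenotic constriction in a 2D microchannel, and
small backpropagation neural networks (BPNNs) are trained on the
simulator's output so that transit time, cell deformation, downstream
velocity and the fluid lift/drag forces can be predicted in microseconds
instead of minutes, anywhere in the studied parameter plane.

It is intended for researchers in cellular biomechanics and computational
biofluid dynamics who want a self-contained, scriptable reference
implementation of the simulate → sweep → train → evaluate workflow.

## The model in brief

* **Flow**: incompressible Navier–Stokes in a plane channel (width
  W = 20 µm) at microvascular Reynolds numbers, Re = ρūW/µ ∈ [0.1, 0.2],
  driven by the fixed pressure drop that sustains the Re-matched mean
  velocity ū; plasma viscosity µ = 8×10⁻⁴ Pa·s, density ρ = 1000 kg/m³.
  Solved on a staggered grid with an immersed-boundary treatment of the
  cell and a volume-penalized constriction with rounded lips.
* **Cell**: diameter d = 10 µm; membrane thickness 0.4 µm, elastic
  modulus 100 Pa (admissible 50–500 Pa), Poisson ratio 0.25; stretching
  stiffness E·h/(1−ν²) plus a small bending regularization; Lagrangian
  markers coupled to the grid by the 4-point regularized delta kernel.
* **Pore**: gap width AR·d, where AR ∈ [0.5, 0.95] is the pore-to-cell
  aspect ratio; AR < 1 means the cell must deform to pass.  A cell that
  lodges permanently (impaction) is detected and excluded from training.
* **Surrogates**: feedforward nets with two hidden layers (tansig hidden,
  purelin output) trained by Levenberg–Marquardt with validation-based
  early stopping.  The transit-time model maps (Re, AR) → t with hidden
  sizes (5, 10); the motion/force models map (Re, AR, displacement) →
  R_max | V_y | F_l | F_d with hidden sizes (20, 30).  Hidden-node counts
  follow the capacity rule Σₙ₌₀^M C(I, n) > h (15 nodes minimum for 2
  inputs and 115 samples).  Accuracy is reported as the coefficient of
  determination R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² against held-out simulations.

See `docs/methods.md` for the numerical methods, parameter meanings and
known limitations.

## Worked example

Simulate one scenario from the shell (desk-scale resolution):

```
$ leukotransit simulate --profile coarse-ci --re 0.12 --ar 0.75 --out runs
outcome=transit transit_time=0.00811039s steps=2034 wall=4.7s (config c5ea9c408b7f)
```

The cell squeezed through the 7.5 µm pore in 8.11 ms; the trajectory
(displacement, R_max, V_y, F_l, F_d vs time) is stored next to a one-row
CSV summary, both stamped with the configuration hash.

Train and test a surrogate on the analytic toy surface
t(Re, AR) = (1/Re)·exp(2(1−AR)) — the fixture that exercises the network
stack without the solver:

```python
from leukotransit.sweep_dataset import toy_surface_table
from leukotransit.bpnn import NetworkSpec, train_surrogate
from leukotransit.evaluation import r_squared

table = toy_surface_table(8, 8, seed=3)
spec = NetworkSpec(layer_sizes=[2, 5, 10, 1], goal=1e-10, max_epochs=400,
                   max_fail=25, seed=5)
model, report = train_surrogate(table, spec, seed=5)
test = table.df[table.df.split == "test"]
print(report.stop_reason, report.best_val_mse)
print(r_squared(model.predict(test[["Re", "AR"]]), test["transit_time"]))
print(model.predict([[0.13, 0.7]])[0])
```

prints

```
max-epochs 1.1586e-06
0.999999
14.014047
```

i.e. the 2-5-10-1 net reproduces the held-out surface to R² ≈ 0.999999
and predicts t(0.13, 0.7) = 14.014 against the analytic 14.016.

The full study pipeline runs the same stages on real simulations:

```bash
leukotransit sweep       --profile coarse-ci --out runs   # 36-case grid, resumable
leukotransit make-tables --profile coarse-ci --out runs
leukotransit train       --profile coarse-ci --target time --out runs
leukotransit evaluate    --profile coarse-ci --model runs/model_time_*.json --out runs
leukotransit surface     --model runs/model_time_*.json --out runs
```

`evaluate` scores the model against freshly simulated held-out scenarios
(ten off-grid (Re, AR) pairs for the time model, four for the
motion/force models); `surface` writes the dense predicted transit-time
map, whose slopes are negative along both axes — transit slows toward low
Re and tight pores.

## Layout

| Path | Contents |
| --- | --- |
| `src/leukotransit/analytic_flow.py` | Poiseuille relations, Re ↔ velocity conversion |
| `src/leukotransit/fsi_sim/` | immersed-boundary solver, membrane, transit driver |
| `src/leukotransit/sweep_dataset.py` | sweep grids, exclusions, supervised tables, splits |
| `src/leukotransit/bpnn.py` | networks, LM/GD trainers, node-count rule, serialization |
| `src/leukotransit/evaluation.py` | R² forms, held-out scoring, response surfaces |
| `src/leukotransit/config.py`, `pipeline.py`, `cli.py` | profiles, orchestration, CLI |
| `docs/methods.md` | models, numerics, design decisions, limitations |
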