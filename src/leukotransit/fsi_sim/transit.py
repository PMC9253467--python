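"""Full pore-transit integration and its recorded observables.

A run ends in one of three outcomes:

* ``transit`` — the trailing membrane point cleared the pore exit plane;
  the elapsed time is the transit time.
* ``impaction`` — the cell lodged in the pore: its centroid speed stayed
  below a small fraction of the cell-free mean velocity for a sustained
  window while the membrane overlapped the pore.  Impaction cases are
  excluded from surrogate training.
* ``timeout-error`` — neither criterion fired within ``max_sim_time``.

Along the way the trajectory is sampled at a fixed output interval:
downstream displacement, deformation extent R_max, downstream centroid
velocity V_y, and the fluid lift and drag tractions F_l, F_d integrated
over the membrane from the interpolated grid stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membrane import Membrane
from .params import SimulationParams
from .solver import FlowState, PoreFlowSolver, SolverError, build_domain

__all__ = ["Trajectory", "TransitResult", "run_transit", "compute_observables"]


@dataclass
class Trajectory:
    """Time series of one scenario's observables."""

    Re: float
    AR: float
    time: np.ndarray = field(default_factory=lambda: np.empty(0))
    displacement: np.ndarray = field(default_factory=lambda: np.empty(0))
    R_max: np.ndarray = field(default_factory=lambda: np.empty(0))
    V_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    F_l: np.ndarray = field(default_factory=lambda: np.empty(0))
    F_d: np.ndarray = field(default_factory=lambda: np.empty(0))
    area: np.ndarray = field(default_factory=lambda: np.empty(0))

    _FIELDS = ("time", "displacement", "R_max", "V_y", "F_l", "F_d", "area")

    def series(self, name: str) -> np.ndarray:
        if name not in self._FIELDS:
            raise KeyError(f"unknown trajectory series {name!r}; have {self._FIELDS}")
        return getattr(self, name)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TransitResult:
    """Outcome of one scenario run."""

    params: SimulationParams
    outcome: str  # transit | impaction | timeout-error
    transit_time: float  # nan unless outcome == transit
    trajectory: Trajectory
    n_steps: int = 0
    dt: float = 0.0
    max_dimensionless_divergence: float = 0.0
    area_drift: float = 0.0  # relative enclosed-area drift over the run
    min_spacing_ratio: float = float("nan")  # marker spacing / grid spacing
    max_spacing_ratio: float = float("nan")
    wall_time: float = 0.0

    @property
    def Re(self) -> float:
        return self.params.Re

    @property
    def AR(self) -> float:
        return self.params.AR


def compute_observables(solver: PoreFlowSolver, state: FlowState, membrane: Membrane):
    """Instantaneous (R_max, V_y, F_l, F_d) of the coupled state.

    ``R_max`` is the max marker distance from the membrane centroid (the
    radius, 5 um, for the undeformed cell).  ``V_y`` is the centroid
    velocity component along the flow axis, from the interpolated marker
    velocities.  The drag ``F_d`` is the axial component of the fluid
    traction integrated over a contour offset two grid cells outside the
    membrane — just past the regularized-delta support, where the stress
    field is one-sided; a closed-contour integral there equals the force
    on the enclosed cell up to the (negligible at these Reynolds numbers)
    inertia of the enclosed fluid shell.  The lift ``F_l`` is the
    transverse traction integrated over the upper half of the same contour
    (the net transverse force on the closed contour is ~0 by symmetry, so
    the half-contour integral is the informative quantity).  Force units
    are N/m (per unit depth of the 2D model).
    """
    vel = solver.interpolate_velocity(state, membrane.X)
    v_y = float(vel[:, 0].mean())
    r_max = membrane.r_max()

    sxx, syy, sxy = solver.stress_fields(state)
    pts = membrane.X + 2.0 * solver.h * membrane.outward_normals()
    d = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    n = np.column_stack([d[:, 1], -d[:, 0]])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    L = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    ds = 0.5 * (L + np.roll(L, 1))
    txx = solver.interpolate_center_field(sxx, pts)
    tyy = solver.interpolate_center_field(syy, pts)
    txy = solver.interpolate_center_field(sxy, pts)
    tr_x = txx * n[:, 0] + txy * n[:, 1]
    tr_y = txy * n[:, 0] + tyy * n[:, 1]
    f_d = float(np.sum(tr_x * ds))
    upper = pts[:, 1] > membrane.centroid[1]
    f_l = float(np.sum(tr_y[upper] * ds[upper]))
    return r_max, v_y, f_l, f_d


def run_transit(params: SimulationParams) -> TransitResult:
    """Integrate one scenario to its outcome.

    Deterministic for identical parameters: the solver contains no random
    number source (the seed field only labels downstream artifacts).
    """
    import time as _time

    t0 = _time.perf_counter()
    state, membrane, solver = build_domain(params)
    dt = solver.dt
    out_every = max(1, int(round(params.output_interval / dt)))
    stall_needed = max(1, int(np.ceil(params.stall_duration / dt)))

    x_start = membrane.centroid[0]
    rec = {k: [] for k in Trajectory._FIELDS}
    spacing_band = [np.inf, 0.0]

    def record():
        spacing_band[0] = min(spacing_band[0], membrane.min_spacing_ratio(solver.h))
        spacing_band[1] = max(spacing_band[1], membrane.max_spacing_ratio(solver.h))
        r_max, v_y, f_l, f_d = compute_observables(solver, state, membrane)
        rec["time"].append(state.t)
        rec["displacement"].append(membrane.centroid[0] - x_start)
        rec["R_max"].append(r_max)
        rec["V_y"].append(v_y)
        rec["F_l"].append(f_l)
        rec["F_d"].append(f_d)
        rec["area"].append(membrane.area)

    area0 = membrane.area
    record()

    outcome = "timeout-error"
    transit_time = float("nan")
    stall_count = 0
    max_div = 0.0
    n_steps = 0
    prev_cx = membrane.centroid[0]
    stall_floor = params.stall_velocity_fraction * params.mean_velocity

    while state.t < params.max_sim_time:
        solver.step(state, membrane)
        n_steps += 1

        if not np.all(np.isfinite(membrane.X)):
            raise SolverError(
                f"membrane positions became non-finite at t={state.t:.4e}s",
                state=state,
                membrane=membrane,
            )

        cx = membrane.centroid[0]
        vc = (cx - prev_cx) / dt
        prev_cx = cx

        trailing = membrane.X[:, 0].min()
        leading = membrane.X[:, 0].max()

        if trailing > params.pore_exit:
            outcome = "transit"
            transit_time = state.t
            record()
            break

        lodged = leading > params.pore_entrance and trailing < params.pore_exit
        if abs(vc) < stall_floor:
            stall_count += 1
        else:
            stall_count = 0
        if lodged and stall_count >= stall_needed:
            outcome = "impaction"
            record()
            break

        if n_steps % out_every == 0:
            record()
            max_div = max(max_div, solver.dimensionless_divergence(state))

        if n_steps % 16 == 0 and membrane.needs_resample(solver.h):
            membrane.resample(solver.h / params.markers_per_grid_cell)

    traj = Trajectory(
        Re=params.Re,
        AR=params.AR,
        **{k: np.asarray(v) for k, v in rec.items()},
    )
    return TransitResult(
        params=params,
        outcome=outcome,
        transit_time=transit_time,
        trajectory=traj,
        n_steps=n_steps,
        dt=dt,
        max_dimensionless_divergence=max_div,
        area_drift=abs(membrane.area - area0) / area0,
        min_spacing_ratio=spacing_band[0],
        max_spacing_ratio=spacing_band[1],
        wall_time=_time.perf_counter() - t0,
    )
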