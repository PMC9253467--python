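"""Staggered-grid incompressible flow solver with an immersed membrane.

Discretization summary
----------------------
* MAC staggering: u on vertical faces, v on horizontal faces, p at cell
  centers; uniform spacing ``h``.
* Time stepping: explicit advection, implicit (backward-Euler) viscosity,
  Chorin projection for incompressibility.  The Helmholtz and Poisson
  operators are assembled once per run and factorized (sparse LU), so each
  step costs three triangular solves on a few thousand unknowns.
* Driving: pressure Dirichlet values at the inlet/outlet ghost cells with a
  zero-gradient (fully developed) velocity closure; no-slip on the channel
  walls and on the rigid constriction, which is a pair of rounded-lip
  blocks masked out of the grid.
* Fluid-structure coupling: the classical immersed-boundary scheme —
  membrane elastic forces are spread to the grid with the 4-point
  regularized delta kernel, and grid velocities are interpolated back to
  advect the markers.

The solver is deliberately free of any random number source: identical
parameters give bit-identical trajectories on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .membrane import Membrane
from .params import ConfigError, SimulationParams

__all__ = ["FlowState", "PoreFlowSolver", "SolverError", "build_domain", "peskin_delta"]


class SolverError(RuntimeError):
    """Solver failure (divergence, CFL violation); carries a state snapshot."""

    def __init__(self, message: str, state=None, membrane=None):
        super().__init__(message)
        self.state = state
        self.membrane = membrane


@dataclass
class FlowState:
    """Velocity/pressure fields on the staggered grid at time ``t``."""

    u: np.ndarray  # (ny, nx+1)
    v: np.ndarray  # (ny+1, nx)
    p: np.ndarray  # (ny, nx)
    t: float = 0.0


def peskin_delta(r: np.ndarray) -> np.ndarray:
    """4-point regularized delta kernel phi(r), support |r| < 2.

    Satisfies the discrete moment conditions sum phi = 1 and sum r*phi = 0
    on any unit-spaced grid, which is what makes spreading/interpolation
    adjoint and momentum-conserving.
    """
    r = np.abs(r)
    out = np.zeros_like(r)
    m1 = r < 1.0
    m2 = (r >= 1.0) & (r < 2.0)
    out[m1] = (3.0 - 2.0 * r[m1] + np.sqrt(1.0 + 4.0 * r[m1] - 4.0 * r[m1] ** 2)) / 8.0
    out[m2] = (5.0 - 2.0 * r[m2] - np.sqrt(-7.0 + 12.0 * r[m2] - 4.0 * r[m2] ** 2)) / 8.0
    return out


def _block_sdf(xc, yc, x0, x1, y_gap, width, lip):
    """Signed distance to the two constriction blocks (negative inside).

    The blocks span ``[x0, x1]`` in x and reach from each wall to within
    ``y_gap/2`` of the channel axis; inner corners carry radius ``lip``.
    Implemented as a rounded-rectangle signed distance, with the boxes
    extended past the walls so only the lumen-side corners are rounded.
    """
    axis = width / 2.0
    dists = []
    for upper in (True, False):
        if upper:
            ylo, yhi = axis + y_gap / 2.0, width + 2 * lip
        else:
            ylo, yhi = -2 * lip, axis - y_gap / 2.0
        cx, cy = (x0 + x1) / 2.0, (ylo + yhi) / 2.0
        bx, by = (x1 - x0) / 2.0 - lip, (yhi - ylo) / 2.0 - lip
        qx = np.abs(xc - cx) - bx
        qy = np.abs(yc - cy) - by
        dist = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0)) + np.minimum(
            np.maximum(qx, qy), 0.0
        )
        dists.append(dist - lip)
    return np.minimum(dists[0], dists[1])


def _solid_fraction(sdf, h):
    """Smooth solid volume fraction from a signed distance (1.5-cell ramp).

    The sub-cell ramp is what makes the effective wall position — and hence
    every observable — vary continuously with the pore aspect ratio instead
    of jumping in grid-spacing increments.
    """
    return np.clip(0.5 - sdf / (1.5 * h), 0.0, 1.0)


def _brinkman_drag(frac, nu, h):
    """Carman-Kozeny-style drag coefficient (1/s) from the solid fraction.

    Diverges as the fraction approaches 1 (hard no-slip in fully solid
    cells) but offers only partial resistance in cut cells, so the
    effective wall position — and the pore conductance — interpolates
    smoothly between grid lines.
    """
    return (nu / h**2) * frac / ((1.0 - frac) ** 2 + 1e-3)


class PoreFlowSolver:
    """Immersed-boundary channel solver for one scenario."""

    # neighbor closure codes
    _ACTIVE, _WALL, _ZERO, _ZG = 0, 1, 2, 3

    def __init__(self, params: SimulationParams, with_pore: bool = True):
        self.params = params
        p = params
        self.h = p.grid_spacing
        self.nx = int(round(p.channel_length / self.h))
        self.ny = int(round(p.channel_width / self.h))
        if self.ny < 6:
            raise ConfigError("grid too coarse: fewer than 6 cells across the channel")
        self.mu = p.viscosity
        self.rho = p.density
        self.nu = self.mu / self.rho

        # Constriction geometry enters in two tiers: cells deep inside the
        # blocks are removed from the unknowns (hard no-slip), while cells
        # cut by the block surface keep a Brinkman volume penalty
        # chi/eps * u whose solid fraction chi follows the signed distance.
        # The penalty tier resolves the wall position to sub-cell accuracy,
        # so the pore gap varies continuously with AR.
        h = self.h
        xc = (np.arange(self.nx) + 0.5) * h
        yc = (np.arange(self.ny) + 0.5) * h
        xu = np.arange(self.nx + 1) * h
        xv = xc
        yu = yc
        yv = np.arange(self.ny + 1) * h

        if with_pore and p.pore_length > 0:
            geo = (p.pore_entrance, p.pore_exit, p.pore_width, p.channel_width, p.lip_radius)
            sdf_c = _block_sdf(*np.meshgrid(xc, yc), *geo)
            sdf_u = _block_sdf(*np.meshgrid(xu, yu), *geo)
            sdf_v = _block_sdf(*np.meshgrid(xv, yv), *geo)
            self.frac_c = _solid_fraction(sdf_c, h)
            self.frac_u = _solid_fraction(sdf_u, h)
            self.frac_v = _solid_fraction(sdf_v, h)
            if p.pore_width < 2.0 * h:
                raise ConfigError("pore gap resolved by fewer than 2 grid cells")
        else:
            self.frac_c = np.zeros((self.ny, self.nx))
            self.frac_u = np.zeros((self.ny, self.nx + 1))
            self.frac_v = np.zeros((self.ny + 1, self.nx))

        self.drag_u = _brinkman_drag(self.frac_u, self.nu, h)
        self.drag_v = _brinkman_drag(self.frac_v, self.nu, h)

        self.solid = self.frac_c >= 1.0  # deep solid, removed from unknowns
        fluid = ~self.solid
        # u faces active: both adjacent cells fluid; the open inlet/outlet
        # boundary faces are genuine unknowns whose momentum equation sees
        # the driving pressure through the ghost-cell gradient
        self.u_active = np.zeros((self.ny, self.nx + 1), dtype=bool)
        self.u_active[:, 1:-1] = fluid[:, :-1] & fluid[:, 1:]
        self.u_active[:, 0] = fluid[:, 0]
        self.u_active[:, -1] = fluid[:, -1]
        # v faces active: both adjacent cells fluid, walls excluded
        self.v_active = np.zeros((self.ny + 1, self.nx), dtype=bool)
        self.v_active[1:-1, :] = fluid[:-1, :] & fluid[1:, :]
        self.fluid = fluid

        # driving pressure
        self.p_in = p.pressure_drop
        self.p_out = 0.0
        self.u_mean = p.mean_velocity

        self.dt = p.dt if p.dt is not None else self._stable_dt()
        self._assemble()
        self._interp_cache = None

    # -- setup --------------------------------------------------------------

    def _stable_dt(self) -> float:
        p = self.params
        gap = p.pore_width if p.pore_length > 0 else p.channel_width
        u_peak = 1.5 * self.u_mean * (p.channel_width / gap) * 2.0  # safety margin
        dt_cfl = p.cfl * self.h / max(u_peak, 1e-12)
        ds = np.pi * p.cell_diameter / self._n_markers()
        kappa = (
            p.stretch_stiffness / ds
            + p.bending_stiffness / ds**3
            + p.area_stiffness * ds**2 / (np.pi * (p.cell_diameter / 2) ** 2)
        )
        dt_memb = p.membrane_dt_safety * self.mu / max(kappa, 1e-12)
        return min(dt_cfl, dt_memb)

    def _n_markers(self) -> int:
        p = self.params
        n = int(round(np.pi * p.cell_diameter / (self.h / p.markers_per_grid_cell)))
        return max(n, 16)

    def make_membrane(self) -> Membrane:
        p = self.params
        center = (p.initial_centroid_x, p.channel_width / 2.0)
        return Membrane(
            center,
            p.cell_diameter / 2.0,
            self._n_markers(),
            k_s=p.stretch_stiffness,
            k_b=p.bending_stiffness,
            k_a=p.area_stiffness,
        )

    def initial_state(self) -> FlowState:
        return FlowState(
            u=np.zeros((self.ny, self.nx + 1)),
            v=np.zeros((self.ny + 1, self.nx)),
            p=np.zeros((self.ny, self.nx)),
            t=0.0,
        )

    def _assemble(self) -> None:
        h2 = self.h**2
        c = self.nu / h2

        def helmholtz(active, closures, penalty):
            # Wall-type neighbors use a quadratic (second-order) no-slip
            # ghost through the half-cell-offset wall: ghost = -2*u0 + u1/3,
            # which is exact for parabolic profiles.  This adds 2c to the
            # diagonal and scales the opposite-side neighbor by 4/3.
            idx = -np.ones(active.shape, dtype=int)
            ids = np.flatnonzero(active.ravel())
            idx.ravel()[ids] = np.arange(len(ids))
            ny, nx = active.shape
            jj, ii = np.nonzero(active)
            n = len(jj)
            diag = np.full(n, 1.0 / self.dt + 4.0 * c)
            diag += penalty[jj, ii]  # Brinkman drag in cut cells
            dirs = ((0, -1), (0, 1), (-1, 0), (1, 0))
            codes, neigh = [], []
            for k, (dj, di) in enumerate(dirs):
                nj, ni = jj + dj, ii + di
                inside = (nj >= 0) & (nj < ny) & (ni >= 0) & (ni < nx)
                codes.append(closures(jj, ii, nj, ni, inside, k))
                neigh.append((nj, ni, inside))
            coeff = [np.full(n, -c) for _ in dirs]
            for ka, kb in ((0, 1), (1, 0), (2, 3), (3, 2)):
                wall = codes[ka] == self._WALL
                diag[wall] += 2.0 * c
                coeff[kb][wall & (codes[kb] == self._ACTIVE)] *= 4.0 / 3.0
                diag[codes[ka] == self._ZG] -= c
            rows, cols, vals = [], [], []
            for k in range(4):
                nj, ni, inside = neigh[k]
                m = inside & (codes[k] == self._ACTIVE)
                rows.append(idx[jj[m], ii[m]])
                cols.append(idx[nj[m], ni[m]])
                vals.append(coeff[k][m])
            rows.append(np.arange(n))
            cols.append(np.arange(n))
            vals.append(diag)
            A = sp.csc_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n),
            )
            return idx, splu(A)

        ua = self.u_active

        def u_closures(jj, ii, nj, ni, inside, k):
            code = np.full(len(jj), self._ZERO)
            horizontal = k < 2
            act = np.zeros(len(jj), dtype=bool)
            act[inside] = ua[nj[inside], ni[inside]]
            code[act] = self._ACTIVE
            rest = ~act
            if horizontal:
                # x-neighbor beyond the inlet/outlet: fully developed
                # (zero-gradient); deep-solid neighbors are Dirichlet-0 nodes
                code[rest & ~inside] = self._ZG
            else:
                # channel wall below/above the domain: quadratic no-slip
                # ghost; deep-solid neighbors stay Dirichlet-0 (the block
                # surface itself is enforced by the volume penalty)
                code[rest & ~inside] = self._WALL
            return code

        va = self.v_active

        def v_closures(jj, ii, nj, ni, inside, k):
            code = np.full(len(jj), self._ZERO)
            horizontal = k < 2
            act = np.zeros(len(jj), dtype=bool)
            act[inside] = va[nj[inside], ni[inside]]
            code[act] = self._ACTIVE
            rest = ~act
            if horizontal:
                code[rest & ~inside] = self._ZG  # inlet/outlet: fully developed
            # wall/deep-solid neighbors stay Dirichlet-0 nodes; block
            # surfaces are enforced by the volume penalty
            return code

        self.u_idx, self.u_lu = helmholtz(ua, u_closures, self.drag_u)
        self.v_idx, self.v_lu = helmholtz(va, v_closures, self.drag_v)

        # pressure Poisson on fluid cells
        fluid = self.fluid
        idx = -np.ones(fluid.shape, dtype=int)
        ids = np.flatnonzero(fluid.ravel())
        idx.ravel()[ids] = np.arange(len(ids))
        jj, ii = np.nonzero(fluid)
        n = len(jj)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for dj, di in ((0, -1), (0, 1), (-1, 0), (1, 0)):
            nj, ni = jj + dj, ii + di
            inside = (nj >= 0) & (nj < self.ny) & (ni >= 0) & (ni < self.nx)
            act = np.zeros(n, dtype=bool)
            act[inside] = fluid[nj[inside], ni[inside]]
            rows.append(idx[jj[act], ii[act]])
            cols.append(idx[nj[act], ni[act]])
            vals.append(np.full(act.sum(), 1.0 / h2))
            diag[act] -= 1.0 / h2
            if di != 0:
                # open (inlet/outlet) boundary: Dirichlet on the pressure
                # increment, which vanishes there (total pressure is pinned
                # to the driving values through the momentum equation)
                open_bnd = ~inside & ((ni < 0) | (ni >= self.nx))
                diag[open_bnd] -= 2.0 / h2
            # wall/solid neighbors: homogeneous Neumann, nothing to add
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        )
        self.p_idx = idx
        self.p_lu = splu(A)
        self._p_cells = (jj, ii)

    # -- IB transfer --------------------------------------------------------

    def _stencil(self, Xs, Ys, x0_off, y0_off):
        """4x4 delta-kernel stencil indices and weights for marker points.

        ``x0_off``/``y0_off`` are the staggering offsets (in cells) of the
        target grid: (0.0, 0.5) for u nodes, (0.5, 0.0) for v, (0.5, 0.5)
        for centers.
        """
        h = self.h
        gx = Xs / h - x0_off
        gy = Ys / h - y0_off
        i0 = np.floor(gx).astype(int) - 1
        j0 = np.floor(gy).astype(int) - 1
        di = np.arange(4)
        ii = i0[:, None] + di[None, :]
        jj = j0[:, None] + di[None, :]
        wx = peskin_delta(gx[:, None] - ii)
        wy = peskin_delta(gy[:, None] - jj)
        return ii, jj, wx, wy

    def spread_forces(self, membrane: Membrane, forces: np.ndarray):
        """Spread nodal membrane forces to u/v grids as force densities."""
        fu = np.zeros((self.ny, self.nx + 1))
        fv = np.zeros((self.ny + 1, self.nx))
        X, Y = membrane.X[:, 0], membrane.X[:, 1]
        inv_h2 = 1.0 / self.h**2

        ii, jj, wx, wy = self._stencil(X, Y, 0.0, 0.5)
        w = wx[:, :, None] * wy[:, None, :] * inv_h2
        np.add.at(
            fu,
            (np.clip(jj, 0, self.ny - 1)[:, None, :], np.clip(ii, 0, self.nx)[:, :, None]),
            forces[:, 0][:, None, None] * w,
        )
        ii, jj, wx, wy = self._stencil(X, Y, 0.5, 0.0)
        w = wx[:, :, None] * wy[:, None, :] * inv_h2
        np.add.at(
            fv,
            (np.clip(jj, 0, self.ny)[:, None, :], np.clip(ii, 0, self.nx - 1)[:, :, None]),
            forces[:, 1][:, None, None] * w,
        )
        return fu, fv

    def interpolate_velocity(self, state: FlowState, X: np.ndarray) -> np.ndarray:
        """Interpolate grid velocity to marker positions (same kernel)."""
        Xs, Ys = X[:, 0], X[:, 1]
        ii, jj, wx, wy = self._stencil(Xs, Ys, 0.0, 0.5)
        w = wx[:, :, None] * wy[:, None, :]
        U = np.sum(
            state.u[np.clip(jj, 0, self.ny - 1)[:, None, :], np.clip(ii, 0, self.nx)[:, :, None]]
            * w,
            axis=(1, 2),
        )
        ii, jj, wx, wy = self._stencil(Xs, Ys, 0.5, 0.0)
        w = wx[:, :, None] * wy[:, None, :]
        V = np.sum(
            state.v[np.clip(jj, 0, self.ny)[:, None, :], np.clip(ii, 0, self.nx - 1)[:, :, None]]
            * w,
            axis=(1, 2),
        )
        return np.column_stack([U, V])

    # -- dynamics -----------------------------------------------------------

    def _advection(self, state: FlowState):
        """Explicit convective terms (u.grad)u on the staggered grids."""
        h = self.h
        u, v = state.u, state.v
        Nu = np.zeros_like(u)
        Nv = np.zeros_like(v)
        # u nodes
        dudx = np.zeros_like(u)
        dudx[:, 1:-1] = (u[:, 2:] - u[:, :-2]) / (2 * h)
        dudy = np.zeros_like(u)
        dudy[1:-1, :] = (u[2:, :] - u[:-2, :]) / (2 * h)
        v_at_u = np.zeros_like(u)
        v_at_u[:, 1:-1] = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
        Nu = u * dudx + v_at_u * dudy
        # v nodes
        dvdx = np.zeros_like(v)
        dvdx[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2 * h)
        dvdy = np.zeros_like(v)
        dvdy[1:-1, :] = (v[2:, :] - v[:-2, :]) / (2 * h)
        u_at_v = np.zeros_like(v)
        u_at_v[1:-1, :] = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
        Nv = u_at_v * dvdx + v * dvdy
        return Nu, Nv

    def step(self, state: FlowState, membrane: Membrane | None):
        """Advance one immersed-boundary time step in place.

        Spreads membrane forces, advances momentum (implicit viscosity),
        projects onto divergence-free fields against the driving pressure
        boundary values, and advects the markers with the interpolated
        velocity.  Returns the max |divergence| (1/s) after projection.
        """
        dt, h = self.dt, self.h
        if membrane is not None:
            forces = membrane.elastic_force()
            fu, fv = self.spread_forces(membrane, forces)
        else:
            fu = fv = None

        umax = max(np.abs(state.u).max(), np.abs(state.v).max())
        if umax * dt / h > 1.0:
            raise SolverError(
                f"CFL violation at t={state.t:.4e}s: u_max={umax:.3e} m/s, "
                f"dt={dt:.3e}s, h={h:.3e}m",
                state=state,
                membrane=membrane,
            )

        Nu, Nv = self._advection(state)

        # explicit gradient of the current pressure (incremental form);
        # padded ghost columns pin the total pressure to the driving values
        P = state.p
        Pext = np.empty((self.ny, self.nx + 2))
        Pext[:, 1:-1] = P
        Pext[:, 0] = 2.0 * self.p_in - P[:, 0]
        Pext[:, -1] = 2.0 * self.p_out - P[:, -1]
        jj, ii = np.nonzero(self.u_active)
        gpu = np.zeros_like(state.u)
        gpu[jj, ii] = (Pext[jj, ii + 1] - Pext[jj, ii]) / h
        gpv = np.zeros_like(state.v)
        jv, iv = np.nonzero(self.v_active)
        gpv[jv, iv] = (P[jv, iv] - P[jv - 1, iv]) / h

        rhs_u = state.u / dt - Nu - gpu / self.rho
        rhs_v = state.v / dt - Nv - gpv / self.rho
        if fu is not None:
            rhs_u = rhs_u + fu / self.rho
            rhs_v = rhs_v + fv / self.rho

        u_star = np.zeros_like(state.u)
        u_star[jj, ii] = self.u_lu.solve(rhs_u[jj, ii])
        v_star = np.zeros_like(state.v)
        v_star[jv, iv] = self.v_lu.solve(rhs_v[jv, iv])

        # projection on the pressure increment (zero at open boundaries)
        pj, pi = self._p_cells
        div = (
            u_star[pj, pi + 1] - u_star[pj, pi] + v_star[pj + 1, pi] - v_star[pj, pi]
        ) / h
        rhs_p = (self.rho / dt) * div
        phi = self.p_lu.solve(rhs_p)
        if not np.all(np.isfinite(phi)):
            raise SolverError(f"pressure solve diverged at t={state.t:.4e}s", state, membrane)
        PHI = np.zeros((self.ny, self.nx))
        PHI[pj, pi] = phi
        PHIext = np.empty((self.ny, self.nx + 2))
        PHIext[:, 1:-1] = PHI
        PHIext[:, 0] = -PHI[:, 0]  # increment vanishes at the open boundaries
        PHIext[:, -1] = -PHI[:, -1]

        coef = dt / (self.rho * h)
        u_star[jj, ii] -= coef * (PHIext[jj, ii + 1] - PHIext[jj, ii])
        v_star[jv, iv] -= coef * (PHI[jv, iv] - PHI[jv - 1, iv])

        state.u = u_star
        state.v = v_star
        state.p = P + PHI
        state.t += dt

        if membrane is not None:
            U = self.interpolate_velocity(state, membrane.X)
            membrane.X = membrane.X + dt * U

        div_after = (
            state.u[pj, pi + 1] - state.u[pj, pi] + state.v[pj + 1, pi] - state.v[pj, pi]
        ) / h
        return float(np.abs(div_after).max())

    # -- diagnostics --------------------------------------------------------

    def max_divergence(self, state: FlowState) -> float:
        pj, pi = self._p_cells
        div = (
            state.u[pj, pi + 1] - state.u[pj, pi] + state.v[pj + 1, pi] - state.v[pj, pi]
        ) / self.h
        return float(np.abs(div).max())

    def dimensionless_divergence(self, state: FlowState) -> float:
        """Max |div u| scaled by h / u_mean (projection-quality measure)."""
        return self.max_divergence(state) * self.h / max(self.u_mean, 1e-300)

    def centerline_profile(self, state: FlowState, x: float) -> np.ndarray:
        """u(y) sampled at the column of u faces nearest ``x``."""
        i = int(round(x / self.h))
        return state.u[:, i].copy()

    def u_node_y(self) -> np.ndarray:
        """y coordinates of u nodes (cell-center heights)."""
        return (np.arange(self.ny) + 0.5) * self.h

    def stress_fields(self, state: FlowState):
        """Cell-centered Cauchy stress components (sxx, syy, sxy)."""
        h = self.h
        u, v, p = state.u, state.v, state.p
        dudx = (u[:, 1:] - u[:, :-1]) / h
        dvdy = (v[1:, :] - v[:-1, :]) / h
        uc = 0.5 * (u[:, 1:] + u[:, :-1])
        vc = 0.5 * (v[1:, :] + v[:-1, :])
        dudy = np.gradient(uc, h, axis=0)
        dvdx = np.gradient(vc, h, axis=1)
        sxx = -p + 2.0 * self.mu * dudx
        syy = -p + 2.0 * self.mu * dvdy
        sxy = self.mu * (dudy + dvdx)
        return sxx, syy, sxy

    def interpolate_center_field(self, field: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Delta-kernel interpolation of a cell-centered field to points."""
        Xs, Ys = X[:, 0], X[:, 1]
        ii, jj, wx, wy = self._stencil(Xs, Ys, 0.5, 0.5)
        w = wx[:, :, None] * wy[:, None, :]
        return np.sum(
            field[np.clip(jj, 0, self.ny - 1)[:, None, :], np.clip(ii, 0, self.nx - 1)[:, :, None]]
            * w,
            axis=(1, 2),
        )


def build_domain(params: SimulationParams):
    """Construct (FlowState, Membrane, solver) for a scenario.

    The channel holds an interior constriction of width ``AR * d``; the
    cell starts as a circle of diameter ``d`` on the channel axis at a
    standoff of ``standoff_diameters * d`` upstream of the pore entrance,
    in quiescent fluid.
    """
    solver = PoreFlowSolver(params)
    state = solver.initial_state()
    membrane = solver.make_membrane()
    top = membrane.X[:, 1].max()
    bot = membrane.X[:, 1].min()
    if top >= params.channel_width or bot <= 0:
        raise ConfigError("initial cell overlaps the channel walls")
    return state, membrane, solver
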