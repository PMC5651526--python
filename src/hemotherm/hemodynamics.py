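"""Reduced pulsatile blood-flow solver.

In the straight exchanger conduit the flow is taken as fully developed and
parallel, u = u(y, t) x_hat, so the convective term vanishes identically and
the axial momentum equation reduces to

    rho_b du/dt = g(t) + d/dy( mu_b(|du/dy|) du/dy )

(in the pipe surrogate the diffusion term carries the usual 1/r d/dr(r ...)
metric).  The axial pressure gradient g(t) = -dp/dx is not prescribed;
instead it is solved for at every instant so that the flow integral of u
matches the prescribed inlet waveform — the reduced embodiment of mass
conservation with a rigid, incompressible vessel.  Viscosity follows the
Carreau–Yasuda law of the constitutive module, evaluated at the single
nonzero strain component |du/dy|.

Time integration is BDF2 (backward Euler on the first step) with Picard
iteration on the shear-dependent viscosity; the scheme is implicit and
unconditionally stable across the admissible step range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import CarreauYasudaParams, cy_viscosity
from .geometry import FluidRegion, Grid

__all__ = ["VelocityField", "SolverError", "solve_steady_profile",
           "solve_unsteady_profile", "relax_profile"]

OUTPUT_DT = 0.01  # saved-output cadence, s


class SolverError(RuntimeError):
    """Raised when a nonlinear or time-stepping iteration fails."""


@dataclass
class VelocityField:
    """Axial velocity on the transverse fluid grid at saved times.

    ``u`` has shape (n_rows, n_times) over the lumen-span rows (fin-band
    rows are identically zero).  ``g`` is the flow-matching axial pressure
    gradient -dp/dx in Pa/m.  ``wall_shear`` holds the shear rate |du/dy|
    at each no-slip face (1/s).
    """

    fluid: FluidRegion
    times: np.ndarray
    u: np.ndarray
    g: np.ndarray
    wall_shear: np.ndarray
    period: float | None = None
    periodicity_residual: float = 0.0
    cycles_run: int = 1

    @property
    def n_times(self) -> int:
        return self.times.size

    def flow(self) -> np.ndarray:
        """Volumetric flow m^3/s at each saved time."""
        return self.fluid.row_area @ self.u

    def mean_profile(self) -> np.ndarray:
        return self.u.mean(axis=1)

    def interp(self, t: float) -> np.ndarray:
        """Profile at arbitrary time by periodic linear interpolation."""
        if self.period is None or self.n_times == 1:
            return self.u[:, 0]
        tp = np.mod(t, self.period)
        tt = np.concatenate([self.times, [self.times[0] + self.period]])
        uu = np.concatenate([self.u, self.u[:, :1]], axis=1)
        j = np.searchsorted(tt, tp, side="right") - 1
        j = min(max(j, 0), self.n_times - 1)
        w = (tp - tt[j]) / (tt[j + 1] - tt[j])
        return (1 - w) * uu[:, j] + w * uu[:, j + 1]


# --------------------------------------------------------------------------
# discrete operator


class _Momentum:
    """Finite-volume transverse diffusion operator over the open rows."""

    def __init__(self, fluid: FluidRegion, rho: float):
        self.fluid = fluid
        self.rho = rho
        self.open = np.nonzero(~fluid.band)[0]
        self.n = self.open.size
        self.pos = -np.ones(fluid.n, dtype=int)
        self.pos[self.open] = np.arange(self.n)
        yf, yc = fluid.yf, fluid.yc
        if fluid.mode == "axisymmetric_pipe":
            self.face_w = yf.copy()          # r at faces
            self.cell_w = yc * np.diff(yf)   # r dr
        else:
            self.face_w = np.ones(yf.size)
            self.cell_w = np.diff(yf)
        self.wall_faces = set(fluid.wall_faces.tolist())
        # classify faces: for each open row, its low face j and high face j+1
        self.area = fluid.row_area[self.open]

    def gradients(self, u_open: np.ndarray) -> np.ndarray:
        """du/dy at every face of the fluid span (walls use half cells)."""
        f = self.fluid
        grad = np.zeros(f.n + 1)
        u_full = np.zeros(f.n)
        u_full[self.open] = u_open
        for j in range(1, f.n):
            if self.pos[j - 1] >= 0 and self.pos[j] >= 0:
                grad[j] = (u_full[j] - u_full[j - 1]) / (f.yc[j] - f.yc[j - 1])
        for j in self.wall_faces:
            lo = j - 1 if j > 0 and self.pos[j - 1] >= 0 else None
            if lo is not None and (j == f.n or self.pos[j] < 0):
                grad[j] = (0.0 - u_full[lo]) / (f.yf[j] - f.yc[lo])
            elif j < f.n and self.pos[j] >= 0:
                grad[j] = (u_full[j] - 0.0) / (f.yc[j] - f.yf[j])
        return grad

    def matrix(self, mu_face: np.ndarray, beta_dt: float) -> sp.csc_matrix:
        """(rho*cell_w*beta_dt) I - L(mu); beta_dt = 0 gives steady -L."""
        f = self.fluid
        rows, cols, vals = [], [], []
        diag = self.rho * self.cell_w[self.open] * beta_dt
        add = np.zeros(self.n)
        for p, j in enumerate(self.open):
            for jf, nb in ((j, j - 1), (j + 1, j + 1)):
                w = self.face_w[jf] * mu_face[jf]
                if 0 <= nb < f.n and self.pos[nb] >= 0 and jf not in self.wall_faces:
                    c = w / abs(f.yc[nb] - f.yc[j])
                    add[p] += c
                    rows.append(p)
                    cols.append(self.pos[nb])
                    vals.append(-c)
                elif jf in self.wall_faces:
                    c = w / abs(f.yf[jf] - f.yc[j])
                    add[p] += c
                # else: symmetry/centreline face, zero stress
        A = sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        A = A.tocsc() + sp.diags(diag + add).tocsc()
        return A


def _mu_faces(op: _Momentum, u_open, params):
    grad = op.gradients(u_open)
    return cy_viscosity(np.abs(grad), params), grad


def solve_steady_profile(q_mean: float, grid: Grid,
                         params: CarreauYasudaParams,
                         tol: float = 1e-10, max_iter: int = 200
                         ) -> VelocityField:
    """Fully developed steady profile carrying flow ``q_mean``.

    The axial pressure gradient is eliminated analytically each Picard
    iteration (the problem is linear in g for frozen viscosity), so the flow
    constraint holds to round-off; the iteration is on the shear-dependent
    viscosity only.
    """
    if q_mean <= 0:
        raise ValueError("q_mean must be positive")
    f = grid.fluid
    op = _Momentum(f, params.rho_b)
    u = np.zeros(op.n)
    mu, _ = _mu_faces(op, u, params)
    for it in range(max_iter):
        A = op.matrix(mu, beta_dt=0.0)
        lu = spla.splu(A)
        u1 = lu.solve(op.cell_w[op.open].copy())
        g = q_mean / float(op.area @ u1)
        u_new = g * u1
        mu_new, _ = _mu_faces(op, u_new, params)
        delta = np.max(np.abs(mu_new - mu)) / np.max(mu)
        u, mu = u_new, mu_new
        if delta < tol:
            break
    else:
        raise SolverError(
            f"viscosity iteration did not converge (residual {delta:.2e})")
    _, grad = _mu_faces(op, u, params)
    u_full = np.zeros(f.n)
    u_full[op.open] = u
    wf = f.wall_faces
    return VelocityField(fluid=f, times=np.array([0.0]),
                         u=u_full[:, None], g=np.array([g]),
                         wall_shear=np.abs(grad[wf])[:, None])


def solve_unsteady_profile(waveform, grid: Grid, params: CarreauYasudaParams,
                           n_cycles: int = 20,
                           dt_bounds: tuple[float, float] = (1e-8, 1e-2),
                           u_tol: float = 1e-4,
                           picard_tol: float = 1e-8) -> VelocityField:
    """March the reduced momentum equation to a periodic state.

    Runs whole cardiac cycles from the steady profile at the mean flow,
    stopping when consecutive cycles agree to ``u_tol`` (m/s, max norm over
    saved snapshots) or ``n_cycles`` is exhausted.  Snapshots are saved at
    the fixed output cadence of 0.01 s; the returned field holds the final
    cycle with times as phases in [0, period).
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    lo, hi = dt_bounds
    if not (1e-8 - 1e-15 <= lo <= hi <= 1e-2 + 1e-15):
        raise ValueError("dt_bounds must lie within [1e-8, 1e-2] s")
    period = waveform.period
    n_save = int(round(period / OUTPUT_DT))
    n_sub = max(1, int(np.ceil(OUTPUT_DT / hi)))
    dt = OUTPUT_DT / n_sub
    if dt < lo:
        raise SolverError(f"required step {dt:.2e}s below dt_bounds floor")

    f = grid.fluid
    op = _Momentum(f, params.rho_b)
    steady = solve_steady_profile(float(np.mean(waveform.q)), grid, params)
    u = steady.u[op.open, 0].copy()
    u_prev = u.copy()
    rho_cw = params.rho_b * op.cell_w[op.open]

    save_u = np.zeros((f.n, n_save))
    save_g = np.zeros(n_save)
    save_ws = np.zeros((f.wall_faces.size, n_save))
    last_cycle = None
    residual = np.inf
    cycles = 0

    t = 0.0
    first_step = True
    for cyc in range(n_cycles):
        for s in range(n_save):
            for sub in range(n_sub):
                t_new = t + dt
                q_t = float(waveform(t_new))
                if first_step:
                    beta, hist = 1.0, rho_cw * u / dt
                else:
                    beta, hist = 1.5, rho_cw * (2.0 * u - 0.5 * u_prev) / dt
                u_guess = u.copy()
                for pic in range(30):
                    mu, _ = _mu_faces(op, u_guess, params)
                    A = op.matrix(mu, beta_dt=beta / dt)
                    lu = spla.splu(A)
                    u_h = lu.solve(hist)
                    u_p = lu.solve(op.cell_w[op.open].copy())
                    g = (q_t - float(op.area @ u_h)) / float(op.area @ u_p)
                    u_new = u_h + g * u_p
                    if np.max(np.abs(u_new - u_guess)) < picard_tol * max(
                            1e-12, np.max(np.abs(u_new))):
                        break
                    u_guess = u_new
                else:
                    raise SolverError(
                        f"Picard stall at t={t_new:.4f}s, dt={dt:.1e}s")
                u_prev, u = u, u_new
                first_step = False
                t = t_new
            mu, grad = _mu_faces(op, u, params)
            save_u[op.open, s] = u
            save_g[s] = g
            save_ws[:, s] = np.abs(grad[f.wall_faces])
        cycles = cyc + 1
        if last_cycle is not None:
            residual = float(np.max(np.abs(save_u - last_cycle)))
            if residual < u_tol:
                break
        last_cycle = save_u.copy()

    times = np.arange(n_save) * OUTPUT_DT
    # roll so that times are phases with save index s holding t=(s+1)*dt_out
    return VelocityField(fluid=f, times=times,
                         u=np.roll(save_u, 1, axis=1),
                         g=np.roll(save_g, 1),
                         wall_shear=np.roll(save_ws, 1, axis=1),
                         period=period, periodicity_residual=residual,
                         cycles_run=cycles)


def relax_profile(u0: np.ndarray, grid: Grid, params: CarreauYasudaParams,
                  t_end: float, dt: float = 1e-3) -> np.ndarray:
    """Integrate the profile with zero pressure gradient (free decay).

    Returns the kinetic-energy history (J per unit length), one entry per
    step, used to verify that viscous dissipation is monotone.
    """
    f = grid.fluid
    op = _Momentum(f, params.rho_b)
    u = np.asarray(u0, dtype=float)[op.open].copy()
    rho_cw = params.rho_b * op.cell_w[op.open]
    ke = []
    steps = int(round(t_end / dt))
    for _ in range(steps):
        mu, _ = _mu_faces(op, u, params)
        A = op.matrix(mu, beta_dt=1.0 / dt)
        u = spla.spsolve(A.tocsc(), rho_cw * u / dt)
        ke.append(0.5 * params.rho_b * float(op.area @ (u * u)))
    return np.asarray(ke)
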