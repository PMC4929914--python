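"""Fractional-step incompressible Navier-Stokes on a staggered grid.

Explicit second-order scheme: Adams-Bashforth 2 for convection and
diffusion (first step forward Euler), immersed-boundary direct forcing on
the provisional velocity, then a pressure projection enforcing the discrete
divergence constraint via the multigrid Poisson solver.

Velocity components live on face centers (u on x-faces, v on y-faces, w on
z-faces); the stored pressure is kinematic (p/rho).  Boundary conditions:
uniform inflow at the upstream x face, convective outflow downstream,
free-slip on lateral faces — or fully periodic (verification mode, e.g. the
Taylor-Green vortex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import StructuredGrid
from .poisson import PoissonSolver

__all__ = ["SolverSettings", "FlowState", "IBNSolver", "taylor_green_fields"]


@dataclass
class SolverSettings:
    """Time step, fluid properties and iteration controls.

    ``poisson_tol`` is the per-step relative residual reduction for the
    pressure solve (warm-started from the previous step); ``cfl_limit``
    bounds max|u| dt / min(dx).
    """

    dt: float
    nu: float
    rho: float = 1.2
    U_inflow: float = 0.0
    poisson_tol: float = 1e-5
    max_vcycles: int = 60
    cfl_limit: float = 1.0


@dataclass
class FlowState:
    """Staggered velocity and cell-centered kinematic pressure."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    time: float = 0.0
    step: int = 0
    solid: np.ndarray | None = None       # cell-centred solid mask
    fresh: np.ndarray | None = None       # cells newly uncovered this step

    def kinetic_energy(self, grid: StructuredGrid) -> float:
        """Volume-integrated kinetic energy per unit density."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return float(0.5 * ((uc ** 2 + vc ** 2 + wc ** 2)
                            * grid.cell_volumes()).sum())


def _tangential_terms(Nn, Tc, d1, g1, bc1, half_lo):
    """Convective and diffusive y-like terms for one velocity component.

    Nn: component values at its updated faces, tangential axis at position
    1, shape (m, n1, n2).  Tc: the tangential velocity averaged onto the
    corner line, shape (m, n1+1, n2) (reduced to (m, n1, n2) for periodic).
    Returns (d(Tc*N)/dy, d2N/dy2-flux-difference) arrays of shape Nn.
    """
    n1 = Nn.shape[1]
    d1b = d1[None, :, None]
    if bc1 == "periodic":
        h = d1[0]
        N_lo = np.roll(Nn, 1, axis=1)
        H = Tc * 0.5 * (N_lo + Nn)
        conv = (np.roll(H, -1, axis=1) - H) / h
        G = (Nn - N_lo) / h
        visc = (np.roll(G, -1, axis=1) - G) / h
        return conv, visc
    lo, hi = bc1
    H = np.zeros((Nn.shape[0], n1 + 1, Nn.shape[2]))
    G = np.zeros_like(H)
    H[:, 1:-1] = Tc[:, 1:-1] * 0.5 * (Nn[:, 1:] + Nn[:, :-1])
    G[:, 1:-1] = (Nn[:, 1:] - Nn[:, :-1]) / g1[None, :, None]
    if lo == "inflow":
        # tangential velocity is zero on the uniform inflow plane
        G[:, 0] = Nn[:, 0] / half_lo
    elif lo == "outflow":
        H[:, 0] = Tc[:, 0] * Nn[:, 0]
    # 'freeslip': both fluxes vanish (no penetration, zero shear)
    if hi == "outflow":
        H[:, -1] = Tc[:, -1] * Nn[:, -1]
    elif hi == "inflow":
        G[:, -1] = -Nn[:, -1] / half_lo
    conv = (H[:, 1:] - H[:, :-1]) / d1b
    visc = (G[:, 1:] - G[:, :-1]) / d1b
    return conv, visc


def _component_rhs(N, T1, T2, f0, f1, f2, bc0, bc1, bc2, nu):
    """RHS (-convection + viscous) for one velocity component.

    ``N`` carries faces along axis 0; ``T1``/``T2`` are the tangential
    components with faces along axes 1 / 2.  Boundary faces of N along a
    non-periodic axis 0 are left untouched (rhs 0 there).
    """
    d0, d1, d2 = np.diff(f0), np.diff(f1), np.diff(f2)
    periodic0 = bc0 == "periodic"
    rhs = np.zeros_like(N)

    if periodic0:
        h0 = d0[0]
        Nw = N[:-1]
        ucc = 0.5 * (Nw + np.roll(Nw, -1, axis=0))
        F = ucc * ucc
        conv0 = (F - np.roll(F, 1, axis=0)) / h0
        dN = (np.roll(Nw, -1, axis=0) - Nw) / h0
        visc0 = (dN - np.roll(dN, 1, axis=0)) / h0
        Nn = Nw
        Tc1 = 0.5 * (np.roll(T1, 1, axis=0) + T1)
        Tc2 = 0.5 * (np.roll(T2, 1, axis=0) + T2)
    else:
        c0 = f0[:-1] + 0.5 * d0
        g0 = np.diff(c0)
        ucc = 0.5 * (N[:-1] + N[1:])
        F = ucc * ucc
        conv0 = (F[1:] - F[:-1]) / g0[:, None, None]
        dN = (N[1:] - N[:-1]) / d0[:, None, None]
        visc0 = (dN[1:] - dN[:-1]) / g0[:, None, None]
        Nn = N[1:-1]
        Tc1 = 0.5 * (T1[:-1] + T1[1:])
        Tc2 = 0.5 * (T2[:-1] + T2[1:])

    g1 = np.diff(f1[:-1] + 0.5 * d1)
    g2 = np.diff(f2[:-1] + 0.5 * d2)
    if bc1 == "periodic":
        Tc1 = Tc1[:, :-1]
    conv1, visc1 = _tangential_terms(Nn, Tc1, d1, g1, bc1, 0.5 * d1[0])

    NnT = Nn.transpose(0, 2, 1)
    Tc2T = Tc2.transpose(0, 2, 1)
    if bc2 == "periodic":
        Tc2T = Tc2T[:, :-1]
    conv2, visc2 = _tangential_terms(NnT, Tc2T, d2, g2, bc2, 0.5 * d2[0])
    conv2 = conv2.transpose(0, 2, 1)
    visc2 = visc2.transpose(0, 2, 1)

    total = -(conv0 + conv1 + conv2) + nu * (visc0 + visc1 + visc2)
    if periodic0:
        rhs[:-1] = total
        rhs[-1] = rhs[0]
    else:
        rhs[1:-1] = total
    return rhs


class IBNSolver:
    """Immersed-boundary Navier-Stokes time stepper bound to one grid."""

    def __init__(self, grid: StructuredGrid, settings: SolverSettings):
        self.grid = grid
        self.settings = settings
        self.poisson = PoissonSolver(grid, tolerance=settings.poisson_tol,
                                     max_cycles=settings.max_vcycles)
        nx, ny, nz = grid.shape
        self.state = FlowState(
            u=np.zeros((nx + 1, ny, nz)),
            v=np.zeros((nx, ny + 1, nz)),
            w=np.zeros((nx, ny, nz + 1)),
            p=np.zeros((nx, ny, nz)),
        )
        self._prev_rhs: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._forcing = None  # callable(state, time) applying IB conditions
        per = grid.periodic
        if any(per) and not all(per):
            raise ValueError("periodicity must be all-or-none")
        self.periodic = all(per)

    # -- initialization -----------------------------------------------------
    def initialize_uniform(self, U: float) -> None:
        self.state.u[:] = U
        self.state.v[:] = 0.0
        self.state.w[:] = 0.0
        self.state.p[:] = 0.0
        self._prev_rhs = None
        self.apply_velocity_bcs(self.state)

    def initialize_fields(self, u, v, w) -> None:
        self.state.u[:] = u
        self.state.v[:] = v
        self.state.w[:] = w
        self._prev_rhs = None

    def set_forcing(self, fn) -> None:
        """Register an immersed-boundary forcing callback.

        The callback receives (state, grid, time) after the provisional
        velocity update and imposes surface velocities in place.
        """
        self._forcing = fn

    # -- boundary conditions ------------------------------------------------
    def apply_velocity_bcs(self, st: FlowState) -> None:
        if self.periodic:
            st.u[-1] = st.u[0]
            st.v[:, -1] = st.v[:, 0]
            st.w[:, :, -1] = st.w[:, :, 0]
            return
        U = self.settings.U_inflow
        st.u[0] = U                     # uniform inflow
        st.v[:, 0] = 0.0                # free-slip lateral: no penetration
        st.v[:, -1] = 0.0
        st.w[:, :, 0] = 0.0
        st.w[:, :, -1] = 0.0

    def _convective_outflow(self, st: FlowState) -> None:
        """Advect the outflow-face u with the mean exit speed."""
        dxl = self.grid.dx[-1]
        Uc = max(float(st.u[-1].mean()), 0.1 * self.settings.U_inflow)
        st.u[-1] -= self.settings.dt * Uc / dxl * (st.u[-1] - st.u[-2])

    def _balance_mass(self, st: FlowState) -> None:
        """Uniformly correct the outflow face so net boundary flux is zero."""
        g = self.grid
        dAx = g.dy[:, None] * g.dz[None, :]
        influx = float((st.u[0] * dAx).sum())
        outflux = float((st.u[-1] * dAx).sum())
        # lateral faces are impermeable (v=w=0), so balance in/out only
        st.u[-1] += (influx - outflux) / dAx.sum()

    # -- operators ----------------------------------------------------------
    def divergence(self, st: FlowState) -> np.ndarray:
        g = self.grid
        return ((st.u[1:] - st.u[:-1]) / g.dx[:, None, None]
                + (st.v[:, 1:] - st.v[:, :-1]) / g.dy[None, :, None]
                + (st.w[:, :, 1:] - st.w[:, :, :-1]) / g.dz[None, None, :])

    def _rhs_all(self, st: FlowState):
        g = self.grid
        nu = self.settings.nu
        if self.periodic:
            bcx = bcy = bcz = "periodic"
        else:
            bcx = ("inflow", "outflow")
            bcy = bcz = ("freeslip", "freeslip")
        ru = _component_rhs(st.u, st.v, st.w, g.xf, g.yf, g.zf,
                            bcx, bcy, bcz, nu)
        rv = _component_rhs(st.v.transpose(1, 2, 0),
                            st.w.transpose(1, 2, 0),
                            st.u.transpose(1, 2, 0),
                            g.yf, g.zf, g.xf, bcy, bcz, bcx, nu)
        rw = _component_rhs(st.w.transpose(2, 0, 1),
                            st.u.transpose(2, 0, 1),
                            st.v.transpose(2, 0, 1),
                            g.zf, g.xf, g.yf, bcz, bcx, bcy, nu)
        return ru, rv.transpose(2, 0, 1), rw.transpose(1, 2, 0)

    def _project(self, st: FlowState) -> int:
        dt = self.settings.dt
        rhs = self.divergence(st) / dt
        if st.solid is not None:
            rhs[st.solid] = 0.0
        result = self.poisson.solve(rhs, p0=st.p if st.step else None,
                                    tolerance=self.settings.poisson_tol)
        phi = result.p
        g = self.grid
        if self.periodic:
            h = g.dx[0]
            st.u[:-1] -= dt * (phi - np.roll(phi, 1, axis=0)) / h
            st.u[-1] = st.u[0]
            h = g.dy[0]
            st.v[:, :-1] -= dt * (phi - np.roll(phi, 1, axis=1)) / h
            st.v[:, -1] = st.v[:, 0]
            h = g.dz[0]
            st.w[:, :, :-1] -= dt * (phi - np.roll(phi, 1, axis=2)) / h
            st.w[:, :, -1] = st.w[:, :, 0]
        else:
            gx = np.diff(g.xc)[:, None, None]
            gy = np.diff(g.yc)[None, :, None]
            gz = np.diff(g.zc)[None, None, :]
            st.u[1:-1] -= dt * (phi[1:] - phi[:-1]) / gx
            st.v[:, 1:-1] -= dt * (phi[:, 1:] - phi[:, :-1]) / gy
            st.w[:, :, 1:-1] -= dt * (phi[:, :, 1:] - phi[:, :, :-1]) / gz
        st.p = phi
        return result.iterations

    def cfl(self) -> float:
        st = self.state
        vmax = max(np.abs(st.u).max(), np.abs(st.v).max(),
                   np.abs(st.w).max(), 1e-30)
        return vmax * self.settings.dt / self.grid.min_spacing

    # -- time stepping ------------------------------------------------------
    def step(self) -> dict:
        """Advance one time step; returns step diagnostics."""
        st = self.state
        dt = self.settings.dt
        if self.cfl() > self.settings.cfl_limit + 1e-12:
            raise RuntimeError(
                f"CFL {self.cfl():.3f} exceeds limit "
                f"{self.settings.cfl_limit} at t={st.time:.6g}")
        rhs = self._rhs_all(st)
        if self._prev_rhs is None:
            incr = [dt * r for r in rhs]
        else:
            incr = [dt * (1.5 * r - 0.5 * rp)
                    for r, rp in zip(rhs, self._prev_rhs)]
        st.u += incr[0]
        st.v += incr[1]
        st.w += incr[2]
        self._prev_rhs = rhs

        if not self.periodic:
            self._convective_outflow(st)
        self.apply_velocity_bcs(st)
        if self._forcing is not None:
            self._forcing(st, self.grid, st.time + dt)
        if not self.periodic:
            self._balance_mass(st)
        iters = self._project(st)
        self.apply_velocity_bcs(st)
        st.time += dt
        st.step += 1
        div = self.divergence(st)
        if st.solid is not None:
            div = np.where(st.solid, 0.0, div)
        return {
            "time": st.time,
            "poisson_iterations": iters,
            "max_divergence": float(np.abs(div).max()),
            "cfl": self.cfl(),
        }


def taylor_green_fields(grid: StructuredGrid, nu: float, t: float = 0.0):
    """Analytic 2-D Taylor-Green vortex (z-invariant) on face centers.

    u =  sin(x) cos(y) exp(-2 nu t),
    v = -cos(x) sin(y) exp(-2 nu t),  w = 0,
    an exact Navier-Stokes solution on the 2*pi-periodic box; kinetic
    energy decays as exp(-4 nu t).
    """
    decay = np.exp(-2.0 * nu * t)
    xc, yc = grid.xc, grid.yc
    xf, yf = grid.xf[:-1], grid.yf[:-1]
    nx, ny, nz = grid.shape
    u = np.zeros((nx + 1, ny, nz))
    v = np.zeros((nx, ny + 1, nz))
    w = np.zeros((nx, ny, nz + 1))
    u[:-1] = (np.sin(xf)[:, None] * np.cos(yc)[None, :])[:, :, None] * decay
    u[-1] = u[0]
    v[:, :-1] = (-np.cos(xc)[:, None] * np.sin(yf)[None, :])[:, :, None] * decay
    v[:, -1] = v[:, 0]
    return u, v, w
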