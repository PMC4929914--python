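"""Geometric multigrid solver for the pressure Poisson equation.

Cell-centered 7-point discretization of div(grad p) = rhs on the stretched
Cartesian grid, with homogeneous Neumann or periodic closures per axis
(the combinations arising from the projection step).  V(2,2) cycles with
red-black Gauss-Seidel smoothing; coarse operators are re-discretized on
coarsened face arrays (every axis with an even cell count is coarsened by
2, others are kept — semi-coarsening — so arbitrary cell counts work).

The all-Neumann/periodic problem is singular: the right-hand side is
projected onto the compatible subspace (volume-weighted mean removed) and
the solution gauge is fixed to zero mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import StructuredGrid

__all__ = ["PoissonSolver", "PoissonResult", "IncompatibleRhsError",
           "SolverDivergenceError"]


class IncompatibleRhsError(ValueError):
    """Right-hand side integral exceeds the allowed compatibility defect."""


class SolverDivergenceError(RuntimeError):
    """The iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class PoissonResult:
    p: np.ndarray
    iterations: int
    residual: float
    residual_history: list[float]
    compatibility_correction: float


from . import kernels


class _Level:
    """One multigrid level: per-axis metric coefficient arrays."""

    def __init__(self, faces: list[np.ndarray], periodic: tuple[bool, ...]):
        self.faces = faces
        self.periodic = periodic
        self.shape = tuple(f.size - 1 for f in faces)
        self.d = [np.diff(f) for f in faces]            # cell sizes
        self.vol = (self.d[0][:, None, None] * self.d[1][None, :, None]
                    * self.d[2][None, None, :])
        # lo/hi neighbour coefficients per axis, shaped for broadcasting;
        # entry i couples cell i with i-1 (lo) / i+1 (hi), zero at closed ends
        self.clo, self.chi = [], []
        for ax in range(3):
            d = self.d[ax]
            n = d.size
            centers = faces[ax][:-1] + 0.5 * d
            lo = np.zeros(n)
            hi = np.zeros(n)
            if n > 1:
                gap = np.diff(centers)
                lo[1:] = 1.0 / (d[1:] * gap)
                hi[:-1] = 1.0 / (d[:-1] * gap)
            if periodic[ax]:
                wrap = 0.5 * (d[0] + d[-1])
                lo[0] = 1.0 / (d[0] * wrap)
                hi[-1] = 1.0 / (d[-1] * wrap)
            shape = [1, 1, 1]
            shape[ax] = n
            self.clo.append(lo.reshape(shape))
            self.chi.append(hi.reshape(shape))
        self.diag = -sum(np.broadcast_to(self.clo[a] + self.chi[a], self.shape)
                         for a in range(3))
        self.diag = np.ascontiguousarray(self.diag)
        # flat per-axis coefficient vectors for the compiled kernels
        self.flat_lo = [np.ascontiguousarray(c.ravel()) for c in self.clo]
        self.flat_hi = [np.ascontiguousarray(c.ravel()) for c in self.chi]
        # red-black checkerboard
        idx = np.add.outer(np.add.outer(np.arange(self.shape[0]),
                                        np.arange(self.shape[1])),
                           np.arange(self.shape[2]))
        self.red = (idx % 2) == 0

    def _neighbor_sum(self, p: np.ndarray) -> np.ndarray:
        """Sum of off-diagonal couplings applied to p."""
        s = np.zeros_like(p)
        for ax in range(3):
            lo_nb = np.roll(p, 1, axis=ax)
            hi_nb = np.roll(p, -1, axis=ax)
            # roll wraps; for non-periodic axes the end coefficients are 0,
            # so the wrapped values never contribute
            s += self.clo[ax] * lo_nb + self.chi[ax] * hi_nb
        return s

    def _kernel_args(self):
        return (self.flat_lo[0], self.flat_hi[0], self.flat_lo[1],
                self.flat_hi[1], self.flat_lo[2], self.flat_hi[2], self.diag)

    def apply(self, p: np.ndarray) -> np.ndarray:
        out = np.empty_like(p)
        if all(self.periodic):
            kernels.apply_operator_periodic(p, *self._kernel_args(), out)
        elif any(self.periodic):
            return self._neighbor_sum(p) + self.diag * p
        else:
            kernels.apply_operator(p, *self._kernel_args(), out)
        return out

    def residual(self, p: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        return rhs - self.apply(p)

    def smooth(self, p: np.ndarray, rhs: np.ndarray, sweeps: int) -> None:
        """Point red-black Gauss-Seidel (periodic axes present) or
        alternating-direction zebra line relaxation (stretched grids, where
        point smoothing stalls on high-aspect outer cells)."""
        args = self._kernel_args()
        if all(self.periodic):
            for _ in range(sweeps):
                kernels.rbgs_sweep_periodic(p, rhs, *args, 0)
                kernels.rbgs_sweep_periodic(p, rhs, *args, 1)
            return
        if any(self.periodic):
            for _ in range(sweeps):
                for mask in (self.red, ~self.red):
                    s = self._neighbor_sum(p)
                    p[mask] = ((rhs - s) / self.diag)[mask]
            return
        for _ in range(sweeps):
            for ax in range(3):
                if self.shape[ax] > 1:
                    kernels.zebra_sweep(p, rhs, *args, ax, 0)
                    kernels.zebra_sweep(p, rhs, *args, ax, 1)
                else:
                    kernels.rbgs_sweep(p, rhs, *args, 0)
                    kernels.rbgs_sweep(p, rhs, *args, 1)

    def coarsen(self) -> "_Level | None":
        can = [self.shape[a] % 2 == 0 and self.shape[a] >= 4 for a in range(3)]
        if not any(can):
            return None
        faces = [self.faces[a][::2] if can[a] else self.faces[a]
                 for a in range(3)]
        return _Level(faces, self.periodic)


def _restrict(fine: _Level, coarse: _Level, r: np.ndarray) -> np.ndarray:
    """Volume-weighted average of fine residuals into coarse cells."""
    w = r * fine.vol
    for ax in range(3):
        if coarse.shape[ax] != fine.shape[ax]:
            shape = list(w.shape)
            shape[ax] //= 2
            shape.insert(ax + 1, 2)
            w = w.reshape(shape).sum(axis=ax + 1)
    return w / coarse.vol


def _prolong(fine: _Level, coarse: _Level, e: np.ndarray) -> np.ndarray:
    """(Tri)linear interpolation of the coarse correction.

    Along each coarsened axis the two fine children get 3/4 of their parent
    plus 1/4 of the neighbouring parent (clamped at closed ends, wrapped for
    periodic axes) -- the standard cell-centered linear stencil.
    """
    for ax in range(3):
        if coarse.shape[ax] == fine.shape[ax]:
            continue
        lo_nb = np.roll(e, 1, axis=ax)
        hi_nb = np.roll(e, -1, axis=ax)
        if not fine.periodic[ax]:
            sl_first = [slice(None)] * e.ndim
            sl_first[ax] = slice(0, 1)
            sl_last = [slice(None)] * e.ndim
            sl_last[ax] = slice(-1, None)
            lo_nb[tuple(sl_first)] = e[tuple(sl_first)]
            hi_nb[tuple(sl_last)] = e[tuple(sl_last)]
        lo_child = 0.75 * e + 0.25 * lo_nb
        hi_child = 0.75 * e + 0.25 * hi_nb
        stacked = np.stack([lo_child, hi_child], axis=ax + 1)
        shape = list(e.shape)
        shape[ax] *= 2
        e = stacked.reshape(shape)
    return e


class PoissonSolver:
    """Multigrid Poisson solver bound to one grid."""

    def __init__(self, grid: StructuredGrid, tolerance: float = 1e-8,
                 max_cycles: int = 60, pre_sweeps: int = 2,
                 post_sweeps: int = 2, coarse_sweeps: int = 60,
                 compat_threshold: float = 1e-3):
        self.grid = grid
        self.tolerance = tolerance
        self.max_cycles = max_cycles
        self.pre_sweeps = pre_sweeps
        self.post_sweeps = post_sweeps
        self.coarse_sweeps = coarse_sweeps
        self.compat_threshold = compat_threshold
        self.levels: list[_Level] = [
            _Level([grid.xf, grid.yf, grid.zf], grid.periodic)]
        while self.levels[-1].shape != () and max(self.levels[-1].shape) > 4:
            nxt = self.levels[-1].coarsen()
            if nxt is None:
                break
            self.levels.append(nxt)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def _vcycle(self, li: int, p: np.ndarray, rhs: np.ndarray) -> None:
        level = self.levels[li]
        if li == len(self.levels) - 1:
            level.smooth(p, rhs, self.coarse_sweeps)
            return
        level.smooth(p, rhs, self.pre_sweeps)
        r = level.residual(p, rhs)
        coarse = self.levels[li + 1]
        rc = _restrict(level, coarse, r)
        ec = np.zeros(coarse.shape)
        self._vcycle(li + 1, ec, rc)
        p += _prolong(level, coarse, ec)
        level.smooth(p, rhs, self.post_sweeps)

    def solve(self, rhs: np.ndarray, p0: np.ndarray | None = None,
              tolerance: float | None = None) -> PoissonResult:
        """Solve div(grad p) = rhs to the relative residual tolerance.

        The rhs volume integral (which must vanish for the singular
        Neumann/periodic problem) is removed; a defect larger than
        ``compat_threshold`` (relative) raises IncompatibleRhsError.
        """
        tol = self.tolerance if tolerance is None else tolerance
        level = self.levels[0]
        rhs = np.asarray(rhs, dtype=float)
        if rhs.shape != level.shape:
            raise ValueError(f"rhs shape {rhs.shape} != grid shape {level.shape}")
        vol = level.vol
        total = float(vol.sum())
        mean = float((rhs * vol).sum() / total)
        scale = float(np.sqrt((rhs * rhs * vol).sum() / total))
        if scale > 0 and abs(mean) > self.compat_threshold * scale:
            raise IncompatibleRhsError(
                f"rhs mean {mean:.3e} exceeds compatibility threshold "
                f"({self.compat_threshold:.1e} * rms {scale:.3e})")
        rhs = rhs - mean
        p = np.zeros(level.shape) if p0 is None else np.array(p0, dtype=float)

        norm0 = float(np.sqrt(((rhs * rhs) * vol).sum() / total))
        if norm0 == 0.0:
            return PoissonResult(p * 0.0, 0, 0.0, [0.0], mean)
        history: list[float] = []
        for it in range(1, self.max_cycles + 1):
            self._vcycle(0, p, rhs)
            r = level.residual(p, rhs)
            res = float(np.sqrt(((r * r) * vol).sum() / total)) / norm0
            history.append(res)
            if res <= tol:
                p -= float((p * vol).sum() / total)  # zero-mean gauge
                return PoissonResult(p, it, res, history, mean)
        raise SolverDivergenceError(
            f"multigrid failed to converge to {tol:.1e} in "
            f"{self.max_cycles} cycles (residual {history[-1]:.3e})",
            history)
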