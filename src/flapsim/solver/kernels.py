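"""Numba-compiled stencil kernels for the multigrid Poisson solver.

The 7-point operator, red-black point relaxation and zebra line relaxation
are tight triple loops; compiling them removes the interpreter overhead
that dominates pure-numpy sweeps on grids of a few hundred thousand cells.
Coefficient conventions match :mod:`flapsim.solver.poisson`: per-axis lo/hi
coupling arrays with zeros at closed ends (so out-of-range neighbours are
simply skipped), and a full 3-D diagonal.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["apply_operator", "apply_operator_periodic", "rbgs_sweep",
           "rbgs_sweep_periodic", "zebra_sweep"]


@njit(cache=True)
def apply_operator_periodic(p, clo_x, chi_x, clo_y, chi_y, clo_z, chi_z,
                            diag, out):
    nx, ny, nz = p.shape
    for i in range(nx):
        im, ip = (i - 1) % nx, (i + 1) % nx
        for j in range(ny):
            jm, jp = (j - 1) % ny, (j + 1) % ny
            for k in range(nz):
                km, kp = (k - 1) % nz, (k + 1) % nz
                out[i, j, k] = (diag[i, j, k] * p[i, j, k]
                                + clo_x[i] * p[im, j, k]
                                + chi_x[i] * p[ip, j, k]
                                + clo_y[j] * p[i, jm, k]
                                + chi_y[j] * p[i, jp, k]
                                + clo_z[k] * p[i, j, km]
                                + chi_z[k] * p[i, j, kp])


@njit(cache=True)
def rbgs_sweep_periodic(p, rhs, clo_x, chi_x, clo_y, chi_y, clo_z, chi_z,
                        diag, color):
    nx, ny, nz = p.shape
    for i in range(nx):
        im, ip = (i - 1) % nx, (i + 1) % nx
        for j in range(ny):
            jm, jp = (j - 1) % ny, (j + 1) % ny
            k0 = (i + j + color) % 2
            for k in range(k0, nz, 2):
                km, kp = (k - 1) % nz, (k + 1) % nz
                s = (clo_x[i] * p[im, j, k] + chi_x[i] * p[ip, j, k]
                     + clo_y[j] * p[i, jm, k] + chi_y[j] * p[i, jp, k]
                     + clo_z[k] * p[i, j, km] + chi_z[k] * p[i, j, kp])
                p[i, j, k] = (rhs[i, j, k] - s) / diag[i, j, k]


@njit(cache=True)
def apply_operator(p, clo_x, chi_x, clo_y, chi_y, clo_z, chi_z, diag, out):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                s = diag[i, j, k] * p[i, j, k]
                if i > 0:
                    s += clo_x[i] * p[i - 1, j, k]
                if i < nx - 1:
                    s += chi_x[i] * p[i + 1, j, k]
                if j > 0:
                    s += clo_y[j] * p[i, j - 1, k]
                if j < ny - 1:
                    s += chi_y[j] * p[i, j + 1, k]
                if k > 0:
                    s += clo_z[k] * p[i, j, k - 1]
                if k < nz - 1:
                    s += chi_z[k] * p[i, j, k + 1]
                out[i, j, k] = s


@njit(cache=True)
def rbgs_sweep(p, rhs, clo_x, chi_x, clo_y, chi_y, clo_z, chi_z, diag,
               color):
    nx, ny, nz = p.shape
    for i in range(nx):
        for j in range(ny):
            k0 = (i + j + color) % 2
            for k in range(k0, nz, 2):
                s = 0.0
                if i > 0:
                    s += clo_x[i] * p[i - 1, j, k]
                if i < nx - 1:
                    s += chi_x[i] * p[i + 1, j, k]
                if j > 0:
                    s += clo_y[j] * p[i, j - 1, k]
                if j < ny - 1:
                    s += chi_y[j] * p[i, j + 1, k]
                if k > 0:
                    s += clo_z[k] * p[i, j, k - 1]
                if k < nz - 1:
                    s += chi_z[k] * p[i, j, k + 1]
                p[i, j, k] = (rhs[i, j, k] - s) / diag[i, j, k]


@njit(cache=True)
def _thomas_line_z(p, rhs, clo_z, chi_z, diag, i, j, s_other, work):
    nz = p.shape[2]
    cp = work[0]
    dp = work[1]
    b0 = diag[i, j, 0]
    cp[0] = chi_z[0] / b0
    dp[0] = (rhs[i, j, 0] - s_other[0]) / b0
    for k in range(1, nz):
        denom = diag[i, j, k] - clo_z[k] * cp[k - 1]
        cp[k] = chi_z[k] / denom
        dp[k] = (rhs[i, j, k] - s_other[k] - clo_z[k] * dp[k - 1]) / denom
    p[i, j, nz - 1] = dp[nz - 1]
    for k in range(nz - 2, -1, -1):
        p[i, j, k] = dp[k] - cp[k] * p[i, j, k + 1]


@njit(cache=True)
def zebra_sweep(p, rhs, clo_x, chi_x, clo_y, chi_y, clo_z, chi_z, diag,
                axis, parity):
    """Exact tridiagonal solve of every other grid line along ``axis``."""
    nx, ny, nz = p.shape
    if axis == 2:
        work = np.empty((2, nz))
        s_other = np.empty(nz)
        for i in range(nx):
            for j in range(ny):
                if (i + j) % 2 != parity:
                    continue
                for k in range(nz):
                    s = 0.0
                    if i > 0:
                        s += clo_x[i] * p[i - 1, j, k]
                    if i < nx - 1:
                        s += chi_x[i] * p[i + 1, j, k]
                    if j > 0:
                        s += clo_y[j] * p[i, j - 1, k]
                    if j < ny - 1:
                        s += chi_y[j] * p[i, j + 1, k]
                    s_other[k] = s
                _thomas_line_z(p, rhs, clo_z, chi_z, diag, i, j,
                               s_other, work)
    elif axis == 1:
        cp = np.empty(ny)
        dp = np.empty(ny)
        for i in range(nx):
            for k in range(nz):
                if (i + k) % 2 != parity:
                    continue
                b0 = diag[i, 0, k]
                s = 0.0
                if i > 0:
                    s += clo_x[i] * p[i - 1, 0, k]
                if i < nx - 1:
                    s += chi_x[i] * p[i + 1, 0, k]
                if k > 0:
                    s += clo_z[k] * p[i, 0, k - 1]
                if k < nz - 1:
                    s += chi_z[k] * p[i, 0, k + 1]
                cp[0] = chi_y[0] / b0
                dp[0] = (rhs[i, 0, k] - s) / b0
                for j in range(1, ny):
                    s = 0.0
                    if i > 0:
                        s += clo_x[i] * p[i - 1, j, k]
                    if i < nx - 1:
                        s += chi_x[i] * p[i + 1, j, k]
                    if k > 0:
                        s += clo_z[k] * p[i, j, k - 1]
                    if k < nz - 1:
                        s += chi_z[k] * p[i, j, k + 1]
                    denom = diag[i, j, k] - clo_y[j] * cp[j - 1]
                    cp[j] = chi_y[j] / denom
                    dp[j] = (rhs[i, j, k] - s - clo_y[j] * dp[j - 1]) / denom
                p[i, ny - 1, k] = dp[ny - 1]
                for j in range(ny - 2, -1, -1):
                    p[i, j, k] = dp[j] - cp[j] * p[i, j + 1, k]
    else:
        cp = np.empty(nx)
        dp = np.empty(nx)
        for j in range(ny):
            for k in range(nz):
                if (j + k) % 2 != parity:
                    continue
                b0 = diag[0, j, k]
                s = 0.0
                if j > 0:
                    s += clo_y[j] * p[0, j - 1, k]
                if j < ny - 1:
                    s += chi_y[j] * p[0, j + 1, k]
                if k > 0:
                    s += clo_z[k] * p[0, j, k - 1]
                if k < nz - 1:
                    s += chi_z[k] * p[0, j, k + 1]
                cp[0] = chi_x[0] / b0
                dp[0] = (rhs[0, j, k] - s) / b0
                for i in range(1, nx):
                    s = 0.0
                    if j > 0:
                        s += clo_y[j] * p[i, j - 1, k]
                    if j < ny - 1:
                        s += chi_y[j] * p[i, j + 1, k]
                    if k > 0:
                        s += clo_z[k] * p[i, j, k - 1]
                    if k < nz - 1:
                        s += chi_z[k] * p[i, j, k + 1]
                    denom = diag[i, j, k] - clo_x[i] * cp[i - 1]
                    cp[i] = chi_x[i] / denom
                    dp[i] = (rhs[i, j, k] - s - clo_x[i] * dp[i - 1]) / denom
                p[nx - 1, j, k] = dp[nx - 1]
                for i in range(nx - 2, -1, -1):
                    p[i, j, k] = dp[i] - cp[i] * p[i + 1, j, k]
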