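"""Flow-field diagnostics: swirling strength and pressure slices.

The swirling strength lambda_ci of a velocity-gradient tensor is the
largest imaginary part among its eigenvalues; it is positive only where
the local flow spirals (complex eigenvalues) and vanishes in pure strain,
making it a sharper vortex marker than vorticity magnitude.  Eigenvalues
of the 3x3 tensors are obtained from the characteristic cubic in closed
form (vectorized Cardano), which is deterministic and cheap over full
fields.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .solver.core import FlowState
from .solver.grid import StructuredGrid
from .solver.traction import velocity_gradient_tensor

__all__ = ["swirling_strength", "swirl_field", "pressure_slice"]


def swirling_strength(tensors: np.ndarray) -> np.ndarray:
    """lambda_ci (s^-1) of one or many 3x3 velocity-gradient tensors.

    Accepts shape (..., 3, 3); returns shape (...).  Real-spectrum tensors
    (including every symmetric tensor) give exactly zero.
    """
    T = np.asarray(tensors, dtype=float)
    if T.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) tensors, got {T.shape}")
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite entries in velocity-gradient tensor")
    # characteristic polynomial lambda^3 - I1 lambda^2 + I2 lambda - I3
    I1 = np.trace(T, axis1=-2, axis2=-1)
    TT = np.einsum("...ij,...jk->...ik", T, T)
    I2 = 0.5 * (I1 ** 2 - np.trace(TT, axis1=-2, axis2=-1))
    I3 = np.linalg.det(T)
    # depressed cubic t^3 + p t + q, lambda = t + I1/3
    p = I2 - I1 ** 2 / 3.0
    q = -2.0 * I1 ** 3 / 27.0 + I1 * I2 / 3.0 - I3
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    out = np.zeros(T.shape[:-2])
    pos = disc > 0.0  # one real root, one complex-conjugate pair
    if np.any(pos):
        sq = np.sqrt(disc[pos])
        u3 = -q[pos] / 2.0 + sq
        v3 = -q[pos] / 2.0 - sq
        u = np.cbrt(u3)
        v = np.cbrt(v3)
        # complex pair: t = -(u+v)/2 +- i sqrt(3)/2 (u-v); polish with two
        # Newton steps on the characteristic cubic to recover full double
        # precision near small discriminants
        lam = (-(u + v) / 2.0 + I1[pos] / 3.0
               + 1j * np.sqrt(3.0) / 2.0 * np.abs(u - v))
        a1, a2, a3 = I1[pos], I2[pos], I3[pos]
        for _ in range(2):
            f = ((lam - a1) * lam + a2) * lam - a3
            fp = (3.0 * lam - 2.0 * a1) * lam + a2
            lam = lam - np.where(np.abs(fp) > 0, f / fp, 0.0)
        out[pos] = np.abs(lam.imag)
    return out


def swirl_field(state: FlowState, grid: StructuredGrid,
                mask_solid: bool = True) -> np.ndarray:
    """Per-cell swirling strength; solid cells are set to zero."""
    G = velocity_gradient_tensor(state, grid)
    lam = swirling_strength(G)
    if mask_solid and state.solid is not None:
        lam = np.where(state.solid, 0.0, lam)
    return lam


def pressure_slice(
    state: FlowState,
    grid: StructuredGrid,
    axis: int,
    coordinate: float,
    rho: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pressure (Pa, = rho * kinematic pressure) on a coordinate plane.

    ``axis`` is the plane normal (0=x: parasagittal planes are y slices,
    axis=1).  Returns (coords_1, coords_2, pressure 2-D array) where the
    two coordinate arrays span the in-plane axes in grid order.  Solid
    cells interpolate to NaN.
    """
    ext = grid.extent()[axis]
    if not (ext[0] <= coordinate <= ext[1]):
        raise ValueError(
            f"slice coordinate {coordinate} outside domain {ext}")
    p = rho * state.p
    if state.solid is not None:
        p = np.where(state.solid, np.nan, p)
    interp = RegularGridInterpolator(
        (grid.xc, grid.yc, grid.zc), p, method="linear",
        bounds_error=False, fill_value=None)
    axes = [grid.xc, grid.yc, grid.zc]
    in_plane = [a for a in range(3) if a != axis]
    A, B = np.meshgrid(axes[in_plane[0]], axes[in_plane[1]], indexing="ij")
    pts = np.empty(A.shape + (3,))
    pts[..., axis] = coordinate
    pts[..., in_plane[0]] = A
    pts[..., in_plane[1]] = B
    return axes[in_plane[0]], axes[in_plane[1]], interp(pts)
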