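"""Surface traction from the flow state.

Traction (Pa) per triangle: -p n + tau . n with the viscous stress tau =
mu (grad u + grad u^T), sampled by trilinear interpolation from the grid at
probe points offset from each triangle centroid along its normal.  Closed
surfaces are sampled on the outside only; zero-thickness membranes are
sampled on both sides and carry the jump.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import FlowState
from .grid import StructuredGrid

__all__ = ["surface_traction", "cell_centered_velocity",
           "velocity_gradient_tensor"]


def cell_centered_velocity(state: FlowState, grid: StructuredGrid) -> np.ndarray:
    """(nx, ny, nz, 3) velocity averaged to cell centers."""
    uc = 0.5 * (state.u[:-1] + state.u[1:])
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    wc = 0.5 * (state.w[:, :, :-1] + state.w[:, :, 1:])
    return np.stack([uc, vc, wc], axis=-1)


def velocity_gradient_tensor(state: FlowState, grid: StructuredGrid) -> np.ndarray:
    """(nx, ny, nz, 3, 3) tensor G[i,j] = d(u_i)/d(x_j) at cell centers.

    Second-order central differences on the (possibly non-uniform) cell
    center coordinates; one-sided at the domain edges.
    """
    vel = cell_centered_velocity(state, grid)
    G = np.empty(vel.shape[:3] + (3, 3))
    coords = (grid.xc, grid.yc, grid.zc)
    for i in range(3):
        grads = np.gradient(vel[..., i], *coords, edge_order=2)
        for j in range(3):
            G[..., i, j] = grads[j]
    return G


def _interpolator(field: np.ndarray, grid: StructuredGrid):
    return RegularGridInterpolator(
        (grid.xc, grid.yc, grid.zc), field,
        method="linear", bounds_error=False, fill_value=None)


def surface_traction(
    state: FlowState,
    grid: StructuredGrid,
    vertices: np.ndarray,
    faces: np.ndarray,
    rho: float,
    nu: float,
    closed: bool = False,
    offset_cells: float = 1.4,
) -> np.ndarray:
    """Per-triangle traction vectors (Pa).

    For membranes (``closed=False``) the traction is the jump between the
    positive-normal and negative-normal sides; for closed surfaces only the
    outside is sampled.  Probe points sit ``offset_cells`` fine cells from
    the centroid along the (unit) normal.  Raises if any triangle centroid
    lies outside the grid.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    centroids = (a + b + c) / 3.0
    ext = grid.extent()
    for axis in range(3):
        if (centroids[:, axis].min() < ext[axis][0]
                or centroids[:, axis].max() > ext[axis][1]):
            raise ValueError("triangle centroid outside the grid domain")
    cross = np.cross(b - a, c - a)
    areas2 = np.linalg.norm(cross, axis=1)
    normals = cross / np.maximum(areas2, 1e-300)[:, None]

    delta = offset_cells * grid.min_spacing
    p_phys = rho * state.p
    mu = rho * nu
    p_interp = _interpolator(p_phys, grid)
    G = velocity_gradient_tensor(state, grid)
    g_interp = [[_interpolator(G[..., i, j], grid) for j in range(3)]
                for i in range(3)]

    def sample(points):
        p = p_interp(points)
        Gs = np.empty((len(points), 3, 3))
        for i in range(3):
            for j in range(3):
                Gs[:, i, j] = g_interp[i][j](points)
        tau = mu * (Gs + np.swapaxes(Gs, 1, 2))
        return p, tau

    def surface_values(side):
        # probe at delta and 2*delta along the normal and extrapolate
        # linearly back to the surface (exact for linear fields, removes
        # the probe-offset bias of one-point sampling)
        p1, tau1 = sample(centroids + side * delta * normals)
        p2, tau2 = sample(centroids + side * 2.0 * delta * normals)
        return 2.0 * p1 - p2, 2.0 * tau1 - tau2

    p_plus, tau_plus = surface_values(+1.0)
    traction = (-p_plus[:, None] * normals
                + np.einsum("tij,tj->ti", tau_plus, normals))
    if not closed:
        p_minus, tau_minus = surface_values(-1.0)
        traction = traction - (
            -p_minus[:, None] * normals
            + np.einsum("tij,tj->ti", tau_minus, normals))
    return traction
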