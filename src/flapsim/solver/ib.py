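"""Sharp-interface immersed boundary: cell classification and forcing.

The closed bird body marks interior cells as solid (ray-parity test);
zero-thickness wing membranes mark a one-cell interface shell.  Direct
forcing imposes the local surface velocity on every staggered velocity face
whose center is inside the body or within about half a fine cell of a
membrane or of the body skin.  Fresh cells (solid one step, fluid the next,
for moving closed bodies) are refilled with the local surface velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ..geometry import WingMesh, trajectory_spline
from .core import FlowState
from .grid import StructuredGrid
from .meshquery import SurfaceDistanceQuery, contains_lattice

__all__ = ["CellClassification", "classify_cells", "MovingSurface",
           "StaticSurface", "ImmersedBoundary"]


@dataclass
class CellClassification:
    """Per-cell flags at one instant."""

    solid: np.ndarray        # inside a closed body
    interface: np.ndarray    # within one fine cell of any surface
    fresh: np.ndarray        # newly fluid since the previous classification

    @property
    def fluid(self) -> np.ndarray:
        return ~(self.solid | self.interface)


def _check_watertight(vertices: np.ndarray, faces: np.ndarray) -> bool:
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return bool(tm.is_watertight)


def _near_mask(query: SurfaceDistanceQuery, pts: np.ndarray,
               radius: float, shape: tuple) -> np.ndarray:
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    lo = query.bounds[0] - 1.5 * radius
    hi = query.bounds[1] + 1.5 * radius
    cand = np.nonzero(np.all((pts >= lo) & (pts <= hi), axis=1))[0]
    if cand.size:
        idx, _, _, _ = query.within(pts[cand], radius)
        mask[cand[idx]] = True
    return mask.reshape(shape)


def classify_cells(
    grid: StructuredGrid,
    body: tuple[np.ndarray, np.ndarray] | None = None,
    membranes: list[tuple[np.ndarray, np.ndarray]] | None = None,
    previous_solid: np.ndarray | None = None,
) -> CellClassification:
    """Classify grid cells against a closed body and thin membranes.

    ``body`` and each membrane are (vertices, faces) pairs.  The body must
    be watertight (interior found by ray parity); membranes mark interface
    cells within one fine-cell distance of their surface.
    ``previous_solid`` enables fresh-cell detection for moving bodies.
    """
    shape = grid.shape
    X, Y, Z = np.meshgrid(grid.xc, grid.yc, grid.zc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    solid = np.zeros(shape, dtype=bool)
    interface = np.zeros(shape, dtype=bool)
    h = grid.min_spacing
    if body is not None:
        verts, faces = body
        if not _check_watertight(verts, faces):
            raise ValueError("body mesh is not watertight")
        solid = contains_lattice(verts, faces, grid.xc, grid.yc, grid.zc)
        interface |= _near_mask(SurfaceDistanceQuery(verts, faces),
                                pts, h, shape)
    for verts, faces in (membranes or []):
        interface |= _near_mask(SurfaceDistanceQuery(verts, faces),
                                pts, h, shape)
    interface &= ~solid
    fresh = (np.zeros(shape, dtype=bool) if previous_solid is None
             else previous_solid & ~solid)
    return CellClassification(solid=solid, interface=interface, fresh=fresh)


class StaticSurface:
    """A fixed surface (the bird body) with zero surface velocity."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.faces = np.asarray(faces, dtype=np.int64)
        self._vertices = np.asarray(vertices, dtype=float)

    def positions(self, t: float) -> np.ndarray:
        return self._vertices

    def velocities(self, t: float) -> np.ndarray:
        return np.zeros_like(self._vertices)


class MovingSurface:
    """A wing mesh animated by its periodic trajectory spline."""

    def __init__(self, mesh: WingMesh):
        self.faces = mesh.triangles
        self._spline = trajectory_spline(mesh)
        self._t0 = float(mesh.times[0])
        dt = mesh.times[1] - mesh.times[0]
        self._period = float(mesh.times[-1] - mesh.times[0] + dt)

    def _wrap(self, t: float) -> float:
        return self._t0 + np.mod(t - self._t0, self._period)

    def positions(self, t: float) -> np.ndarray:
        return self._spline(self._wrap(t))

    def velocities(self, t: float) -> np.ndarray:
        return self._spline(self._wrap(t), 1)


class ImmersedBoundary:
    """Direct-forcing callback for :class:`~flapsim.solver.core.IBNSolver`.

    Velocity faces inside the closed body or within ``shell`` fine cells of
    any registered surface are set to the local surface velocity each step.
    """

    def __init__(self, grid: StructuredGrid,
                 body: trimesh.Trimesh | None = None,
                 moving: list[MovingSurface] | None = None,
                 shell: float = 0.55):
        self.grid = grid
        self.moving = list(moving or [])
        self.shell_radius = shell * grid.min_spacing
        # face-center point sets for the three staggered components
        self._face_pts = []
        self._face_shapes = []
        for comp in range(3):
            axes = [grid.xc, grid.yc, grid.zc]
            axes[comp] = grid.faces(comp)
            F0, F1, F2 = np.meshgrid(*axes, indexing="ij")
            self._face_pts.append(
                np.column_stack([F0.ravel(), F1.ravel(), F2.ravel()]))
            self._face_shapes.append(F0.shape)
        self.body = body
        self._body_masks = [None, None, None]
        self.solid_cells = None
        if body is not None:
            verts = np.asarray(body.vertices, dtype=float)
            faces = np.asarray(body.faces, dtype=np.int64)
            if not _check_watertight(verts, faces):
                raise ValueError("body mesh is not watertight")
            query = SurfaceDistanceQuery(verts, faces)
            for comp in range(3):
                axes = [grid.xc, grid.yc, grid.zc]
                axes[comp] = grid.faces(comp)
                inside = contains_lattice(verts, faces, *axes)
                near = _near_mask(query, self._face_pts[comp],
                                  self.shell_radius, self._face_shapes[comp])
                self._body_masks[comp] = inside | near
            self.solid_cells = contains_lattice(verts, faces, grid.xc,
                                                grid.yc, grid.zc)

    def _force_component(self, arr: np.ndarray, comp: int,
                         query: SurfaceDistanceQuery, verts: np.ndarray,
                         faces: np.ndarray, vel: np.ndarray) -> None:
        pts = self._face_pts[comp]
        lo = query.bounds[0] - 2.0 * self.shell_radius
        hi = query.bounds[1] + 2.0 * self.shell_radius
        cand = np.nonzero(np.all((pts >= lo) & (pts <= hi), axis=1))[0]
        if cand.size == 0:
            return
        idx, dist, closest, tri_id = query.within(pts[cand],
                                                  self.shell_radius)
        if idx.size == 0:
            return
        bary = trimesh.triangles.points_to_barycentric(
            query.triangles[tri_id], closest)
        bary = np.clip(bary, 0.0, 1.0)
        bary /= bary.sum(axis=1, keepdims=True)
        v_tri = vel[faces[tri_id]]            # (m, 3 verts, 3)
        v_surf = (bary[:, :, None] * v_tri).sum(axis=1)[:, comp]
        arr.reshape(-1)[cand[idx]] = v_surf

    def __call__(self, state: FlowState, grid: StructuredGrid,
                 t: float) -> None:
        comps = (state.u, state.v, state.w)
        for comp in range(3):
            if self._body_masks[comp] is not None:
                comps[comp][self._body_masks[comp]] = 0.0
        for surf in self.moving:
            verts = surf.positions(t)
            vel = surf.velocities(t)
            query = SurfaceDistanceQuery(verts, surf.faces)
            for comp in range(3):
                self._force_component(comps[comp], comp, query,
                                      verts, surf.faces, vel)
        state.solid = self.solid_cells
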