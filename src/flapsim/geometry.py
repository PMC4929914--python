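"""Wing and body surface reconstruction.

From nine tracked markers per frame, the wing planform outline is a closed
periodic cubic spline in anatomical order (leading edge root to tip, then
trailing edge back to the root).  The membrane surface is built once as a
2-D constrained triangulation of the outline's best-fit-plane projection;
per frame, interior nodes are lifted to 3-D by solving a discrete Laplace
(harmonic) problem with the frame's 3-D outline as Dirichlet data, so the
mesh connectivity is constant in time and only node positions move.  Node
trajectories are then refined with periodic cubic splines in time, whose
analytic derivative supplies nodal velocities.

The bird body is a watertight fusiform surface of revolution pitched at the
body angle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import trimesh
from scipy.interpolate import CubicSpline
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .config import FlightConfig
from .kinematics import MarkerTrajectorySet

__all__ = [
    "DegenerateOutlineError",
    "OutlineSpline",
    "WingMesh",
    "BodyMesh",
    "reconstruct_outline",
    "triangulate_wing",
    "estimate_shoulder",
    "reconstruct_wing_series",
    "refine_in_time",
    "phase_average",
    "segment_strokes",
    "build_body",
    "save_wing_mesh",
    "load_wing_mesh",
]


class DegenerateOutlineError(ValueError):
    """Markers do not define a usable planform outline."""


# ---------------------------------------------------------------------------
# outline spline


@dataclass
class OutlineSpline:
    """Closed periodic cubic spline through the 9 markers.

    Parameterized by normalized chord length ``u`` in [0, 1); ``marker_u``
    holds the parameter values of the input markers.
    """

    _spline: CubicSpline
    marker_u: np.ndarray
    markers: np.ndarray

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return self._spline(np.mod(u, 1.0))


def reconstruct_outline(markers: np.ndarray) -> OutlineSpline:
    """Fit the closed planform outline through one frame's 9 markers.

    Markers must be in anatomical order (LE root->tip, TIP, TE tip->root).
    Centripetal (square-root chord length) parameterization, which bounds
    overshoot near the high-curvature tip; the spline passes through every
    marker.  Raises :class:`DegenerateOutlineError` for a wrong marker
    count, duplicated markers, or (near-)collinear marker sets.
    """
    pts = np.asarray(markers, dtype=float)
    if pts.shape != (9, 3):
        raise DegenerateOutlineError(
            f"expected 9 markers of 3 coordinates, got shape {pts.shape}")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    scale = seg.sum()
    if scale <= 0 or np.any(seg < 1e-9 * max(scale, 1e-12)):
        raise DegenerateOutlineError("duplicated or coincident markers")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise DegenerateOutlineError("markers are collinear")
    seg = np.sqrt(seg)
    u = np.concatenate([[0.0], np.cumsum(seg)]) / seg.sum()
    spline = CubicSpline(u, closed, axis=0, bc_type="periodic")
    return OutlineSpline(_spline=spline, marker_u=u[:9], markers=pts)


# ---------------------------------------------------------------------------
# meshes


@dataclass
class WingMesh:
    """Time-resolved triangulated wing membrane.

    ``nodes`` has shape (n_frames, n_nodes, 3); connectivity is shared by
    all frames.  ``boundary`` lists boundary-node indices in outline order
    with their spline parameters ``boundary_u``.
    """

    times: np.ndarray
    nodes: np.ndarray
    triangles: np.ndarray
    side: str
    shoulder: np.ndarray
    boundary: np.ndarray
    boundary_u: np.ndarray
    node_velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.nodes.ndim == 2:
            self.nodes = self.nodes[None]
        n_nodes = self.nodes.shape[1]
        if self.triangles.min() < 0 or self.triangles.max() >= n_nodes:
            raise ValueError("triangle indices out of range")

    @property
    def n_frames(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def triangle_areas(self, frame: int = 0) -> np.ndarray:
        p = self.nodes[frame]
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def triangle_centroids(self, frame: int = 0) -> np.ndarray:
        p = self.nodes[frame]
        return p[self.triangles].mean(axis=1)

    def triangle_normals(self, frame: int = 0) -> np.ndarray:
        p = self.nodes[frame]
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def area(self, frame: int = 0) -> float:
        return float(self.triangle_areas(frame).sum())

    def areas(self) -> np.ndarray:
        return np.array([self.area(i) for i in range(self.n_frames)])

    def frame_trimesh(self, frame: int = 0) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.nodes[frame],
                               faces=self.triangles, process=False)

    def tip_index(self, frame: int = 0) -> int:
        b = self.boundary
        d = np.linalg.norm(self.nodes[frame, b] - self.shoulder, axis=1)
        return int(b[np.argmax(d)])


@dataclass
class BodyMesh:
    """Static watertight body surface in the bird-fixed frame."""

    nodes: np.ndarray
    triangles: np.ndarray
    chi_b: float

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.nodes, faces=self.triangles,
                               process=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]


# ---------------------------------------------------------------------------
# triangulation of a single frame


def _project_to_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project 3-D points onto their best-fit (PCA) plane; return (2-D
    coordinates, plane origin, plane basis (2,3))."""
    origin = points.mean(axis=0)
    centered = points - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:2]
    return centered @ basis.T, origin, basis


def _cotangent_laplacian(points2d: np.ndarray, triangles: np.ndarray) -> csc_matrix:
    n = len(points2d)
    ii, jj, vv = [], [], []
    for k in range(3):
        i = triangles[:, k]
        j = triangles[:, (k + 1) % 3]
        o = triangles[:, (k + 2) % 3]
        a = points2d[i] - points2d[o]
        b = points2d[j] - points2d[o]
        cross = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
        cot = (a * b).sum(axis=1) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        ii.extend([i, j]); jj.extend([j, i]); vv.extend([w, w])
    ii = np.concatenate(ii); jj = np.concatenate(jj); vv = np.concatenate(vv)
    W = coo_matrix((vv, (ii, jj)), shape=(n, n)).tocsc()
    D = coo_matrix((np.asarray(W.sum(axis=1)).ravel(), (np.arange(n), np.arange(n))),
                   shape=(n, n)).tocsc()
    return D - W


class _WingParameterization:
    """Frame-independent 2-D triangulation and harmonic-lift factorization."""

    def __init__(self, outline: OutlineSpline, target_elements: int):
        if target_elements < 2:
            raise ValueError("target_elements must be at least 2")
        # dense polygon for area / containment checks
        u_dense = np.linspace(0.0, 1.0, 512, endpoint=False)
        dense3d = outline(u_dense)
        dense2d, origin, basis = _project_to_plane(dense3d)
        poly = Polygon(dense2d)
        if not poly.is_valid or not poly.is_simple:
            raise DegenerateOutlineError("outline is self-intersecting")
        if poly.exterior.is_ccw is False:
            # flip the 2-D basis so the polygon is counterclockwise
            basis = basis[::-1]
            dense2d = dense2d[:, ::-1]
            poly = Polygon(dense2d)
        area = poly.area

        # lattice pitch h giving ~target equilateral triangles of area
        # sqrt(3)/4 h^2 each
        h = math.sqrt(4.0 * area / (math.sqrt(3.0) * target_elements))
        perimeter = poly.exterior.length
        n_b = max(12, int(round(perimeter / h)))
        self.boundary_u = np.linspace(0.0, 1.0, n_b, endpoint=False)
        b2d = _project(outline(self.boundary_u), origin, basis)

        interior = _hex_lattice(poly, h)
        pts2d = np.vstack([b2d, interior]) if len(interior) else b2d

        tri = Delaunay(pts2d)
        cent = pts2d[tri.simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        simplices = tri.simplices[keep]
        # enforce counterclockwise orientation in the parameter plane
        e1 = pts2d[simplices[:, 1]] - pts2d[simplices[:, 0]]
        e2 = pts2d[simplices[:, 2]] - pts2d[simplices[:, 0]]
        flip = (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]) < 0
        simplices[flip] = simplices[flip][:, [0, 2, 1]]
        # drop nodes unused after the containment filter
        used = np.unique(simplices)
        remap = -np.ones(len(pts2d), dtype=np.int64)
        remap[used] = np.arange(len(used))
        self.points2d = pts2d[used]
        self.triangles = remap[simplices]
        self.boundary_idx = remap[np.arange(n_b)]
        if np.any(self.boundary_idx < 0):
            raise DegenerateOutlineError("triangulation dropped boundary nodes")
        self.interior_idx = np.setdiff1d(np.arange(len(used)),
                                         self.boundary_idx)
        L = _cotangent_laplacian(self.points2d, self.triangles)
        self._L_ib = L[self.interior_idx][:, self.boundary_idx]
        self._lu = splu(L[self.interior_idx][:, self.interior_idx].tocsc())

    def lift(self, boundary3d: np.ndarray) -> np.ndarray:
        """Harmonic 3-D node positions for given boundary positions."""
        nodes = np.empty((len(self.points2d), 3))
        nodes[self.boundary_idx] = boundary3d
        if len(self.interior_idx):
            rhs = -self._L_ib @ boundary3d
            nodes[self.interior_idx] = self._lu.solve(rhs)
        return nodes


def _project(points3d: np.ndarray, origin: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return (points3d - origin) @ basis.T


def _hex_lattice(poly: Polygon, h: float) -> np.ndarray:
    """Hexagonal lattice points strictly inside the polygon (margin h/2)."""
    minx, miny, maxx, maxy = poly.bounds
    rows = []
    dy = h * math.sqrt(3.0) / 2.0
    j = 0
    y = miny + 0.5 * h
    while y < maxy:
        xs = np.arange(minx + (0.25 + 0.5 * (j % 2)) * h, maxx, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        j += 1
    if not rows:
        return np.empty((0, 2))
    pts = np.vstack(rows)
    inner = poly.buffer(-0.45 * h)
    if inner.is_empty:
        return np.empty((0, 2))
    keep = shapely.contains_xy(inner, pts[:, 0], pts[:, 1])
    return pts[keep]


def triangulate_wing(
    outline: OutlineSpline,
    target_elements: int = 1335,
    side: str = "left",
    shoulder: np.ndarray | None = None,
    time: float = 0.0,
) -> WingMesh:
    """Triangulate a single frame's planform into a membrane mesh.

    The triangle count lands within ~15% of ``target_elements``; the mesh
    boundary follows the outline spline, and interior nodes are the harmonic
    lift of the 2-D parameterization.
    """
    param = _WingParameterization(outline, target_elements)
    nodes = param.lift(outline(param.boundary_u))
    if shoulder is None:
        # proximal end of the outline: midpoint of first and last markers
        shoulder = 0.5 * (outline.markers[0] + outline.markers[-1])
    return WingMesh(
        times=np.array([time]),
        nodes=nodes[None],
        triangles=param.triangles,
        side=side,
        shoulder=np.asarray(shoulder, dtype=float),
        boundary=param.boundary_idx,
        boundary_u=param.boundary_u,
    )


def estimate_shoulder(wing_markers: np.ndarray) -> np.ndarray:
    """Least-squares shoulder position from multi-frame spar lines.

    The five leading-edge markers and the wingtip lie on the (straight)
    leading-edge spar, which pivots about the fixed shoulder joint.  The
    shoulder is recovered as the static point minimizing the summed squared
    distance to every frame's spar line.
    """
    wing_markers = np.asarray(wing_markers, dtype=float)
    if wing_markers.ndim == 2:
        wing_markers = wing_markers[None]
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for frame in wing_markers:
        spar = frame[:6]  # LE1..LE5 and TIP
        center = spar.mean(axis=0)
        _, _, vt = np.linalg.svd(spar - center, full_matrices=False)
        u = vt[0]
        P = np.eye(3) - np.outer(u, u)
        A += P
        b += P @ center
    return np.linalg.solve(A, b)


def reconstruct_wing_series(
    markers: MarkerTrajectorySet,
    side: str = "left",
    target_elements: int = 1335,
) -> WingMesh:
    """Reconstruct the time-resolved wing mesh for one wing.

    The 2-D parameterization (and hence connectivity) is built from the
    first frame; every frame re-fits the outline spline through its own
    markers and lifts the same parameter nodes to 3-D.
    """
    wing = markers.wing(side)
    outline0 = reconstruct_outline(wing[0])
    param = _WingParameterization(outline0, target_elements)
    n_frames = markers.n_times
    nodes = np.empty((n_frames, len(param.points2d), 3))
    for it in range(n_frames):
        outline = outline0 if it == 0 else reconstruct_outline(wing[it])
        nodes[it] = param.lift(outline(param.boundary_u))
    shoulder = estimate_shoulder(wing)
    return WingMesh(
        times=markers.times.copy(),
        nodes=nodes,
        triangles=param.triangles,
        side=side,
        shoulder=shoulder,
        boundary=param.boundary_idx,
        boundary_u=param.boundary_u,
    )


# ---------------------------------------------------------------------------
# temporal refinement and phase averaging


def refine_in_time(mesh: WingMesh, refinement_factor: int) -> WingMesh:
    """Refine node trajectories in time with periodic cubic splines.

    The series is treated as an integer number of wingbeat cycles sampled
    uniformly; a wrap frame equal to the first closes the period.  Nodal
    velocities are the analytic spline derivative.  At the original sample
    instants, positions are unchanged (interpolation).
    """
    if refinement_factor < 1 or int(refinement_factor) != refinement_factor:
        raise ValueError("refinement_factor must be a positive integer")
    if mesh.n_frames < 10:
        raise ValueError("need at least 10 frames to refine in time")
    t = mesh.times
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6):
        raise ValueError("temporal refinement requires uniform sampling")
    t_ext = np.append(t, t[-1] + dt)
    pos_ext = np.concatenate([mesh.nodes, mesh.nodes[:1]], axis=0)
    spline = CubicSpline(t_ext, pos_ext, axis=0, bc_type="periodic")
    n_new = mesh.n_frames * refinement_factor
    t_new = t[0] + np.arange(n_new) * dt / refinement_factor
    return WingMesh(
        times=t_new,
        nodes=spline(t_new),
        triangles=mesh.triangles.copy(),
        side=mesh.side,
        shoulder=mesh.shoulder.copy(),
        boundary=mesh.boundary.copy(),
        boundary_u=mesh.boundary_u.copy(),
        node_velocities=spline(t_new, 1),
    )


def trajectory_spline(mesh: WingMesh) -> CubicSpline:
    """Periodic cubic spline of all node trajectories (for CFD sampling)."""
    t = mesh.times
    dt = t[1] - t[0]
    t_ext = np.append(t, t[-1] + dt)
    pos_ext = np.concatenate([mesh.nodes, mesh.nodes[:1]], axis=0)
    return CubicSpline(t_ext, pos_ext, axis=0, bc_type="periodic")


def phase_average(
    phases: np.ndarray,
    values: np.ndarray,
    n_bins: int = 22,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-average a cyclic series.

    ``phases`` are in cycles (need not be wrapped); ``values`` may be any
    shape with leading axis matching ``phases``.  Requires at least two
    complete cycles.  Returns (bin centers in [0,1), per-bin means).
    """
    phases = np.asarray(phases, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.ptp(phases) < 2.0 - 1.0 / max(n_bins, 1):
        raise ValueError("phase averaging requires at least 2 complete cycles")
    # nudge against representation error so samples on bin edges land in
    # the bin they parameterize
    bins = np.floor(np.mod(phases, 1.0) * n_bins + 1e-9).astype(int) % n_bins
    centers = (np.arange(n_bins) + 0.5) / n_bins
    out = np.empty((n_bins,) + values.shape[1:])
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            raise ValueError(f"phase bin {b} is empty; use fewer bins")
        out[b] = values[sel].mean(axis=0)
    return centers, out


def segment_strokes(
    times: np.ndarray,
    tip_positions: np.ndarray,
    beta_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a tip trajectory into wingbeat phases and stroke labels.

    Cycle boundaries are placed at maxima of the tip elevation within the
    stroke plane (start of downstroke); downstroke runs from each maximum to
    the following minimum, upstroke is the remainder.  Returns (phase array
    in cycles, boolean downstroke mask).
    """
    from .kinematics import stroke_frame

    a_hat, _, _ = stroke_frame(beta_deg)
    elev = -(np.asarray(tip_positions) @ a_hat)  # high at start of downstroke
    n = len(elev)
    if n < 8:
        raise ValueError("too few samples to segment strokes")
    maxima = [i for i in range(1, n - 1)
              if elev[i] >= elev[i - 1] and elev[i] > elev[i + 1]]
    # a series that starts or ends at the top of the stroke has its cycle
    # boundary on the first/last sample
    if elev[0] >= elev[1] and (not maxima or maxima[0] > 2):
        maxima.insert(0, 0)
    if elev[-1] > elev[-2] and (not maxima or maxima[-1] < n - 3):
        maxima.append(n - 1)
    if len(maxima) < 2:
        raise ValueError("fewer than one full cycle in tip trajectory")
    period = np.mean(np.diff(times[maxima]))
    phase = (times - times[maxima[0]]) / period
    minima = [i for i in range(1, n - 1)
              if elev[i] <= elev[i - 1] and elev[i] < elev[i + 1]]
    down = np.zeros(n, dtype=bool)
    frac = np.mod(phase, 1.0)
    if minima:
        # downstroke fraction from mean maximum-to-minimum spacing
        dfrac = np.clip(np.mean([
            np.mod(times[m] - times[maxima[0]], period) / period
            for m in minima]), 0.2, 0.8)
    else:
        dfrac = 0.5
    down = frac < dfrac
    return phase, down


# ---------------------------------------------------------------------------
# body


def build_body(
    config: FlightConfig,
    length: float = 8.0e-2,
    max_radius: float = 1.1e-2,
    center: np.ndarray | None = None,
    n_rings: int = 42,
    n_segments: int = 42,
) -> BodyMesh:
    """Build a watertight fusiform body pitched at the body angle chi_b.

    A surface of revolution with a smooth tapered radius profile (blunter
    nose, finer tail), nose pointing upstream and raised by ``chi_b``
    degrees.  Default tessellation gives ~3500 triangles.
    """
    if center is None:
        center = np.array([1.0e-2, 0.0, -1.2e-2])
    xi = np.linspace(0.0, 1.0, n_rings + 2)[1:-1]
    radius = max_radius * np.sin(np.pi * xi ** 0.8) ** 0.9
    axial = (xi - 0.35) * length  # nose at xi=0

    chi = math.radians(config.chi_b)
    axis = np.array([-math.cos(chi), 0.0, math.sin(chi)])   # toward the nose
    e1 = np.array([math.sin(chi), 0.0, math.cos(chi)])      # "up" normal
    e2 = np.array([0.0, 1.0, 0.0])

    ang = 2.0 * np.pi * np.arange(n_segments) / n_segments
    ring_dirs = np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)

    # pole vertices sit on the axis just beyond the end rings
    d_nose = axial[0] - 0.6 * (axial[1] - axial[0])
    d_tail = axial[-1] + 0.6 * (axial[-1] - axial[-2])
    pole_nose = center - d_nose * axis
    pole_tail = center - d_tail * axis

    verts = [pole_nose]
    for k in range(n_rings):
        ring = center - axial[k] * axis + radius[k] * ring_dirs
        verts.extend(ring)
    verts.append(pole_tail)
    verts = np.array(verts)

    faces = []
    def ring_idx(k, s):
        return 1 + k * n_segments + (s % n_segments)
    for s in range(n_segments):  # nose fan
        faces.append([0, ring_idx(0, s), ring_idx(0, s + 1)])
    for k in range(n_rings - 1):
        for s in range(n_segments):
            a, b = ring_idx(k, s), ring_idx(k, s + 1)
            c, d = ring_idx(k + 1, s), ring_idx(k + 1, s + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    tail = len(verts) - 1
    for s in range(n_segments):  # tail fan
        faces.append([tail, ring_idx(n_rings - 1, s + 1), ring_idx(n_rings - 1, s)])
    faces = np.array(faces, dtype=np.int64)

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if tm.volume < 0:
        faces = faces[:, [0, 2, 1]]
        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not tm.is_watertight:
        raise RuntimeError("body construction produced a non-watertight mesh")
    return BodyMesh(nodes=verts, triangles=faces, chi_b=config.chi_b)


# ---------------------------------------------------------------------------
# mesh I/O


def save_wing_mesh(mesh: WingMesh, directory: str | Path, fmt: str = "obj") -> None:
    """Save a multi-frame wing mesh as one OBJ/PLY per frame plus metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(mesh.n_frames):
        mesh.frame_trimesh(i).export(directory / f"frame_{i:05d}.{fmt}")
    meta = {
        "times": mesh.times.tolist(),
        "side": mesh.side,
        "shoulder": mesh.shoulder.tolist(),
        "boundary": mesh.boundary.tolist(),
        "boundary_u": mesh.boundary_u.tolist(),
        "format": fmt,
        "n_frames": mesh.n_frames,
    }
    (directory / "wingmesh.json").write_text(json.dumps(meta))


def load_wing_mesh(directory: str | Path) -> WingMesh:
    directory = Path(directory)
    meta = json.loads((directory / "wingmesh.json").read_text())
    fmt = meta["format"]
    frames = []
    triangles = None
    for i in range(meta["n_frames"]):
        tm = trimesh.load(directory / f"frame_{i:05d}.{fmt}", process=False)
        frames.append(np.asarray(tm.vertices))
        if triangles is None:
            triangles = np.asarray(tm.faces)
    return WingMesh(
        times=np.array(meta["times"]),
        nodes=np.stack(frames),
        triangles=triangles,
        side=meta["side"],
        shoulder=np.array(meta["shoulder"]),
        boundary=np.array(meta["boundary"], dtype=np.int64),
        boundary_u=np.array(meta["boundary_u"]),
    )
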