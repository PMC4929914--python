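"""Non-uniform single-block Cartesian grids.

Each axis is a strictly increasing array of face coordinates with a uniform
fine block (around the wings) and geometrically stretched outer regions,
with the adjacent-cell size ratio capped (default 1.1).  Velocity
components live on face centers (staggered), pressure at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StructuredGrid", "build_grid", "uniform_periodic_grid"]

MAX_STRETCH = 1.1


@dataclass
class StructuredGrid:
    """Face coordinates per axis plus periodicity flags."""

    xf: np.ndarray
    yf: np.ndarray
    zf: np.ndarray
    periodic: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        for name in ("xf", "yf", "zf"):
            f = np.asarray(getattr(self, name), dtype=float)
            if f.ndim != 1 or f.size < 3:
                raise ValueError(f"{name} must be a 1-D array of >= 3 faces")
            if np.any(np.diff(f) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, f)

    # -- derived geometry ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.xf.size - 1, self.yf.size - 1, self.zf.size - 1)

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def faces(self, axis: int) -> np.ndarray:
        return (self.xf, self.yf, self.zf)[axis]

    def centers(self, axis: int) -> np.ndarray:
        f = self.faces(axis)
        return 0.5 * (f[:-1] + f[1:])

    def spacing(self, axis: int) -> np.ndarray:
        return np.diff(self.faces(axis))

    @property
    def xc(self) -> np.ndarray:
        return self.centers(0)

    @property
    def yc(self) -> np.ndarray:
        return self.centers(1)

    @property
    def zc(self) -> np.ndarray:
        return self.centers(2)

    @property
    def dx(self) -> np.ndarray:
        return self.spacing(0)

    @property
    def dy(self) -> np.ndarray:
        return self.spacing(1)

    @property
    def dz(self) -> np.ndarray:
        return self.spacing(2)

    @property
    def min_spacing(self) -> float:
        return float(min(self.dx.min(), self.dy.min(), self.dz.min()))

    def cell_volumes(self) -> np.ndarray:
        return (self.dx[:, None, None] * self.dy[None, :, None]
                * self.dz[None, None, :])

    def max_stretch_ratio(self) -> float:
        r = 1.0
        for ax in range(3):
            d = self.spacing(ax)
            if d.size > 1:
                q = d[1:] / d[:-1]
                r = max(r, q.max(), (1.0 / q).max())
        return float(r)

    def extent(self) -> tuple[tuple[float, float], ...]:
        return tuple((float(self.faces(a)[0]), float(self.faces(a)[-1]))
                     for a in range(3))


def _stretched_side(gap: float, h: float, ratio: float) -> np.ndarray:
    """Geometric spacings covering at least ``gap`` outward from the block.

    Successive spacings grow by exactly ``ratio`` (capped at 8x the fine
    spacing), so the adjacent-cell ratio invariant holds everywhere; the
    covered distance may overshoot the request by up to one outer cell.
    """
    if gap <= 0.25 * h:
        return np.empty(0)
    spacings = []
    total = 0.0
    d = h
    while total < gap:
        d = min(d * ratio, 8.0 * h)
        spacings.append(d)
        total += d
    return np.array(spacings)


def _axis_faces(lo: float, hi: float, f_lo: float, f_hi: float,
                h: float, ratio: float) -> np.ndarray:
    if not (lo <= f_lo < f_hi <= hi):
        raise ValueError("fine block must lie inside the domain")
    n_fine = max(2, int(round((f_hi - f_lo) / h)))
    whole_axis = (f_lo - lo <= 0.25 * h) and (hi - f_hi <= 0.25 * h)
    if whole_axis:
        # keep the axis uniform: absorb the multigrid padding into the
        # fine count instead of appending stretched cells
        n_fine = max(4, -(-n_fine // 4) * 4)
    h_eff = (f_hi - f_lo) / n_fine
    fine = f_lo + h_eff * np.arange(n_fine + 1)
    left = _stretched_side(f_lo - lo, h_eff, ratio)
    right = _stretched_side(hi - f_hi, h_eff, ratio)
    faces = np.concatenate([
        f_lo - np.cumsum(left)[::-1] if left.size else np.empty(0),
        fine,
        f_hi + np.cumsum(right) if right.size else np.empty(0),
    ])
    # pad to a cell count divisible by 4 (keeps the multigrid hierarchy
    # deep); padding cells continue the outer stretching
    side = 1
    while (faces.size - 1) % 4:
        if side > 0:
            d = min((faces[-1] - faces[-2]) * ratio, 8.0 * h_eff)
            faces = np.append(faces, faces[-1] + d)
        else:
            d = min((faces[1] - faces[0]) * ratio, 8.0 * h_eff)
            faces = np.insert(faces, 0, faces[0] - d)
        side = -side
    return faces


def build_grid(
    domain: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    fine_block: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    fine_spacing: float,
    stretch_ratio: float = 1.05,
) -> StructuredGrid:
    """Build a stretched Cartesian grid with a uniform fine block.

    ``domain`` and ``fine_block`` give (lo, hi) per axis in metres;
    ``fine_spacing`` is the uniform spacing inside the fine block.  The
    adjacent-cell stretching ratio must not exceed 1.1.  The outer faces may
    overshoot the requested domain by up to one (coarse) cell so the
    geometric stretching stays exact.
    """
    if stretch_ratio > MAX_STRETCH + 1e-12:
        raise ValueError(f"stretch ratio {stretch_ratio} exceeds {MAX_STRETCH}")
    if stretch_ratio < 1.0:
        raise ValueError("stretch ratio must be >= 1")
    if fine_spacing <= 0:
        raise ValueError("fine spacing must be positive")
    faces = [_axis_faces(domain[a][0], domain[a][1],
                         fine_block[a][0], fine_block[a][1],
                         fine_spacing, stretch_ratio) for a in range(3)]
    grid = StructuredGrid(*faces)
    if grid.max_stretch_ratio() > MAX_STRETCH + 1e-9:
        raise ValueError(
            f"generated grid stretch ratio {grid.max_stretch_ratio():.4f} "
            f"exceeds {MAX_STRETCH}")
    return grid


def uniform_periodic_grid(n: tuple[int, int, int],
                          lengths: tuple[float, float, float]) -> StructuredGrid:
    """Uniform fully periodic box (verification mode, e.g. Taylor-Green)."""
    faces = [np.linspace(0.0, lengths[a], n[a] + 1) for a in range(3)]
    return StructuredGrid(*faces, periodic=(True, True, True))
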