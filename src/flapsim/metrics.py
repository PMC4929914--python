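"""Kinematic descriptors of the reconstructed wing motion.

Chord angle ``psi``: the signed angle between a wing section's chord
(leading edge to trailing edge) and the flight direction, measured in the
parasagittal (X-Z) projection; positive when the leading edge is pitched up
relative to the trailing edge.

Effective angle of attack ``alpha``: the angle between the chord and the
relative wind, which combines the freestream with the translational
velocity of the section's leading edge; positive when the flow impinges on
the ventral surface.  With a motionless wing, ``alpha == psi``.

Twist is the distal-minus-proximal chord-angle difference ``psi_d - psi_p``
evaluated at spanwise stations r/R = 0.90 and 0.15.  Cycle summaries give
the mean tip speed (body-fixed frame), the advance ratio J = U/U_tip and
the downstroke / upstroke / cycle mean wing areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FlightConfig
from .geometry import WingMesh, segment_strokes
from .kinematics import RHAT_DISTAL, RHAT_PROXIMAL

__all__ = [
    "ChordSection",
    "KinematicsSeries",
    "CycleSummary",
    "extract_chord",
    "chord_angle",
    "effective_aoa",
    "compute_kinematics",
    "cycle_summaries",
]


@dataclass
class ChordSection:
    """A wing cross-section at spanwise station r_hat = r/R."""

    r_hat: float
    le_point: np.ndarray
    te_point: np.ndarray
    le_velocity: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_hat <= 1.0):
            raise ValueError(f"r_hat must lie in [0, 1], got {self.r_hat}")
        if np.linalg.norm(self.te_point - self.le_point) <= 0:
            raise ValueError("zero-length chord")

    @property
    def chord_vector(self) -> np.ndarray:
        return self.te_point - self.le_point

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.chord_vector))


@dataclass
class KinematicsSeries:
    """Per-sample kinematic descriptors plus stroke phase/labels."""

    table: pd.DataFrame  # one row per time sample

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()


@dataclass
class CycleSummary:
    U_tip: float
    J: float
    S_down: float
    S_up: float
    S_mean: float
    twist_extreme_down: float
    twist_extreme_up: float


def _boundary_polyline(mesh: WingMesh, frame: int) -> tuple[np.ndarray, np.ndarray]:
    pos = mesh.nodes[frame, mesh.boundary]
    vel = (mesh.node_velocities[frame, mesh.boundary]
           if mesh.node_velocities is not None
           else np.zeros_like(pos))
    return pos, vel


def extract_chord(mesh: WingMesh, r_hat: float, frame: int = 0) -> ChordSection:
    """Intersect the wing boundary with the plane of constant span station.

    The spanwise coordinate is measured along the instantaneous
    shoulder-to-tip axis.  The leading-edge crossing is taken from the LE
    half of the outline (shoulder to tip), the trailing-edge crossing from
    the TE half.  Velocities are interpolated with the same weights when the
    mesh carries nodal velocities.
    """
    if not (0.0 <= r_hat <= 1.0):
        raise ValueError(f"station r_hat={r_hat} lies outside the wing")
    pos, vel = _boundary_polyline(mesh, frame)
    # span axis: shoulder to wingtip, the tip taken as the farthest node on
    # the leading-edge side of the outline (the spar passes through both)
    le_side = np.nonzero(mesh.boundary_u <= 0.5)[0]
    if le_side.size < 3:
        le_side = np.arange(min(3, len(pos)))
    rel = pos - mesh.shoulder
    tip_le = int(le_side[np.argmax(np.linalg.norm(rel[le_side], axis=1))])
    axis = rel[tip_le] / np.linalg.norm(rel[tip_le])
    proj = rel @ axis
    tip_local = int(np.argmax(proj))
    R_inst = float(proj[tip_local])
    span = proj / R_inst  # per-node station

    target = r_hat

    def crossing(i0: int, i1: int) -> tuple[np.ndarray, np.ndarray] | None:
        """First boundary crossing of `target` on nodes i0..i1 (inclusive)."""
        idx = np.arange(i0, i1 + 1)
        s = span[idx]
        hits = np.nonzero((s[:-1] - target) * (s[1:] - target) <= 0)[0]
        best = None
        for h in hits:
            a, b = idx[h], idx[h + 1]
            denom = span[b] - span[a]
            w = 0.5 if abs(denom) < 1e-14 else (target - span[a]) / denom
            p = (1 - w) * pos[a] + w * pos[b]
            v = (1 - w) * vel[a] + w * vel[b]
            if best is None:
                best = (p, v)
        return best

    le = crossing(0, tip_local)
    te = crossing(tip_local, len(pos) - 1)
    if le is None or te is None:
        raise ValueError(f"station r_hat={r_hat} does not intersect the wing outline")
    return ChordSection(r_hat=r_hat, le_point=le[0], te_point=te[0],
                        le_velocity=le[1])


def chord_angle(section: ChordSection, config: FlightConfig) -> float:
    """Chord angle psi in degrees (parasagittal projection).

    Zero for a chord parallel to the flight direction with the leading edge
    upstream; positive when the leading edge is pitched up.
    """
    d = section.chord_vector
    dx, dz = d[0], d[2]
    if math.hypot(dx, dz) < 1e-12 * max(section.chord_length, 1e-30):
        raise ValueError("chord has no parasagittal projection")
    return math.degrees(math.atan2(-dz, dx))


def effective_aoa(section: ChordSection, config: FlightConfig) -> float:
    """Effective angle of attack alpha in degrees.

    The relative wind is the freestream (U in +X) minus the leading-edge
    velocity in the bird-fixed frame; alpha = psi + upwash angle of the
    relative wind, so a wing translating downward sees increased alpha and
    one translating upward can see negative alpha.
    """
    rel = np.array([config.U, 0.0, 0.0]) - section.le_velocity
    if np.linalg.norm([rel[0], rel[2]]) < 1e-9 * config.U:
        raise ValueError("relative flow speed vanishes; angle of attack undefined")
    gamma_up = math.degrees(math.atan2(rel[2], rel[0]))
    return chord_angle(section, config) + gamma_up


def compute_kinematics(mesh: WingMesh, config: FlightConfig) -> KinematicsSeries:
    """Per-sample chord angles, AoA, twist, tip speed and area for one wing.

    The mesh should carry nodal velocities (see
    :func:`flapsim.geometry.refine_in_time`).  Angle series are unwrapped so
    they are continuous in time, then wrapped back to (-180, 180].
    """
    if mesh.node_velocities is None:
        raise ValueError("mesh has no nodal velocities; refine_in_time first")
    n = mesh.n_frames
    psi_p = np.empty(n); psi_d = np.empty(n)
    alpha_p = np.empty(n); alpha_d = np.empty(n)
    tip_speed = np.empty(n); area = np.empty(n)
    tip_pos = np.empty((n, 3))
    for i in range(n):
        sec_p = extract_chord(mesh, RHAT_PROXIMAL, i)
        sec_d = extract_chord(mesh, RHAT_DISTAL, i)
        psi_p[i] = chord_angle(sec_p, config)
        psi_d[i] = chord_angle(sec_d, config)
        alpha_p[i] = effective_aoa(sec_p, config)
        alpha_d[i] = effective_aoa(sec_d, config)
        it = mesh.tip_index(i)
        tip_speed[i] = np.linalg.norm(mesh.node_velocities[i, it])
        tip_pos[i] = mesh.nodes[i, it]
        area[i] = mesh.area(i)

    def continuous(a):
        # unwrap to remove 360-degree jumps, then map into (-180, 180]
        w = np.rad2deg(np.unwrap(np.deg2rad(a)))
        r = np.mod(w, 360.0)
        r[r > 180.0] -= 360.0
        return r

    psi_p, psi_d = continuous(psi_p), continuous(psi_d)
    alpha_p, alpha_d = continuous(alpha_p), continuous(alpha_d)

    phase, down = segment_strokes(mesh.times, tip_pos, beta_deg=_beta_of(config))
    table = pd.DataFrame({
        "time_s": mesh.times,
        "phase": phase,
        "downstroke": down,
        "psi_p_deg": psi_p,
        "psi_d_deg": psi_d,
        "alpha_p_deg": alpha_p,
        "alpha_d_deg": alpha_d,
        "twist_deg": psi_d - psi_p,
        "tip_speed_m_s": tip_speed,
        "area_m2": area,
    })
    return KinematicsSeries(table=table)


def _beta_of(config: FlightConfig) -> float:
    return config.beta


def cycle_summaries(series: KinematicsSeries, config: FlightConfig) -> CycleSummary:
    """Whole-cycle kinematic summaries.

    U_tip is the time-mean tip speed in the body-fixed frame; J = U/U_tip;
    S_down and S_up are phase-conditional mean areas; S_mean is the cycle
    mean.  Twist extremes are reported per half-stroke.
    """
    t = series.table
    if len(t) == 0:
        raise ValueError("empty kinematics series")
    down = t["downstroke"].to_numpy()
    U_tip = float(t["tip_speed_m_s"].mean())
    tw = t["twist_deg"].to_numpy()
    area = t["area_m2"].to_numpy()
    return CycleSummary(
        U_tip=U_tip,
        J=config.U / U_tip,
        S_down=float(area[down].mean()) if down.any() else float("nan"),
        S_up=float(area[~down].mean()) if (~down).any() else float("nan"),
        S_mean=float(area.mean()),
        twist_extreme_down=float(tw[down].min()) if down.any() else float("nan"),
        twist_extreme_up=float(tw[~down].max()) if (~down).any() else float("nan"),
    )
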