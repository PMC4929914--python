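"""Synthetic wing kinematics: marker-trajectory generation and I/O.

The original study tracked nine painted markers per wing (five on the
leading edge, one at the wingtip, three on the trailing edge) at 1000 Hz in
a wind tunnel.  This module generates marker trajectories with the same
structure from an analytic kinematic program, so the reconstruction /
metrics / CFD stages are testable without the video data.

The wing is modelled as a membrane planform of span ``R`` with an elliptic
chord distribution, flapping about a stroke plane inclined at ``beta`` from
horizontal, pitching about its leading-edge spar with a spanwise-linear
twist, with optional out-of-plane deviation and cyclic area modulation.

Phase convention: phase 0 is the top of the stroke (start of downstroke);
phase in [0, 0.5) is downstroke, [0.5, 1) upstroke.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .config import FlightConfig

__all__ = [
    "MARKER_LABELS",
    "InvalidProgramError",
    "MarkerParseError",
    "KinematicProgram",
    "MarkerTrajectorySet",
    "default_kinematic_program",
    "sinusoidal_program",
    "generate_markers",
    "wing_surface_points",
    "wing_surface_velocities",
    "stroke_frame",
    "write_markers",
    "read_markers",
]

#: Anatomical marker order: leading edge root to tip, wingtip, trailing edge
#: tip to root.  This order is also the outline order used downstream.
MARKER_LABELS = ("LE1", "LE2", "LE3", "LE4", "LE5", "TIP", "TE1", "TE2", "TE3")

# spanwise stations r/R and chord fractions s (0=LE, 1=TE) of the 9 markers
_MARKER_RHAT = np.array([0.02, 0.25, 0.50, 0.75, 0.95, 1.0, 0.80, 0.45, 0.12])
_MARKER_S = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 1.0, 1.0, 1.0])

# stations at which the proximal / distal reference chords sit
RHAT_PROXIMAL = 0.15
RHAT_DISTAL = 0.90


class InvalidProgramError(ValueError):
    """A kinematic program violates its contract (e.g. non-periodic waveform)."""


class MarkerParseError(ValueError):
    """A marker table on disk is malformed."""


@dataclass
class KinematicProgram:
    """Prescribed wing motion as periodic functions of cycle phase.

    All waveforms take phase in cycles (period 1) and return degrees, except
    ``area_modulation`` which is a dimensionless scale with cycle-mean 1.
    ``twist_profile(phase, r_hat)`` is the local chord pitch angle (the chord
    angle psi of the section), positive leading-edge-up.
    """

    stroke_angle_waveform: Callable[[np.ndarray], np.ndarray]
    deviation_waveform: Callable[[np.ndarray], np.ndarray]
    twist_profile: Callable[[np.ndarray, np.ndarray], np.ndarray]
    area_modulation: Callable[[np.ndarray], np.ndarray]
    n_frames_per_cycle: int = 22
    n_cycles: int = 3
    noise_sd: float = 2.0e-4
    shoulder_halfwidth: float = 8.0e-3  # lateral shoulder offset from midline (m)

    def validate(self) -> None:
        phases = np.linspace(0.0, 0.9, 10)
        for name in ("stroke_angle_waveform", "deviation_waveform", "area_modulation"):
            fn = getattr(self, name)
            a = np.asarray(fn(phases), dtype=float)
            b = np.asarray(fn(phases + 1.0), dtype=float)
            if not np.allclose(a, b, atol=1e-9 * max(1.0, np.abs(a).max())):
                raise InvalidProgramError(f"{name} is not periodic with period 1")
        tw0 = np.asarray(self.twist_profile(phases, np.full_like(phases, 0.5)))
        tw1 = np.asarray(self.twist_profile(phases + 1.0, np.full_like(phases, 0.5)))
        if not np.allclose(tw0, tw1, atol=1e-9 * max(1.0, np.abs(tw0).max())):
            raise InvalidProgramError("twist_profile is not periodic with period 1")
        # cycle-mean of the area modulation must be 1 so the mean area is S_ref
        phi = np.linspace(0.0, 1.0, 720, endpoint=False)
        mean = float(np.mean(self.area_modulation(phi)))
        if abs(mean - 1.0) > 1e-3:
            raise InvalidProgramError(
                f"area_modulation cycle-mean is {mean:.5f}, must equal 1")
        if self.n_frames_per_cycle < 10:
            raise InvalidProgramError("need at least 10 frames per cycle")
        if self.n_cycles < 1:
            raise InvalidProgramError("need at least 1 cycle")
        if self.noise_sd < 0:
            raise InvalidProgramError("noise_sd must be non-negative")


@dataclass
class MarkerTrajectorySet:
    """Time-stamped 3-D coordinates of the 9 markers on each wing.

    ``coords`` has shape (n_times, n_wings, 9, 3) in metres, wings ordered
    as in ``sides`` (left first by convention).
    """

    times: np.ndarray
    coords: np.ndarray
    sides: tuple[str, ...] = ("left", "right")
    labels: tuple[str, ...] = MARKER_LABELS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2] != 9 or self.coords.shape[3] != 3:
            raise ValueError(
                f"coords must have shape (n_times, n_wings, 9, 3), got {self.coords.shape}")
        if self.coords.shape[0] != self.times.size:
            raise ValueError("times and coords disagree on the number of frames")
        if self.coords.shape[1] != len(self.sides):
            raise ValueError("sides and coords disagree on the number of wings")

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def wing(self, side: str) -> np.ndarray:
        """(n_times, 9, 3) coordinates of one wing."""
        return self.coords[:, self.sides.index(side)]

    def check_reach(self, config: FlightConfig, tolerance: float = 0.05) -> None:
        """Verify wingtip stays within R*(1+tolerance) of the shoulder."""
        tip = self.coords[:, :, MARKER_LABELS.index("TIP"), :]
        for iw, side in enumerate(self.sides):
            sh = np.array([0.0, (+1 if side == "left" else -1) * _shoulder_y(self), 0.0])
            reach = np.linalg.norm(tip[:, iw] - sh, axis=-1)
            if np.any(reach > config.R * (1.0 + tolerance)):
                raise ValueError(
                    f"{side} wingtip exceeds wing length: max reach "
                    f"{reach.max():.4g} m > {config.R * (1 + tolerance):.4g} m")


def _shoulder_y(mset: MarkerTrajectorySet) -> float:
    # estimate the lateral shoulder offset from the most proximal LE marker
    le1 = mset.coords[:, :, 0, 1]
    return float(np.abs(le1).mean())


# ---------------------------------------------------------------------------
# default program


def default_kinematic_program(
    Phi_deg: float = 102.5,
    n_frames_per_cycle: int = 22,
    n_cycles: int = 3,
    noise_sd: float = 2.0e-4,
) -> KinematicProgram:
    """Kinematic program emulating the fast-forward-flight wingbeat.

    Cosine stroke at the full stroke amplitude; no out-of-plane deviation;
    spanwise-linear twist shaped so the proximal chord angle stays positive
    through the cycle while the distal chord pitches leading-edge-down near
    mid-downstroke and strongly leading-edge-up near mid-upstroke, with the
    distal-minus-proximal twist peaking near -25 deg at mid-downstroke and
    +40 deg at mid-upstroke; sinusoidal area modulation giving downstroke /
    upstroke mean areas of about 5.34 / 5.03 cm^2 around the 5.18 cm^2 mean.
    """

    def stroke(phi):
        return 0.5 * Phi_deg * np.cos(2.0 * np.pi * np.asarray(phi, dtype=float))

    def deviation(phi):
        return np.zeros_like(np.asarray(phi, dtype=float))

    def twist(phi, r_hat):
        phi = np.asarray(phi, dtype=float)
        r_hat = np.asarray(r_hat, dtype=float)
        s = np.sin(2.0 * np.pi * phi)
        # proximal chord angle stays positive (and above the local upwash
        # angle, so the proximal AoA stays positive through the upstroke)
        psi_p = 17.0 + 3.0 * s
        tw = 7.5 - 32.5 * s               # distal-minus-proximal twist
        frac = (r_hat - RHAT_PROXIMAL) / (RHAT_DISTAL - RHAT_PROXIMAL)
        return psi_p + tw * frac

    # downstroke-conditional mean of sin(2*pi*phi) over [0, 0.5] is 2/pi, so
    # amplitude A gives S_down/S_ref = 1 + 2A/pi; A=0.04852 -> 5.34/5.03 cm^2
    amp = (5.34 / 5.18 - 1.0) * np.pi / 2.0

    def area(phi):
        return 1.0 + amp * np.sin(2.0 * np.pi * np.asarray(phi, dtype=float))

    return KinematicProgram(
        stroke_angle_waveform=stroke,
        deviation_waveform=deviation,
        twist_profile=twist,
        area_modulation=area,
        n_frames_per_cycle=n_frames_per_cycle,
        n_cycles=n_cycles,
        noise_sd=noise_sd,
    )


def sinusoidal_program(
    Phi_deg: float = 102.5,
    n_frames_per_cycle: int = 22,
    n_cycles: int = 3,
    noise_sd: float = 0.0,
    pitch_deg: float | Callable[[np.ndarray], np.ndarray] = 0.0,
) -> KinematicProgram:
    """Pure cosine stroke with uniform (untwisted) pitch; analytic reference.

    With no twist, deviation or noise, the tip speed relative to the body has
    peak pi*f*Phi*R and cycle mean 2*f*Phi*R.  ``pitch_deg`` may be a constant
    or a function of phase (uniform over the span), for pitch-recovery tests.
    """

    def stroke(phi):
        return 0.5 * Phi_deg * np.cos(2.0 * np.pi * np.asarray(phi, dtype=float))

    def deviation(phi):
        return np.zeros_like(np.asarray(phi, dtype=float))

    if callable(pitch_deg):
        def twist(phi, r_hat):
            return np.broadcast_to(
                np.asarray(pitch_deg(np.asarray(phi, dtype=float)), dtype=float),
                np.broadcast_shapes(np.shape(phi), np.shape(r_hat))).copy()
    else:
        def twist(phi, r_hat):
            return np.full(np.broadcast_shapes(np.shape(phi), np.shape(r_hat)),
                           float(pitch_deg))

    def area(phi):
        return np.ones_like(np.asarray(phi, dtype=float))

    return KinematicProgram(
        stroke_angle_waveform=stroke,
        deviation_waveform=deviation,
        twist_profile=twist,
        area_modulation=area,
        n_frames_per_cycle=n_frames_per_cycle,
        n_cycles=n_cycles,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# wing surface geometry


def stroke_frame(beta_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal stroke-plane frame (a_hat, y_hat, n_hat).

    ``a_hat`` is the in-plane downstroke direction (forward and down for a
    steep stroke plane), ``y_hat`` the lateral axis, ``n_hat`` the stroke
    plane normal.
    """
    b = math.radians(beta_deg)
    a_hat = np.array([-math.cos(b), 0.0, -math.sin(b)])
    y_hat = np.array([0.0, 1.0, 0.0])
    n_hat = np.cross(a_hat, y_hat)  # (sin b, 0, -cos b)
    return a_hat, y_hat, n_hat


def _chord_distribution(r_hat: np.ndarray, config: FlightConfig) -> np.ndarray:
    """Elliptic chord c(r_hat) with planform area S_ref (m)."""
    c0 = 4.0 * config.S_ref / (math.pi * config.R)
    r = np.clip(np.asarray(r_hat, dtype=float), 0.0, 1.0)
    return c0 * np.sqrt(np.maximum(0.0, 1.0 - r * r))


def wing_surface_points(
    config: FlightConfig,
    program: KinematicProgram,
    phase: float,
    r_hat: np.ndarray,
    s: np.ndarray,
    side: str = "left",
) -> np.ndarray:
    """Points on the analytic wing surface at a given cycle phase.

    ``r_hat`` and ``s`` broadcast together; returns (..., 3) coordinates in
    the bird-fixed frame.  The left wing is constructed explicitly; the right
    wing is its mirror image through the sagittal (y=0) plane.
    """
    r_hat = np.asarray(r_hat, dtype=float)
    s = np.asarray(s, dtype=float)
    r_hat, s = np.broadcast_arrays(r_hat, s)

    a_hat, y_hat, n_hat = stroke_frame(config.beta)
    theta = math.radians(float(program.stroke_angle_waveform(np.asarray(phase))))
    dev = math.radians(float(program.deviation_waveform(np.asarray(phase))))

    span0 = math.cos(theta) * y_hat - math.sin(theta) * a_hat
    span = math.cos(dev) * span0 + math.sin(dev) * n_hat

    # chord base direction: unit projection of +X perpendicular to the span
    x_hat = np.array([1.0, 0.0, 0.0])
    c0 = x_hat - np.dot(x_hat, span) * span
    c0 = c0 / np.linalg.norm(c0)
    sxc = np.cross(span, c0)

    # twist_profile prescribes the parasagittal (X-Z projected) chord angle
    # psi.  The chord direction d = cos(t) c0 + sin(t) sxc must satisfy
    # atan2(-d_z, d_x) = psi; expanding gives A cos t + B sin t = 0 with the
    # orientation condition cos(psi) d_x - sin(psi) d_z > 0, solved in
    # closed form.
    psi = np.radians(program.twist_profile(np.full_like(r_hat, phase), r_hat))
    sp, cp = np.sin(psi), np.cos(psi)
    A = sp * c0[0] + cp * c0[2]
    B = sp * sxc[0] + cp * sxc[2]
    t = np.arctan2(-A, B)
    d_x = np.cos(t) * c0[0] + np.sin(t) * sxc[0]
    d_z = np.cos(t) * c0[2] + np.sin(t) * sxc[2]
    t = np.where(cp * d_x - sp * d_z > 0, t, t + np.pi)
    chord_dir = (np.cos(t)[..., None] * c0 + np.sin(t)[..., None] * sxc)

    scale = float(program.area_modulation(np.asarray(phase)))
    chord = _chord_distribution(r_hat, config) * scale

    shoulder = np.array([0.0, program.shoulder_halfwidth, 0.0])
    pts = (shoulder
           + r_hat[..., None] * config.R * span
           + (s * chord)[..., None] * chord_dir)
    if side == "right":
        pts = pts * np.array([1.0, -1.0, 1.0])
    elif side != "left":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return pts


def wing_surface_velocities(
    config: FlightConfig,
    program: KinematicProgram,
    phase: float,
    r_hat: np.ndarray,
    s: np.ndarray,
    side: str = "left",
    dphi: float = 1e-5,
) -> np.ndarray:
    """Body-frame surface velocities (m/s) by central phase differencing."""
    p_plus = wing_surface_points(config, program, phase + dphi, r_hat, s, side)
    p_minus = wing_surface_points(config, program, phase - dphi, r_hat, s, side)
    return (p_plus - p_minus) * (config.f_beat / (2.0 * dphi))


# ---------------------------------------------------------------------------
# marker generation and I/O


def generate_markers(
    config: FlightConfig,
    program: KinematicProgram,
    seed: int = 0,
) -> MarkerTrajectorySet:
    """Generate the 9-marker trajectories for both wings.

    Markers lie on the analytic wing surface swept through the program's
    waveforms; left and right wings are exactly mirror-symmetric before
    noise.  Isotropic Gaussian noise of ``program.noise_sd`` metres is added
    with a seeded generator; ``noise_sd=0`` gives a deterministic output
    independent of the seed.
    """
    program.validate()
    n = program.n_frames_per_cycle * program.n_cycles
    times = np.arange(n) / (program.n_frames_per_cycle * config.f_beat)
    phases = times * config.f_beat

    coords = np.empty((n, 2, 9, 3))
    for it, phi in enumerate(phases):
        left = wing_surface_points(config, program, float(phi),
                                   _MARKER_RHAT, _MARKER_S, side="left")
        coords[it, 0] = left
        coords[it, 1] = left * np.array([1.0, -1.0, 1.0])

    if program.noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, program.noise_sd, size=coords.shape)

    return MarkerTrajectorySet(times=times, coords=coords)


def write_markers(mset: MarkerTrajectorySet, path: str | Path) -> None:
    """Write a marker set as a tidy CSV.

    Columns: time_s, wing, marker_id, x_m, y_m, z_m; one row per marker per
    frame, frames in time order, wings and markers in canonical order.
    """
    n_t, n_w = mset.coords.shape[:2]
    rows = {
        "time_s": np.repeat(mset.times, n_w * 9),
        "wing": np.tile(np.repeat(list(mset.sides), 9), n_t),
        "marker_id": np.tile(list(mset.labels), n_t * n_w),
        "x_m": mset.coords[..., 0].ravel(),
        "y_m": mset.coords[..., 1].ravel(),
        "z_m": mset.coords[..., 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12e")


def read_markers(path: str | Path) -> MarkerTrajectorySet:
    """Read a marker CSV written by :func:`write_markers`.

    Raises :class:`MarkerParseError` for malformed files, naming the frame
    or column at fault.  Round-trips with :func:`write_markers` to 1e-12 m.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise MarkerParseError(f"{path}: empty marker file") from exc
    required = {"time_s", "wing", "marker_id", "x_m", "y_m", "z_m"}
    missing = required - set(df.columns)
    if missing:
        raise MarkerParseError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise MarkerParseError(f"{path}: marker table has no rows")
    for col in ("x_m", "y_m", "z_m"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise MarkerParseError(
                f"{path}: non-numeric value in column {col} at data row {bad[0]}")

    sides = tuple(dict.fromkeys(df["wing"]))
    times = np.array(sorted(df["time_s"].unique()))
    coords = np.empty((times.size, len(sides), 9, 3))
    grouped = df.set_index(["time_s", "wing", "marker_id"]).sort_index()
    for it, t in enumerate(times):
        for iw, side in enumerate(sides):
            try:
                block = grouped.loc[(t, side)]
            except KeyError as exc:
                raise MarkerParseError(
                    f"{path}: frame t={t} missing wing {side!r}") from exc
            if len(block) != 9 or set(block.index) != set(MARKER_LABELS):
                raise MarkerParseError(
                    f"{path}: frame t={t} wing {side!r} has {len(block)} markers, "
                    "expected the 9 canonical markers")
            coords[it, iw] = block.loc[list(MARKER_LABELS),
                                       ["x_m", "y_m", "z_m"]].to_numpy()
    return MarkerTrajectorySet(times=times, coords=coords, sides=sides)
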