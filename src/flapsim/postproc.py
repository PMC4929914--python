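"""Aerodynamic force, power and performance post-processing.

Forces on each surface are normalized by the flight dynamic pressure and
the reference single-wing area S:

    C_Z = F_Z / (1/2 rho U^2 S),   C_T = F_T / (1/2 rho U^2 S),

with thrust F_T = -F_X (X pointing downstream).  Body lift/drag use the
same normalization.  The aerodynamic power coefficient of one wing is

    C_P = (integral of f . u dA) / (1/2 rho U^3 S),

where f is the surface stress and u the surface velocity in the bird-fixed
frame.  Derived performance: total aerodynamic power P = 1/2 C_P rho U^3
(2S) for the wing pair, total vertical force F_total = 1/2 (2 C_Z + C_Z,b)
rho U^2 S compared against body weight, and thrust versus body drag
2 C_T / C_D,b.  S is always the fixed reference area, not the
instantaneous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FlightConfig

__all__ = [
    "ForceSeries",
    "StrokeAverages",
    "DerivedPerformance",
    "integrate_forces",
    "power_numerator",
    "power_coefficient",
    "force_coefficients",
    "stroke_averages",
    "performance_summary",
    "grid_convergence_table",
    "format_summary_table",
]


def integrate_forces(tractions: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Net force vector (N): sum of per-triangle traction times area."""
    tractions = np.asarray(tractions, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if tractions.ndim != 2 or tractions.shape[1] != 3:
        raise ValueError(f"tractions must be (n, 3), got {tractions.shape}")
    if areas.shape != (tractions.shape[0],):
        raise ValueError("areas length does not match triangle count")
    return (tractions * areas[:, None]).sum(axis=0)


def power_numerator(tractions: np.ndarray, velocities: np.ndarray,
                    areas: np.ndarray) -> float:
    """Integral of f . u dA (W) over one surface.

    ``velocities`` are per-triangle surface velocities in the bird-fixed
    frame (the freestream excluded).
    """
    tractions = np.asarray(tractions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if velocities.shape != tractions.shape:
        raise ValueError("velocity/traction frame or shape mismatch")
    return float(((tractions * velocities).sum(axis=1) * areas).sum())


def _qS(config: FlightConfig) -> float:
    return 0.5 * config.rho * config.U ** 2 * config.S_ref


def force_coefficients(force: np.ndarray, config: FlightConfig) -> dict:
    """C_Z, C_T (and C_Y) from a force vector on one surface."""
    qS = _qS(config)
    return {
        "C_Z": float(force[2]) / qS,
        "C_T": float(-force[0]) / qS,
        "C_Y": float(force[1]) / qS,
    }


def power_coefficient(power_w: float, config: FlightConfig) -> float:
    """C_P from the f.u surface integral of one wing (W)."""
    return power_w / (0.5 * config.rho * config.U ** 3 * config.S_ref)


@dataclass
class ForceSeries:
    """Per-time-step force/power coefficients for every surface.

    ``table`` columns: time_s, phase, downstroke, then per surface
    (wing_left, wing_right, body) the coefficient columns that apply
    (C_Z/C_T/C_Y for all, C_P for wings; the body's C_T is reported as
    drag C_D_b = -C_T).
    """

    table: pd.DataFrame

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()

    def has_wings(self) -> bool:
        return "wing_left_C_Z" in self.table.columns


@dataclass
class StrokeAverages:
    """Down/up/whole-cycle means of one coefficient column."""

    down: float
    up: float
    cycle: float

    @property
    def down_up_ratio(self) -> float:
        return self.down / self.up if self.up != 0 else math.inf


@dataclass
class DerivedPerformance:
    """Cycle-resolved performance summary (Table-3-style)."""

    C_Z: StrokeAverages | None
    C_T: StrokeAverages | None
    C_P: StrokeAverages | None
    C_Z_b: StrokeAverages | None
    C_D_b: StrokeAverages | None
    P_aero_W: float | None = None
    P_mass_specific_W_kg: float | None = None
    weight_support_frac: float | None = None
    thrust_to_body_drag: float | None = None
    body_share: float | None = None
    body_weight_frac: float | None = None


def stroke_averages(series: ForceSeries, column: str) -> StrokeAverages:
    """Time-weighted down/up/cycle averages of one coefficient column."""
    t = series.table
    if column not in t.columns:
        raise ValueError(f"column {column!r} missing from force series")
    if "downstroke" not in t.columns:
        raise ValueError("force series carries no stroke segmentation")
    vals = t[column].to_numpy()
    down = t["downstroke"].to_numpy()
    if not down.any() or down.all():
        raise ValueError("series does not contain both half-strokes")
    return StrokeAverages(
        down=float(vals[down].mean()),
        up=float(vals[~down].mean()),
        cycle=float(vals.mean()),
    )


def performance_summary(
    config: FlightConfig,
    C_Z: float,
    C_T: float,
    C_P: float,
    C_Z_b: float,
    C_D_b: float,
) -> dict:
    """Derived performance scalars from whole-cycle mean coefficients.

    P is the aerodynamic power of the wing pair; weight support compares
    the total vertical force (two wings plus body) against body weight;
    ``body_share`` is the body's fraction of the total vertical force and
    ``body_weight_frac`` the body lift against body weight.
    """
    if config.M <= 0 or config.U <= 0:
        raise ValueError("mass and speed must be positive")
    q = 0.5 * config.rho * config.U ** 2 * config.S_ref
    P = 0.5 * C_P * config.rho * config.U ** 3 * (2.0 * config.S_ref)
    F_total = 0.5 * (2.0 * C_Z + C_Z_b) * config.rho * config.U ** 2 * config.S_ref
    total_cz = 2.0 * C_Z + C_Z_b
    return {
        "P_aero_W": P,
        "P_mass_specific_W_kg": P / config.M,
        "weight_support_frac": F_total / config.weight,
        "thrust_to_body_drag": (2.0 * C_T) / C_D_b if C_D_b else math.inf,
        "body_share": C_Z_b / total_cz if total_cz else math.nan,
        "body_weight_frac": (C_Z_b * q) / config.weight,
    }


def derived_performance(series: ForceSeries, config: FlightConfig,
                        body_only: bool = False) -> DerivedPerformance:
    """Stroke averages for every coefficient plus the derived scalars.

    Wing coefficients average the left and right wing (mirror-symmetric
    kinematics make them identical up to solver tolerance).
    """
    t = series.table
    if not body_only:
        cz = _mean_cols(series, ["wing_left_C_Z", "wing_right_C_Z"])
        ct = _mean_cols(series, ["wing_left_C_T", "wing_right_C_T"])
        cp = _mean_cols(series, ["wing_left_C_P", "wing_right_C_P"])
        sa_cz = _stroke_avg(t, cz)
        sa_ct = _stroke_avg(t, ct)
        sa_cp = _stroke_avg(t, cp)
    else:
        sa_cz = sa_ct = sa_cp = None
    sa_czb = _stroke_avg(t, t["body_C_Z"].to_numpy())
    sa_cdb = _stroke_avg(t, t["body_C_D"].to_numpy())
    out = DerivedPerformance(C_Z=sa_cz, C_T=sa_ct, C_P=sa_cp,
                             C_Z_b=sa_czb, C_D_b=sa_cdb)
    if not body_only:
        perf = performance_summary(config, sa_cz.cycle, sa_ct.cycle,
                                   sa_cp.cycle, sa_czb.cycle, sa_cdb.cycle)
        out.P_aero_W = perf["P_aero_W"]
        out.P_mass_specific_W_kg = perf["P_mass_specific_W_kg"]
        out.weight_support_frac = perf["weight_support_frac"]
        out.thrust_to_body_drag = perf["thrust_to_body_drag"]
        out.body_share = perf["body_share"]
        out.body_weight_frac = perf["body_weight_frac"]
    return out


def _mean_cols(series: ForceSeries, cols: list[str]) -> np.ndarray:
    return np.mean([series[c] for c in cols], axis=0)


def _stroke_avg(table: pd.DataFrame, vals: np.ndarray) -> StrokeAverages:
    down = table["downstroke"].to_numpy()
    return StrokeAverages(down=float(vals[down].mean()),
                          up=float(vals[~down].mean()),
                          cycle=float(vals.mean()))


def grid_convergence_table(coarse: dict[str, float],
                           fine: dict[str, float]) -> pd.DataFrame:
    """Force-coefficient comparison between two grids.

    Rows: coarse value, fine value, percent difference relative to the
    fine-grid value for each coefficient key present in both.
    """
    keys = [k for k in coarse if k in fine]
    diff = {k: abs(fine[k] - coarse[k]) / abs(fine[k]) * 100.0 for k in keys}
    return pd.DataFrame(
        {k: [coarse[k], fine[k], diff[k]] for k in keys},
        index=["baseline", "fine mesh", "difference (%)"])


def format_summary_table(perf: DerivedPerformance) -> str:
    """Plain-text summary mirroring the stroke-resolved coefficient table."""
    rows = []
    header = f"{'':24s}{'C_Z':>10s}{'C_T':>10s}{'C_P':>10s}{'C_Z,b':>10s}{'C_D,b':>10s}"
    rows.append(header)

    def line(label, attr):
        vals = []
        for name in ("C_Z", "C_T", "C_P", "C_Z_b", "C_D_b"):
            sa = getattr(perf, name)
            vals.append("      --  " if sa is None
                        else f"{getattr(sa, attr):10.3f}")
        return f"{label:24s}" + "".join(vals)

    rows.append(line("whole cycle", "cycle"))
    rows.append(line("downstroke", "down"))
    rows.append(line("upstroke", "up"))
    rows.append(line("down-/upstroke ratio", "down_up_ratio"))
    if perf.P_aero_W is not None:
        rows.append("")
        rows.append(f"aerodynamic power P       : {perf.P_aero_W * 1e3:8.1f} mW")
        rows.append(f"mass-specific power       : {perf.P_mass_specific_W_kg:8.1f} W/kg")
        rows.append(f"weight support            : {perf.weight_support_frac * 100:8.1f} %")
        rows.append(f"thrust / body drag        : {perf.thrust_to_body_drag * 100:8.1f} %")
        rows.append(f"body share of lift        : {perf.body_share * 100:8.1f} %")
        rows.append(f"body lift / weight        : {perf.body_weight_frac * 100:8.1f} %")
    return "\n".join(rows)
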