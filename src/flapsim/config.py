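"""Flight and physics configuration.

All downstream stages (marker synthesis, surface reconstruction, kinematic
metrics, the flow solver and the force post-processing) share a single
:class:`FlightConfig` carrying the scalar flight parameters of the bird and
the fluid.  The default instance describes a female calliope hummingbird
(*Selasphorus calliope*) in fast forward flight at 8.3 m/s.

Coordinate frame (bird-fixed, wind-tunnel style): +X downstream along the
freestream, +Z vertically up, +Y to the bird's left; origin at the shoulder
midpoint.  Thrust is the force in -X.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Mapping

__all__ = ["FlightConfig", "default_calliope_config"]


@dataclass(frozen=True)
class FlightConfig:
    """Scalar flight/fluid parameters.

    Parameters
    ----------
    U : float
        Forward flight speed (m/s).
    rho : float
        Air density (kg/m^3).
    M : float
        Body mass (kg).
    g : float
        Gravitational acceleration (m/s^2).
    f_beat : float
        Wingbeat frequency (Hz).
    beta : float
        Stroke-plane angle from horizontal (degrees).
    Phi : float
        Stroke amplitude (degrees).
    R : float
        Wing length, shoulder to tip (m).
    S_ref : float
        Reference single-wing planform area (m^2).
    chi_b : float
        Body pitch angle from horizontal (degrees).
    dt : float
        Simulation time step (s).
    Re, nu : float, optional
        Reynolds number based on mean chord, Re = U*cbar/nu, and kinematic
        viscosity (m^2/s).  Exactly one must be given; the other is derived.
    """

    U: float
    rho: float
    M: float
    g: float
    f_beat: float
    beta: float
    Phi: float
    R: float
    S_ref: float
    chi_b: float
    dt: float
    Re: float | None = None
    nu: float | None = None

    def __post_init__(self) -> None:
        positive = {
            "U": self.U, "rho": self.rho, "M": self.M, "g": self.g,
            "f_beat": self.f_beat, "R": self.R, "S_ref": self.S_ref,
            "dt": self.dt,
        }
        for name, value in positive.items():
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (0.0 <= self.beta <= 90.0):
            raise ValueError(f"beta must lie in [0, 90] degrees, got {self.beta!r}")
        if not (0.0 < self.Phi < 180.0):
            raise ValueError(f"Phi must lie in (0, 180) degrees, got {self.Phi!r}")
        if (self.Re is None) == (self.nu is None):
            raise ValueError("exactly one of Re or nu must be supplied")
        if self.Re is None:
            object.__setattr__(self, "Re", self.U * self.cbar / self.nu)
        else:
            if not (self.Re > 0):
                raise ValueError("Re must be strictly positive")
            object.__setattr__(self, "nu", self.U * self.cbar / self.Re)

    @property
    def cbar(self) -> float:
        """Mean chord length, S_ref / R (m)."""
        return self.S_ref / self.R

    @property
    def T_beat(self) -> float:
        """Wingbeat period 1/f_beat (s)."""
        return 1.0 / self.f_beat

    @property
    def steps_per_cycle(self) -> int:
        """Number of time steps per wingbeat cycle at the configured dt."""
        return round(self.T_beat / self.dt)

    @property
    def beta_rad(self) -> float:
        return math.radians(self.beta)

    @property
    def Phi_rad(self) -> float:
        return math.radians(self.Phi)

    @property
    def weight(self) -> float:
        """Body weight M*g (N)."""
        return self.M * self.g

    def replace(self, **changes: Any) -> "FlightConfig":
        """Return a copy with some fields replaced.

        `Re` and `nu` are re-derived: pass one of them (or neither) but not
        both, as in the constructor.
        """
        d = dataclasses.asdict(self)
        if "Re" in changes and "nu" not in changes:
            d["nu"] = None
        elif "nu" in changes and "Re" not in changes:
            d["Re"] = None
        elif "Re" not in changes and "nu" not in changes:
            d["nu"] = None  # keep Re, re-derive nu for consistency
        d.update(changes)
        return FlightConfig(**d)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FlightConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown FlightConfig fields: {sorted(unknown)}")
        missing = {f.name for f in dataclasses.fields(cls)
                   if f.default is dataclasses.MISSING} - set(data)
        if missing:
            raise ValueError(f"missing FlightConfig fields: {sorted(missing)}")
        return cls(**dict(data))


def default_calliope_config() -> FlightConfig:
    """Calliope hummingbird in fast forward flight.

    Morphology and kinematics of the wind-tunnel study subject: flight speed
    8.3 m/s, body mass 2.8 g, wingbeat frequency 45.5 Hz, stroke plane angle
    67.9 deg, stroke amplitude 102.5 deg, wing length 4.51 cm, mean single
    wing area 5.18 cm^2, body angle 12 deg.  The flow model runs at Re = 3000
    (based on mean chord) with a 5 microsecond production time step.  Air
    density 1.2 kg/m^3 and g = 9.81 m/s^2.
    """
    return FlightConfig(
        U=8.3,
        rho=1.2,
        M=2.8e-3,
        g=9.81,
        f_beat=45.5,
        beta=67.9,
        Phi=102.5,
        R=4.51e-2,
        S_ref=5.18e-4,
        chi_b=12.0,
        dt=5e-6,
        Re=3000.0,
    )
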