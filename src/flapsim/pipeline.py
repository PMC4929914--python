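"""End-to-end pipelines: kinematics reconstruction and flow simulation.

``run_kinematics_pipeline`` chains marker generation (or reading), wing
reconstruction, temporal refinement and kinematic metrics.

``run_flow_pipeline`` runs the immersed-boundary Navier-Stokes simulation
of the flapping wings and body at a chosen grid profile, samples surface
tractions into force/power coefficient series, and derives the
stroke-resolved performance summary.  ``mode='isolated_body'`` removes the
wings while keeping the identical body, orientation and grid — the paired
experiment separating wing-body interaction from bare-body aerodynamics.

Desk-scale profiles run the same physics as the production-scale
configuration at reduced Reynolds number and resolution; they support
qualitative (directional) conclusions, not production force magnitudes.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .config import FlightConfig, default_calliope_config
from .geometry import build_body, refine_in_time, reconstruct_wing_series
from .kinematics import (KinematicProgram, MarkerTrajectorySet,
                         default_kinematic_program, generate_markers,
                         read_markers, write_markers)
from .metrics import compute_kinematics, cycle_summaries
from .postproc import (ForceSeries, derived_performance,
                       force_coefficients, format_summary_table,
                       integrate_forces, power_coefficient, power_numerator)
from .solver.core import IBNSolver, SolverSettings
from .solver.grid import build_grid
from .solver.ib import ImmersedBoundary, MovingSurface
from .solver.traction import surface_traction

__all__ = [
    "GridProfile", "PROFILES", "RunManifest",
    "run_kinematics_pipeline", "run_flow_pipeline",
    "ProductionOptInError",
]


class ProductionOptInError(RuntimeError):
    """Raised when the production-emulation profile runs without opt-in."""


@dataclass
class GridProfile:
    """Grid/resolution bundle for the flow solver."""

    name: str
    domain: tuple            # ((x0,x1),(y0,y1),(z0,z1)) metres
    fine_block: tuple
    fine_spacing_chords: float   # fine spacing as a fraction of mean chord
    stretch_ratio: float
    Re: float
    wing_elements: int
    n_cycles: int
    discard_cycles: int
    cfl_target: float = 0.4
    sample_every: int = 4


PROFILES: dict[str, GridProfile] = {
    # scaled-down single-CPU profile used by the automated verification runs
    "mini": GridProfile(
        name="mini",
        domain=((-0.10, 0.15), (-0.095, 0.095), (-0.085, 0.075)),
        fine_block=((-0.048, 0.050), (-0.058, 0.058), (-0.042, 0.042)),
        fine_spacing_chords=1.0 / 4.5,
        stretch_ratio=1.09,
        Re=300.0,
        wing_elements=300,
        n_cycles=2,
        discard_cycles=1,
    ),
    # desk profile: chord/16 fine spacing, Re=300 (hours on one CPU)
    "desk": GridProfile(
        name="desk",
        domain=((-0.10, 0.15), (-0.10, 0.10), (-0.09, 0.07)),
        fine_block=((-0.05, 0.055), (-0.06, 0.06), (-0.045, 0.045)),
        fine_spacing_chords=1.0 / 16.0,
        stretch_ratio=1.08,
        Re=300.0,
        wing_elements=1335,
        n_cycles=3,
        discard_cycles=1,
    ),
    # documents the production-scale configuration (25x20x16 cm domain,
    # ~1/60 cm spacing, Re=3000, seven cycles); requires explicit opt-in
    "production-emulation": GridProfile(
        name="production-emulation",
        domain=((-0.115, 0.135), (-0.10, 0.10), (-0.09, 0.07)),
        fine_block=((-0.06, 0.06), (-0.065, 0.065), (-0.05, 0.05)),
        fine_spacing_chords=1.0 / 69.0,   # ~1/60 cm
        stretch_ratio=1.05,
        Re=3000.0,
        wing_elements=1335,
        n_cycles=7,
        discard_cycles=1,
    ),
}


@dataclass
class RunManifest:
    """Reproducibility record: a manifest plus the packaged inputs fully
    determines every output for fixed seeds and serial execution."""

    kind: str
    version: str
    seed: int
    config: dict
    profile: str | None = None
    mode: str | None = None
    grid_shape: tuple | None = None
    steps_per_cycle: int | None = None
    wall_time_s: float | None = None
    outputs: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


# ---------------------------------------------------------------------------
# kinematics pipeline


def run_kinematics_pipeline(
    config: FlightConfig | None = None,
    program: KinematicProgram | None = None,
    seed: int = 0,
    markers: MarkerTrajectorySet | str | Path | None = None,
    target_elements: int = 1335,
    refinement: int = 4,
    outdir: str | Path | None = None,
):
    """Markers -> wing meshes -> kinematic metrics and cycle summaries.

    Returns a dict with the marker set, reconstructed/refined left and
    right wing meshes, per-sample metrics tables and cycle summaries.
    """
    t0 = _time.perf_counter()
    config = config or default_calliope_config()
    if markers is None:
        program = program or default_kinematic_program(Phi_deg=config.Phi)
        mset = generate_markers(config, program, seed=seed)
    elif isinstance(markers, (str, Path)):
        mset = read_markers(markers)
    else:
        mset = markers
    mset.check_reach(config)

    results = {"markers": mset, "config": config}
    for side in ("left", "right"):
        mesh = reconstruct_wing_series(mset, side, target_elements)
        mesh = refine_in_time(mesh, refinement)
        series = compute_kinematics(mesh, config)
        summary = cycle_summaries(series, config)
        results[f"mesh_{side}"] = mesh
        results[f"metrics_{side}"] = series
        results[f"summary_{side}"] = summary

    manifest = RunManifest(
        kind="kinematics", version=__version__, seed=seed,
        config=config.to_dict(),
        wall_time_s=_time.perf_counter() - t0)
    results["manifest"] = manifest

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_markers(mset, outdir / "markers.csv")
        for side in ("left", "right"):
            results[f"metrics_{side}"].table.to_csv(
                outdir / f"metrics_{side}.csv", index=False)
            s = results[f"summary_{side}"]
            pd.DataFrame([dataclasses.asdict(s)]).to_csv(
                outdir / f"summary_{side}.csv", index=False)
        manifest.outputs = {"markers": "markers.csv",
                            "metrics": "metrics_{side}.csv"}
        manifest.write(outdir / "manifest.json")
    return results


# ---------------------------------------------------------------------------
# flow pipeline


def _wing_surfaces(config: FlightConfig, profile: GridProfile,
                   seed: int) -> list[MovingSurface]:
    program = default_kinematic_program(
        Phi_deg=config.Phi, n_frames_per_cycle=22, n_cycles=1, noise_sd=0.0)
    mset = generate_markers(config, program, seed=seed)
    surfaces = []
    for side in ("left", "right"):
        mesh = reconstruct_wing_series(mset, side, profile.wing_elements)
        surfaces.append(MovingSurface(mesh))
    return surfaces


def run_flow_pipeline(
    config: FlightConfig | None = None,
    profile: str | GridProfile = "mini",
    mode: str = "full",
    seed: int = 0,
    opt_in_production: bool = False,
    outdir: str | Path | None = None,
    n_cycles: int | None = None,
    progress: bool = False,
) -> dict:
    """Simulate the flapping wings (and body) and post-process forces.

    ``mode`` is ``'full'`` (wings + body) or ``'isolated_body'`` (same
    body, orientation and grid, wings removed).  Returns a dict with the
    force series, the derived performance, the solver and grid, and the
    manifest.
    """
    t0 = _time.perf_counter()
    config = config or default_calliope_config()
    if isinstance(profile, str):
        if profile == "production-emulation" and not opt_in_production:
            raise ProductionOptInError(
                "the production-emulation profile needs hundreds of millions "
                "of grid points and days of single-CPU time; pass "
                "opt_in_production=True to run it anyway")
        profile = PROFILES[profile]
    if mode not in ("full", "isolated_body"):
        raise ValueError(f"unknown mode {mode!r}")

    run_cfg = config.replace(Re=profile.Re)
    h = run_cfg.cbar * profile.fine_spacing_chords
    grid = build_grid(profile.domain, profile.fine_block, h,
                      profile.stretch_ratio)

    # time step: integer steps per wingbeat cycle at the CFL target,
    # conservatively against inflow + peak tip speed
    u_scale = run_cfg.U + np.pi * run_cfg.f_beat * run_cfg.Phi_rad * run_cfg.R
    steps_per_cycle = int(np.ceil(run_cfg.T_beat
                                  / (profile.cfl_target * h / u_scale)))
    dt = run_cfg.T_beat / steps_per_cycle
    run_cfg = run_cfg.replace(dt=dt)

    body = build_body(run_cfg)
    body_tm = body.as_trimesh()
    wings = _wing_surfaces(run_cfg, profile, seed) if mode == "full" else []
    ib = ImmersedBoundary(grid, body=body_tm, moving=wings)

    settings = SolverSettings(dt=dt, nu=run_cfg.nu, rho=run_cfg.rho,
                              U_inflow=run_cfg.U, poisson_tol=3e-5,
                              cfl_limit=1.0)
    solver = IBNSolver(grid, settings)
    solver.set_forcing(ib)
    solver.initialize_uniform(run_cfg.U)

    n_cyc = n_cycles if n_cycles is not None else profile.n_cycles
    total_steps = n_cyc * steps_per_cycle
    sample_from = profile.discard_cycles * steps_per_cycle
    body_areas = body_tm.area_faces
    rows = []
    for istep in range(total_steps):
        diag = solver.step()
        t = solver.state.time
        if istep >= sample_from and (istep + 1) % profile.sample_every == 0:
            rows.append(_sample_forces(solver, grid, run_cfg, body_tm,
                                       body_areas, wings, t))
        if progress and (istep + 1) % 50 == 0:
            print(f"  step {istep + 1}/{total_steps} t={t * 1e3:.2f} ms "
                  f"cfl={diag['cfl']:.2f} div={diag['max_divergence']:.2e} "
                  f"pits={diag['poisson_iterations']}")
    table = pd.DataFrame(rows)
    series = ForceSeries(table=table)
    perf = derived_performance(series, run_cfg,
                               body_only=(mode == "isolated_body"))

    manifest = RunManifest(
        kind="flow", version=__version__, seed=seed,
        config=run_cfg.to_dict(), profile=profile.name, mode=mode,
        grid_shape=grid.shape, steps_per_cycle=steps_per_cycle,
        wall_time_s=_time.perf_counter() - t0)

    results = {"series": series, "performance": perf, "solver": solver,
               "grid": grid, "config": run_cfg, "manifest": manifest,
               "wings": wings, "body": body_tm}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"forces_{mode}.csv", index=False)
        (outdir / f"summary_{mode}.txt").write_text(
            format_summary_table(perf) + "\n")
        manifest.outputs = {"forces": f"forces_{mode}.csv",
                            "summary": f"summary_{mode}.txt"}
        manifest.write(outdir / f"manifest_{mode}.json")
    return results


def _sample_forces(solver, grid, config, body_tm, body_areas, wings, t):
    """One force/power sample row across all surfaces."""
    st = solver.state
    phase = float(np.mod(t * config.f_beat, 1.0))
    row = {"time_s": t, "phase": phase, "downstroke": phase < 0.5}
    # body: closed surface, outside-sampled
    trac_b = surface_traction(st, grid, body_tm.vertices, body_tm.faces,
                              config.rho, config.nu, closed=True)
    Fb = integrate_forces(trac_b, body_areas)
    cb = force_coefficients(Fb, config)
    row["body_C_Z"] = cb["C_Z"]
    row["body_C_D"] = -cb["C_T"]       # drag is +X force
    row["body_C_Y"] = cb["C_Y"]
    for surf, name in zip(wings, ("wing_left", "wing_right")):
        verts = surf.positions(t)
        vels = surf.velocities(t)
        tm_faces = surf.faces
        a, b, c = (verts[tm_faces[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        trac = surface_traction(st, grid, verts, tm_faces,
                                config.rho, config.nu, closed=False)
        F = integrate_forces(trac, areas)
        cw = force_coefficients(F, config)
        tri_vel = vels[tm_faces].mean(axis=1)
        # aerodynamic power consumed: stress exerted by the wing on the
        # fluid (minus the fluid-on-wing traction) dotted with wing velocity
        P = power_numerator(-trac, tri_vel, areas)
        row[f"{name}_C_Z"] = cw["C_Z"]
        row[f"{name}_C_T"] = cw["C_T"]
        row[f"{name}_C_Y"] = cw["C_Y"]
        row[f"{name}_C_P"] = power_coefficient(P, config)
    return row
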