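import numpy as np
import pytest

from flapsim.geometry import reconstruct_wing_series, refine_in_time, triangulate_wing, reconstruct_outline
from flapsim.kinematics import generate_markers, sinusoidal_program
from flapsim.metrics import (ChordSection, chord_angle, compute_kinematics,
                             cycle_summaries, effective_aoa, extract_chord)


def _section(le, te, vel=(0, 0, 0)):
    return ChordSection(r_hat=0.5, le_point=np.array(le, float),
                        te_point=np.array(te, float),
                        le_velocity=np.array(vel, float))


def _planform_mesh(R, chord_of_rhat, n=120):
    """Static WingMesh whose boundary densely samples an analytic planform
    (straight leading-edge spar along +y, trailing edge at x=c(r/R))."""
    from flapsim.geometry import WingMesh
    r = np.linspace(0.0, 1.0, n)
    le = np.column_stack([np.zeros(n), r * R, np.zeros(n)])
    te = np.column_stack([chord_of_rhat(r[::-1]), r[::-1] * R, np.zeros(n)])
    boundary = np.vstack([le, te[1:]])
    m = len(boundary)
    tri = np.column_stack([np.zeros(m - 2, dtype=int),
                           np.arange(1, m - 1), np.arange(2, m)])
    return WingMesh(times=np.array([0.0]), nodes=boundary[None],
                    triangles=tri, side="left", shoulder=np.zeros(3),
                    boundary=np.arange(m),
                    boundary_u=np.linspace(0, 1, m, endpoint=False),
                    node_velocities=np.zeros((1, m, 3)))


class TestChordAngle:
    def test_zero_for_streamwise_chord(self, config):
        sec = _section([0, 0, 0], [0.01, 0, 0])
        assert chord_angle(sec, config) == pytest.approx(0.0, abs=1e-12)

    def test_positive_45_for_leading_edge_up(self, config):
        c = 0.01 / np.sqrt(2)
        sec = _section([0, 0, 0], [c, 0, -c])  # TE below and downstream
        assert chord_angle(sec, config) == pytest.approx(45.0, abs=1e-9)

    def test_zero_parasagittal_projection_rejected(self, config):
        sec = _section([0, 0, 0], [0, 0.01, 0])  # purely spanwise
        with pytest.raises(ValueError, match="projection"):
            chord_angle(sec, config)


class TestEffectiveAoA:
    def test_static_chord_equals_chord_angle(self, config):
        c = 0.01
        a = np.radians(20.0)
        sec = _section([0, 0, 0], [c * np.cos(a), 0, -c * np.sin(a)])
        assert effective_aoa(sec, config) == pytest.approx(20.0, abs=1e-9)

    def test_downward_translation_at_flight_speed_gives_45(self, config):
        sec = _section([0, 0, 0], [0.01, 0, 0], vel=(0, 0, -config.U))
        assert effective_aoa(sec, config) == pytest.approx(45.0, abs=1e-9)

    def test_upward_translation_gives_negative_aoa(self, config):
        c = 0.01
        a = np.radians(20.0)
        sec = _section([0, 0, 0], [c * np.cos(a), 0, -c * np.sin(a)],
                       vel=(0, 0, config.U))
        assert effective_aoa(sec, config) == pytest.approx(20.0 - 45.0,
                                                           abs=1e-9)

    def test_vanishing_relative_flow_rejected(self, config):
        sec = _section([0, 0, 0], [0.01, 0, 0], vel=(config.U, 0, 0))
        with pytest.raises(ValueError, match="undefined"):
            effective_aoa(sec, config)


class TestExtractChord:
    def test_station_outside_wing_rejected(self, left_wing_mesh):
        with pytest.raises(ValueError):
            extract_chord(left_wing_mesh, 1.05, 0)

    def test_rectangular_planform_chord_constant(self, config):
        mesh = _planform_mesh(config.R, lambda r: np.full_like(r, 0.012))
        for r_hat in (0.2, 0.5, 0.85):
            sec = extract_chord(mesh, r_hat, 0)
            assert sec.chord_length == pytest.approx(0.012, rel=1e-6)

    def test_elliptic_chord_length(self, config):
        # chord at r_hat=0.9 of an elliptic planform is c_root sqrt(1-0.81)
        c_root = 4.0 * config.S_ref / (np.pi * config.R)
        mesh = _planform_mesh(
            config.R, lambda r: c_root * np.sqrt(np.maximum(0, 1 - r ** 2)))
        sec = extract_chord(mesh, 0.9, 0)
        assert sec.chord_length == pytest.approx(
            c_root * np.sqrt(1 - 0.9 ** 2), rel=0.02)

    def test_prescribed_pitch_recovered(self, config):
        # generator pitching psi(t) = 30 sin(2 pi f t) recovered within 0.5 deg
        prog = sinusoidal_program(
            Phi_deg=config.Phi, n_frames_per_cycle=22, n_cycles=3,
            noise_sd=0.0, pitch_deg=lambda phi: 30 * np.sin(2 * np.pi * phi))
        mset = generate_markers(config, prog, seed=0)
        mesh = refine_in_time(reconstruct_wing_series(mset, "left", 700), 4)
        series = compute_kinematics(mesh, config)
        phase = np.mod(series["time_s"] * config.f_beat, 1.0)
        expected = 30 * np.sin(2 * np.pi * phase)
        assert np.abs(series["psi_p_deg"] - expected).max() < 0.5
        assert np.abs(series["psi_d_deg"] - expected).max() < 0.5


class TestKinematicsSeries:
    def test_angles_continuous_and_in_range(self, left_wing_mesh, config):
        series = compute_kinematics(left_wing_mesh, config)
        for col in ("psi_p_deg", "psi_d_deg", "alpha_p_deg", "alpha_d_deg"):
            vals = series[col]
            assert np.all(vals > -180.0) and np.all(vals <= 180.0)
            assert np.abs(np.diff(vals)).max() < 90.0  # no wrap jumps

    def test_twist_is_distal_minus_proximal(self, left_wing_mesh, config):
        series = compute_kinematics(left_wing_mesh, config)
        np.testing.assert_allclose(
            series["twist_deg"],
            series["psi_d_deg"] - series["psi_p_deg"], atol=1e-12)

    def test_default_program_signs_match_flight_style(self, left_wing_mesh,
                                                      config):
        """Proximal chord angle and AoA positive all cycle; distal chord
        pitched down near mid-downstroke and up with negative AoA near
        mid-upstroke (the thrust-at-negative-lift upstroke mechanism)."""
        series = compute_kinematics(left_wing_mesh, config)
        frac = np.mod(series["phase"], 1.0)
        assert np.all(series["psi_p_deg"] > 0)
        assert np.all(series["alpha_p_deg"] > 0)
        mid_dn = np.argmin(np.abs(frac - 0.25))
        mid_up = np.argmin(np.abs(frac - 0.75))
        assert series["psi_d_deg"][mid_dn] < 0
        assert series["psi_d_deg"][mid_up] > 0
        assert series["alpha_d_deg"][mid_dn] > 0
        assert series["alpha_d_deg"][mid_up] < 0

    def test_twist_extremes_at_midstrokes(self, left_wing_mesh, config):
        series = compute_kinematics(left_wing_mesh, config)
        frac = np.mod(series["phase"], 1.0)
        tw = series["twist_deg"]
        assert frac[np.argmin(tw)] == pytest.approx(0.25, abs=0.06)
        assert frac[np.argmax(tw)] == pytest.approx(0.75, abs=0.06)


class TestCycleSummaries:
    def test_advance_ratio_identity(self, left_wing_mesh, config):
        series = compute_kinematics(left_wing_mesh, config)
        s = cycle_summaries(series, config)
        assert s.J == pytest.approx(config.U / s.U_tip, rel=1e-12)

    def test_sinusoidal_tip_speed_and_advance_ratio(self, config):
        prog = sinusoidal_program(Phi_deg=config.Phi, n_frames_per_cycle=22,
                                  n_cycles=3, noise_sd=0.0)
        mset = generate_markers(config, prog, seed=0)
        mesh = refine_in_time(reconstruct_wing_series(mset, "left", 700), 4)
        s = cycle_summaries(compute_kinematics(mesh, config), config)
        expected = 2 * config.f_beat * config.Phi_rad * config.R
        assert s.U_tip == pytest.approx(expected, rel=0.01)
        assert s.J == pytest.approx(config.U / expected, rel=0.01)

    def test_measured_tip_speed_reproduces_printed_advance_ratio(self, config):
        # with the observed mean wingtip speed of 8.14 m/s at U = 8.3 m/s
        # the advance ratio evaluates to 1.02
        assert config.U / 8.14 == pytest.approx(1.02, abs=0.005)
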