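import math

import numpy as np
import pytest

from flapsim.config import default_calliope_config
from flapsim.kinematics import (InvalidProgramError, MarkerParseError,
                                MarkerTrajectorySet, default_kinematic_program,
                                generate_markers, read_markers,
                                sinusoidal_program, write_markers)


@pytest.fixture(scope="module")
def config():
    return default_calliope_config()


def _tip_speeds(config, n_frames=200):
    """Tip speed series from densely sampled sinusoidal-program markers,
    differentiated with a periodic central difference (the independent
    oracle path: no spline machinery involved)."""
    prog = sinusoidal_program(Phi_deg=config.Phi, n_frames_per_cycle=n_frames,
                              n_cycles=1, noise_sd=0.0)
    mset = generate_markers(config, prog, seed=0)
    tip = mset.wing("left")[:, 5]
    dt = mset.times[1] - mset.times[0]
    vel = (np.roll(tip, -1, axis=0) - np.roll(tip, 1, axis=0)) / (2 * dt)
    return np.linalg.norm(vel, axis=1)


class TestSinusoidalTipSpeed:
    def test_peak_matches_closed_form(self, config):
        # peak body-relative tip speed of a cosine stroke: pi f Phi R
        speeds = _tip_speeds(config)
        expected = math.pi * config.f_beat * config.Phi_rad * config.R
        assert expected == pytest.approx(11.53, abs=0.01)
        assert speeds.max() == pytest.approx(expected, rel=1e-3)

    def test_cycle_mean_matches_closed_form(self, config):
        # mean of |sin| over a cycle gives 2 f Phi R
        speeds = _tip_speeds(config)
        expected = 2.0 * config.f_beat * config.Phi_rad * config.R
        assert expected == pytest.approx(7.34, abs=0.01)
        assert speeds.mean() == pytest.approx(expected, rel=1e-3)


class TestGenerateMarkers:
    def test_marker_set_shape_and_reach(self, config):
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=0.0)
        mset = generate_markers(config, prog, seed=3)
        assert mset.coords.shape == (66, 2, 9, 3)
        mset.check_reach(config)

    def test_mirror_symmetry(self, config):
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=0.0)
        mset = generate_markers(config, prog, seed=0)
        left, right = mset.coords[:, 0], mset.coords[:, 1]
        np.testing.assert_allclose(left * [1, -1, 1], right, atol=1e-15)

    def test_noiseless_output_is_seed_independent(self, config):
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=0.0)
        a = generate_markers(config, prog, seed=1)
        b = generate_markers(config, prog, seed=99)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_noise_is_seed_reproducible(self, config):
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=2e-4)
        a = generate_markers(config, prog, seed=7)
        b = generate_markers(config, prog, seed=7)
        c = generate_markers(config, prog, seed=8)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert np.abs(a.coords - c.coords).max() > 1e-6

    def test_area_modulation_mean_is_reference_area(self, config):
        # generator planform area integrates to S_ref * modulation
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=0.0)
        phi = np.linspace(0, 1, 400, endpoint=False)
        assert float(np.mean(prog.area_modulation(phi))) == pytest.approx(1.0, abs=1e-3)

    def test_non_periodic_waveform_rejected(self, config):
        prog = default_kinematic_program(Phi_deg=config.Phi)
        prog.stroke_angle_waveform = lambda phi: np.asarray(phi, dtype=float)
        with pytest.raises(InvalidProgramError, match="periodic"):
            generate_markers(config, prog, seed=0)

    def test_too_few_frames_rejected(self, config):
        prog = default_kinematic_program(Phi_deg=config.Phi,
                                         n_frames_per_cycle=5)
        with pytest.raises(InvalidProgramError, match="frames"):
            generate_markers(config, prog, seed=0)


class TestMarkerIO:
    def test_roundtrip_lossless(self, config, tmp_path):
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=2e-4,
                                         n_cycles=2)
        mset = generate_markers(config, prog, seed=5)
        path = tmp_path / "markers.csv"
        write_markers(mset, path)
        back = read_markers(path)
        np.testing.assert_allclose(back.coords, mset.coords, atol=1e-12)
        np.testing.assert_allclose(back.times, mset.times, atol=1e-15)
        assert back.sides == mset.sides

    def test_missing_marker_is_parse_error(self, config, tmp_path):
        prog = default_kinematic_program(Phi_deg=config.Phi, noise_sd=0.0,
                                         n_cycles=1)
        mset = generate_markers(config, prog, seed=0)
        path = tmp_path / "markers.csv"
        write_markers(mset, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:5] + lines[6:]))  # drop one marker row
        with pytest.raises(MarkerParseError, match="9"):
            read_markers(path)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(MarkerParseError):
            read_markers(path)

    def test_header_only_file_is_error(self, tmp_path):
        path = tmp_path / "header.csv"
        path.write_text("time_s,wing,marker_id,x_m,y_m,z_m\n")
        with pytest.raises(MarkerParseError, match="no rows"):
            read_markers(path)


class TestDefaultProgram:
    def test_twist_profile_peaks_at_midstrokes(self):
        prog = default_kinematic_program()
        # distal-minus-proximal twist at the analysis stations
        tw = (prog.twist_profile(np.array([0.25, 0.75]), np.full(2, 0.90))
              - prog.twist_profile(np.array([0.25, 0.75]), np.full(2, 0.15)))
        assert tw[0] == pytest.approx(-25.0, abs=0.5)
        assert tw[1] == pytest.approx(40.0, abs=0.5)

    def test_area_modulation_down_up_split(self):
        # downstroke-mean area ~5.34 cm^2, upstroke ~5.03, mean 5.18
        prog = default_kinematic_program()
        phi = np.linspace(0, 1, 2000, endpoint=False)
        mod = prog.area_modulation(phi)
        S = 5.18
        assert S * mod[phi < 0.5].mean() == pytest.approx(5.34, abs=0.02)
        assert S * mod[phi >= 0.5].mean() == pytest.approx(5.03, abs=0.02)
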