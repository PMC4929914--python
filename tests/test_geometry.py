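import numpy as np
import pytest
from scipy.spatial import cKDTree

from flapsim.config import default_calliope_config
from flapsim.geometry import (DegenerateOutlineError, build_body,
                              estimate_shoulder, load_wing_mesh,
                              phase_average, reconstruct_outline,
                              reconstruct_wing_series, refine_in_time,
                              save_wing_mesh, segment_strokes,
                              triangulate_wing)
from flapsim.kinematics import default_kinematic_program, generate_markers


def _ellipse_markers(a=1.0, b=0.6, n=9):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(ang), b * np.sin(ang), np.zeros(n)])


class TestOutline:
    def test_passes_through_markers(self):
        markers = _ellipse_markers()
        outline = reconstruct_outline(markers)
        np.testing.assert_allclose(outline(outline.marker_u), markers,
                                   atol=1e-12)

    def test_ellipse_outline_accuracy(self):
        # sampled outline stays within 1% of the semi-major axis of the
        # generating ellipse
        a, b = 1.0, 0.6
        outline = reconstruct_outline(_ellipse_markers(a, b))
        pts = outline(np.linspace(0, 1, 1500, endpoint=False))[:, :2]
        tt = np.linspace(0, 2 * np.pi, 30000)
        ref = np.column_stack([a * np.cos(tt), b * np.sin(tt)])
        dist, _ = cKDTree(ref).query(pts)
        assert dist.max() < 0.01 * a

    def test_wrong_marker_count_rejected(self):
        with pytest.raises(DegenerateOutlineError, match="9"):
            reconstruct_outline(_ellipse_markers(n=8))

    def test_collinear_markers_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 9), np.zeros(9), np.zeros(9)])
        with pytest.raises(DegenerateOutlineError, match="collinear"):
            reconstruct_outline(pts)

    def test_duplicate_markers_rejected(self):
        pts = _ellipse_markers()
        pts[4] = pts[3]
        with pytest.raises(DegenerateOutlineError, match="duplicat"):
            reconstruct_outline(pts)


class TestTriangulation:
    def test_count_and_area_of_default_scale(self, config, clean_markers):
        frame = clean_markers.wing("left")[4]
        mesh = triangulate_wing(reconstruct_outline(frame), 1335)
        assert abs(mesh.n_triangles - 1335) <= 0.15 * 1335
        # area within 5% of the generating planform at that phase
        prog = default_kinematic_program(Phi_deg=config.Phi)
        phase = clean_markers.times[4] * config.f_beat
        target = config.S_ref * float(prog.area_modulation(np.asarray(phase)))
        assert mesh.area() == pytest.approx(target, rel=0.05)

    def test_area_is_sum_of_triangle_cross_products(self, clean_markers):
        frame = clean_markers.wing("left")[0]
        mesh = triangulate_wing(reconstruct_outline(frame), 400)
        p = mesh.nodes[0]
        brute = 0.0
        for tri in mesh.triangles:
            a, b, c = p[tri]
            brute += 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        assert mesh.area() == pytest.approx(brute, rel=1e-12)

    def test_boundary_follows_outline(self, clean_markers):
        frame = clean_markers.wing("left")[7]
        outline = reconstruct_outline(frame)
        mesh = triangulate_wing(outline, 1000)
        chord = 4 * 5.18e-4 / (np.pi * 4.51e-2)  # root chord scale
        err = np.linalg.norm(mesh.nodes[0][mesh.boundary]
                             - outline(mesh.boundary_u), axis=1)
        assert err.max() < chord / 100.0

    def test_planar_markers_give_planar_mesh(self):
        mesh = triangulate_wing(reconstruct_outline(_ellipse_markers()), 300)
        assert np.abs(mesh.nodes[0][:, 2]).max() < 1e-12


class TestSeriesReconstruction:
    def test_shoulder_recovered_from_spar_lines(self, clean_markers):
        sh = estimate_shoulder(clean_markers.wing("left"))
        np.testing.assert_allclose(sh, [0.0, 8.0e-3, 0.0], atol=1e-9)

    def test_instantaneous_area_tracks_modulation(self, config, clean_markers):
        prog = default_kinematic_program(Phi_deg=config.Phi)
        series = reconstruct_wing_series(clean_markers, "left", 600)
        target = config.S_ref * prog.area_modulation(
            clean_markers.times * config.f_beat)
        ratio = series.areas() / target
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_connectivity_constant_in_time(self, clean_markers):
        series = reconstruct_wing_series(clean_markers, "left", 300)
        assert series.nodes.shape[0] == clean_markers.n_times
        assert series.triangles.ndim == 2  # one shared connectivity


class TestTemporalRefinement:
    def test_sinusoidal_trajectory_error(self):
        # nodes moving as sin(2 pi f t), 22 samples/cycle, refined x10
        f = 45.5
        t = np.arange(22) / (22 * f)
        base = np.zeros((22, 4, 3))
        base[:, :, 2] = np.sin(2 * np.pi * f * t)[:, None]
        mesh = _trivial_mesh(t, base)
        fine = refine_in_time(mesh, 10)
        exact = np.sin(2 * np.pi * f * fine.times)
        err = np.abs(fine.nodes[:, 0, 2] - exact).max()
        assert err < 1e-4  # amplitude is 1

    def test_velocities_match_finite_differences(self):
        f = 45.5
        t = np.arange(22) / (22 * f)
        base = np.zeros((22, 4, 3))
        base[:, :, 1] = np.cos(2 * np.pi * f * t)[:, None]
        fine = refine_in_time(_trivial_mesh(t, base), 8)
        dt = fine.times[1] - fine.times[0]
        fd = (np.roll(fine.nodes, -1, axis=0)
              - np.roll(fine.nodes, 1, axis=0)) / (2 * dt)
        err = np.abs(fine.node_velocities - fd).max()
        # central differences of the refined positions carry an O(dt^2)
        # truncation error bounded by |f'''| dt^2 / 6
        bound = 1.5 * (2 * np.pi * f) ** 3 * dt ** 2 / 6.0
        assert err < bound

    def test_identity_at_factor_one(self, left_wing_mesh):
        again = refine_in_time(left_wing_mesh, 1)
        np.testing.assert_allclose(again.nodes, left_wing_mesh.nodes,
                                   atol=1e-12)

    def test_positions_unchanged_at_original_samples(self, clean_markers):
        series = reconstruct_wing_series(clean_markers, "left", 300)
        fine = refine_in_time(series, 5)
        np.testing.assert_allclose(fine.nodes[::5], series.nodes, atol=1e-12)

    def test_cycle_mean_preserved(self, clean_markers):
        series = reconstruct_wing_series(clean_markers, "left", 300)
        fine = refine_in_time(series, 7)
        coarse_mean = series.nodes.mean(axis=0)
        fine_mean = fine.nodes.mean(axis=0)
        scale = np.abs(series.nodes).max()
        assert np.abs(fine_mean - coarse_mean).max() < 0.005 * scale


def _trivial_mesh(times, nodes):
    from flapsim.geometry import WingMesh
    tri = np.array([[0, 1, 2], [0, 2, 3]])
    return WingMesh(times=times, nodes=nodes, triangles=tri, side="left",
                    shoulder=np.zeros(3), boundary=np.arange(4),
                    boundary_u=np.linspace(0, 1, 4, endpoint=False))


class TestPhaseAverage:
    def test_identical_cycles_reproduce_single_cycle(self):
        phases = np.arange(88) / 22.0
        vals = np.sin(2 * np.pi * phases)
        centers, avg = phase_average(phases, vals, n_bins=22)
        np.testing.assert_allclose(avg, vals[:22], atol=1e-12)

    def test_noise_suppression_within_standard_error(self):
        rng = np.random.default_rng(11)
        n_cycles, per = 7, 50
        phases = np.arange(n_cycles * per) / per
        clean = np.sin(2 * np.pi * phases)
        sd = 0.3
        noisy = clean + rng.normal(0, sd, clean.size)
        _, avg = phase_average(phases, noisy, n_bins=per)
        amp = 0.5 * (avg.max() - avg.min())
        assert abs(amp - 1.0) < 3.0 * sd / np.sqrt(n_cycles)

    def test_commutes_with_linear_maps(self):
        rng = np.random.default_rng(3)
        phases = np.arange(100) / 25.0
        vals = rng.normal(size=100)
        _, avg = phase_average(phases, vals, n_bins=10)
        _, avg2 = phase_average(phases, 3.5 * vals - 1.25, n_bins=10)
        np.testing.assert_allclose(avg2, 3.5 * avg - 1.25, atol=1e-12)

    def test_constant_series_is_constant(self):
        phases = np.arange(60) / 20.0
        _, avg = phase_average(phases, np.full(60, 2.5), n_bins=20)
        np.testing.assert_allclose(avg, 2.5)

    def test_fewer_than_two_cycles_rejected(self):
        phases = np.arange(20) / 22.0
        with pytest.raises(ValueError, match="2 complete cycles"):
            phase_average(phases, np.zeros(20), n_bins=10)


class TestStrokeSegmentation:
    def test_default_program_split_at_half_phase(self, config, clean_markers):
        tip = clean_markers.wing("left")[:, 5]
        phase, down = segment_strokes(clean_markers.times, tip, config.beta)
        frac = np.mod(phase, 1.0)
        assert np.all(down[(frac > 0.05) & (frac < 0.45)])
        assert not np.any(down[(frac > 0.55) & (frac < 0.95)])


class TestBody:
    def test_watertight_and_positive_volume(self, config):
        body = build_body(config)
        tm = body.as_trimesh()
        assert tm.is_watertight
        assert tm.volume > 0
        # hummingbird scale: a few cubic centimetres
        assert 2e-6 < tm.volume < 5e-5

    def test_every_edge_shared_by_two_triangles(self, config):
        body = build_body(config)
        edges = np.sort(np.vstack([body.triangles[:, [0, 1]],
                                   body.triangles[:, [1, 2]],
                                   body.triangles[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)

    def test_major_axis_pitched_at_body_angle(self, config):
        body = build_body(config)
        centered = body.nodes - body.nodes.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        pitch = np.degrees(np.arctan2(abs(axis[2]), abs(axis[0])))
        assert pitch == pytest.approx(config.chi_b, abs=0.5)

    def test_mesh_scale_near_reference_counts(self, config):
        body = build_body(config)
        assert 3000 <= body.n_triangles <= 4000
        assert 1500 <= body.n_nodes <= 2000


class TestMeshIO:
    def test_save_load_roundtrip(self, tmp_path, clean_markers):
        series = reconstruct_wing_series(clean_markers, "left", 200)
        save_wing_mesh(series, tmp_path / "wing", fmt="obj")
        back = load_wing_mesh(tmp_path / "wing")
        np.testing.assert_allclose(back.nodes, series.nodes, atol=1e-5)
        np.testing.assert_array_equal(back.triangles, series.triangles)
        assert back.side == series.side
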