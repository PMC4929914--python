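import numpy as np
import pandas as pd
import pytest

from flapsim.postproc import (ForceSeries, derived_performance,
                              force_coefficients, format_summary_table,
                              grid_convergence_table, performance_summary,
                              power_coefficient, stroke_averages)


def _series(n=40, down_frac=0.5, **cols):
    phase = np.arange(n) / n
    base = {"time_s": phase / 45.5, "phase": phase,
            "downstroke": phase < down_frac}
    base.update(cols)
    return ForceSeries(table=pd.DataFrame(base))


class TestCoefficients:
    def test_normalization_round_trip(self, config):
        qS = 0.5 * config.rho * config.U ** 2 * config.S_ref
        F = np.array([-0.01, 0.002, 0.03])
        c = force_coefficients(F, config)
        assert c["C_Z"] * qS == pytest.approx(F[2])
        assert -c["C_T"] * qS == pytest.approx(F[0])

    def test_power_coefficient_normalization(self, config):
        qU = 0.5 * config.rho * config.U ** 3 * config.S_ref
        assert power_coefficient(qU, config) == pytest.approx(1.0)


class TestStrokeAverages:
    def test_symmetric_series_ratio_one(self, config):
        vals = np.concatenate([np.full(20, 0.3), np.full(20, 0.3)])
        s = _series(40, C=vals)
        sa = stroke_averages(s, "C")
        assert sa.down == pytest.approx(sa.up, rel=1e-12)
        assert sa.cycle == pytest.approx(sa.down, rel=1e-12)
        assert sa.down_up_ratio == pytest.approx(1.0, rel=1e-12)

    def test_equal_duration_cycle_mean_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=40)
        sa = stroke_averages(_series(40, C=vals), "C")
        assert sa.cycle == pytest.approx(0.5 * (sa.down + sa.up))

    def test_printed_down_up_ratios(self):
        # down/up ratios from the published stroke-resolved table
        assert 0.157 / 0.073 == pytest.approx(2.15, abs=0.01)
        assert 0.394 / 0.137 == pytest.approx(2.88, abs=0.01)
        assert 0.342 / 0.189 == pytest.approx(1.81, abs=0.01)

    def test_whole_cycle_is_mean_of_half_strokes(self):
        # published whole-cycle row equals the mean of down and up rows
        # the printed rows carry three decimals, so halves of sums can sit
        # half an ulp of the printed precision away
        assert 0.5 * (1.006 - 0.074) == pytest.approx(0.466)
        assert 0.5 * (0.157 + 0.073) == pytest.approx(0.115)
        assert 0.5 * (0.394 + 0.137) == pytest.approx(0.266, abs=5.1e-4)
        assert 0.5 * (0.342 + 0.189) == pytest.approx(0.266, abs=5.1e-4)
        assert 0.5 * (0.157 + 0.146) == pytest.approx(0.151, abs=5.1e-4)

    def test_missing_stroke_labels_rejected(self, config):
        s = ForceSeries(table=pd.DataFrame({"C": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="segmentation"):
            stroke_averages(s, "C")


class TestPerformanceSummary:
    def test_published_coefficients_reproduce_headline_numbers(self, config):
        perf = performance_summary(config, C_Z=0.466, C_T=0.115, C_P=0.266,
                                   C_Z_b=0.266, C_D_b=0.151)
        assert perf["P_aero_W"] * 1e3 == pytest.approx(94.5, abs=0.2)
        assert perf["P_mass_specific_W_kg"] == pytest.approx(34.0, abs=0.5)
        assert perf["weight_support_frac"] == pytest.approx(0.94, abs=0.01)
        assert perf["thrust_to_body_drag"] == pytest.approx(1.52, abs=0.01)
        assert perf["body_share"] == pytest.approx(0.222, abs=0.001)

    def test_all_zero_coefficients_give_zero_outputs(self, config):
        perf = performance_summary(config, 0.0, 0.0, 0.0, 0.0, 1e-9)
        assert perf["P_aero_W"] == 0.0
        assert perf["weight_support_frac"] == 0.0
        assert perf["thrust_to_body_drag"] == 0.0

    def test_nonpositive_mass_rejected(self, config):
        bad = config.replace(M=config.M)
        object.__setattr__(bad, "M", -1.0)  # bypass constructor validation
        with pytest.raises(ValueError):
            performance_summary(bad, 0.4, 0.1, 0.2, 0.2, 0.15)


class TestDerivedPerformance:
    def test_mirror_symmetric_wings_and_report(self, config):
        n = 40
        phase = np.arange(n) / n
        cz = 0.8 * np.where(phase < 0.5, 1.0, -0.2)
        series = _series(
            n,
            wing_left_C_Z=cz, wing_right_C_Z=cz,
            wing_left_C_T=np.full(n, 0.1), wing_right_C_T=np.full(n, 0.1),
            wing_left_C_Y=np.full(n, 0.05), wing_right_C_Y=np.full(n, -0.05),
            wing_left_C_P=np.full(n, 0.2), wing_right_C_P=np.full(n, 0.2),
            body_C_Z=np.full(n, 0.1), body_C_D=np.full(n, 0.15),
        )
        perf = derived_performance(series, config)
        assert perf.C_Z.down == pytest.approx(0.8)
        assert perf.C_Z.up == pytest.approx(-0.16)
        assert perf.C_T.down_up_ratio == pytest.approx(1.0)
        text = format_summary_table(perf)
        assert "whole cycle" in text and "down-/upstroke ratio" in text

    def test_body_only_mode_has_no_wing_rows(self, config):
        series = _series(20, body_C_Z=np.full(20, 0.1),
                         body_C_D=np.full(20, 0.15))
        perf = derived_performance(series, config, body_only=True)
        assert perf.C_Z is None and perf.P_aero_W is None
        assert perf.C_Z_b.cycle == pytest.approx(0.1)


class TestGridConvergence:
    def test_published_two_mesh_comparison(self):
        tbl = grid_convergence_table(
            {"C_Z": 0.374, "C_T": 0.112, "C_Z_b": 0.239, "C_D_b": 0.151},
            {"C_Z": 0.381, "C_T": 0.117, "C_Z_b": 0.238, "C_D_b": 0.150})
        diffs = tbl.loc["difference (%)"]
        assert diffs["C_Z"] == pytest.approx(1.84, abs=0.01)
        assert diffs["C_T"] == pytest.approx(4.27, abs=0.01)
        assert diffs["C_Z_b"] == pytest.approx(0.42, abs=0.01)
        assert diffs["C_D_b"] == pytest.approx(0.67, abs=0.01)
        assert diffs.max() < 5.0
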