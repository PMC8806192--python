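"""FUCCI calibration: crosstalk arithmetic, early-S gating, polynomial fit
and inversion, timing uncertainty, and time assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from cycledecay import calibration as cal
from cycledecay.synthetic import SimulationConfig, simulate_fucci_traces


class TestCrosstalkCorrection:
    @pytest.mark.parametrize("g1,g2,expected", [
        (100.0, 50.0, 19.0),   # 50 - 0.31*100
        (0.0, 7.0, 7.0),       # no G1 signal, nothing to remove
        (10.0, 1.0, -2.1),     # correction may go negative
    ])
    def test_default_31_percent_subtraction(self, g1, g2, expected):
        assert cal.correct_crosstalk(g1, g2) == pytest.approx(expected)

    @pytest.mark.parametrize("fraction", [-0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, fraction):
        with pytest.raises(ValueError):
            cal.correct_crosstalk(1.0, 1.0, fraction)

    @settings(max_examples=50, derandomize=True)
    @given(g1=st.floats(0, 1e4), g2_true=st.floats(0, 1e4),
           f=st.floats(0, 1))
    def test_corrupt_then_correct_is_exact(self, g1, g2_true, f):
        corrupted = g2_true + f * g1
        recovered = cal.correct_crosstalk(g1, corrupted, f)
        assert recovered == pytest.approx(g2_true, abs=1e-6 * (1 + g2_true))


class TestEarlySGate:
    @staticmethod
    def _table(extra):
        # anchors pin the channel ranges at G1 [0,100], G2 [0,200]
        rows = [(0.0, 0.0), (100.0, 200.0)] + extra
        return pd.DataFrame(rows, columns=["g1", "g2_corrected"])

    def test_cell_inside_gate_is_member(self):
        table = self._table([(50.0, 10.0)])  # G2 at 5% of range
        subset, mean_g1 = cal.gate_early_s(table)
        assert 50.0 in subset["g1"].to_numpy()

    def test_cell_above_g2_bound_excluded(self):
        table = self._table([(50.0, 10.0), (50.0, 30.0)])  # 15% of range
        subset, _ = cal.gate_early_s(table)
        assert 30.0 not in subset["g2_corrected"].to_numpy()

    def test_cell_below_g1_bound_excluded(self):
        table = self._table([(50.0, 10.0), (1.0, 10.0)])  # G1 at 1%
        subset, _ = cal.gate_early_s(table)
        assert 1.0 not in subset["g1"].to_numpy()

    def test_empty_gate_raises_named_error(self):
        # plenty of cells, none satisfying both gate conditions
        table = self._table([(1.0, 150.0), (2.0, 180.0), (99.0, 190.0)])
        with pytest.raises(ValueError, match="early-S gate"):
            cal.gate_early_s(table)

    def test_synthetic_snapshot_gate_recovers_early_s_cells(self, small_facs):
        snap = small_facs.copy()
        snap["g2_corrected"] = cal.correct_crosstalk(snap["g1"], snap["g2_raw"])
        subset, mean_g1 = cal.gate_early_s(snap)
        assert (subset["gate_label"] == "earlyS").mean() > 0.9
        assert mean_g1 > 0


class TestPolynomialFit:
    def test_exact_cubic_recovered(self):
        t = np.arange(0.0, 545.0, 5.0)
        coef = np.array([0.0, 1e-3, 2e-6, 1e-8])
        y = np.polynomial.polynomial.polyval(t, coef)
        traces = pd.DataFrame({"cell_id": "c0", "t_min": t, "g1": y})
        curve = cal.fit_mean_trace_polynomial(traces, early_s_mean=1.0)
        assert np.allclose(curve.coefficients, coef, rtol=1e-6, atol=1e-10)

    def test_decreasing_trace_raises_monotonicity_error(self):
        t = np.arange(0.0, 100.0, 5.0)
        traces = pd.DataFrame({"cell_id": "c0", "t_min": t, "g1": -t})
        with pytest.raises(ValueError, match="increasing"):
            cal.fit_mean_trace_polynomial(traces, early_s_mean=1.0)

    def test_too_few_time_points_rejected(self):
        traces = pd.DataFrame({"cell_id": "c0", "t_min": [0, 5, 10],
                               "g1": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="4 distinct"):
            cal.fit_mean_trace_polynomial(traces, early_s_mean=1.0)

    def test_fit_tracks_true_curve_within_2_percent(self, small_sim,
                                                    small_traces):
        from cycledecay.synthetic import fucci_accumulation
        clipped, _ = cal.clip_traces(small_traces)
        curve = cal.fit_mean_trace_polynomial(clipped)
        t = np.linspace(*curve.valid_time_range, 100)
        t_end = curve.valid_time_range[1]
        true_norm = (fucci_accumulation(t, small_sim.fucci_tau)
                     / fucci_accumulation(t_end, small_sim.fucci_tau))
        fit_norm = curve(t) / curve(t_end)
        assert np.max(np.abs(fit_norm - true_norm)) < 0.02

    def test_clip_time_lands_at_g2_rise(self, small_sim, small_traces):
        _, clip_time = cal.clip_traces(small_traces)
        assert small_sim.g1_end <= clip_time <= small_sim.g1_end + 15


class TestInversion:
    @pytest.fixture()
    def curve(self):
        return cal.CalibrationCurve(
            coefficients=[0.0, 1e-3, 2e-6, 1e-8],
            valid_time_range=(0.0, 540.0),
            early_s_mean_intensity=1.0)

    @pytest.mark.parametrize("t0", [30.0, 120.0, 240.0])
    def test_round_trip_within_tolerance(self, curve, t0):
        t, flag = cal.invert_time(curve, float(curve(t0)))
        assert t == pytest.approx(t0, abs=1e-4)
        assert flag == "ok"

    def test_below_range_clamps_low(self, curve):
        t, flag = cal.invert_time(curve, float(curve(0.0)) - 1.0)
        assert (t, flag) == (0.0, "clamped_low")

    def test_above_range_clamps_high(self, curve):
        t, flag = cal.invert_time(curve, float(curve(540.0)) + 1.0)
        assert (t, flag) == (540.0, "clamped_high")

    def test_beyond_confidence_horizon_flagged(self, curve):
        t, flag = cal.invert_time(curve, float(curve(400.0)))
        assert flag == "low_confidence"
        assert t == pytest.approx(400.0, abs=1e-4)

    def test_non_monotone_curve_rejected(self):
        bad = cal.CalibrationCurve(
            coefficients=[0.0, 1.0, -5e-3, 1e-6],
            valid_time_range=(0.0, 540.0),
            early_s_mean_intensity=1.0)
        with pytest.raises(ValueError, match="increasing"):
            cal.invert_time(bad, 0.5)


class TestTimingSD:
    def test_zero_heterogeneity_gives_zero_sd(self):
        cfg = SimulationConfig(trace_amplitude_cv=0.0,
                               measurement_noise_sd=0.0, n_traces=5,
                               n_g2m_cells=1, n_g1_cells=1,
                               n_genes_immediate=1, n_genes_delayed=1,
                               n_genes_stable=1, n_early_s_cells=0,
                               qc_spikeins=False)
        traces, _ = simulate_fucci_traces(cfg)
        clipped, _ = cal.clip_traces(traces)
        curve = cal.fit_mean_trace_polynomial(clipped)
        table = cal.timing_sd(clipped, curve)
        interior = table[~table["flagged"]]
        assert np.allclose(interior["timing_sd"], 0.0, atol=1e-6)

    def test_multiplicative_spread_on_linear_curve_matches_local_slope(self):
        # two traces at (1±d) x linear curve: timing SD ~ intensity SD / slope
        slope, d = 2e-3, 0.1
        t = np.arange(0.0, 545.0, 5.0)
        frames = [pd.DataFrame({"cell_id": f"c{i}", "t_min": t,
                                "g1": (1 + s * d) * slope * t})
                  for i, s in enumerate((-1.0, 1.0))]
        traces = pd.concat(frames, ignore_index=True)
        curve = cal.CalibrationCurve(
            coefficients=[0.0, slope, 0.0, 0.0],
            valid_time_range=(0.0, 540.0), early_s_mean_intensity=1.0)
        table = cal.timing_sd(traces, curve)
        interior = table[(~table["flagged"]) & (table["t_min"] > 0)]
        expected = d * interior["t_min"]  # sd/slope = d*t for linear curve
        assert np.allclose(interior["timing_sd"], expected, rtol=1e-3)

    def test_sd_table_non_negative_on_synthetic_traces(self, small_traces):
        clipped, _ = cal.clip_traces(small_traces)
        curve = cal.fit_mean_trace_polynomial(clipped)
        table = cal.timing_sd(clipped, curve)
        assert (table["timing_sd"] >= 0).all()

    def test_sd_non_decreasing_in_amplitude_cv(self):
        means = []
        for cv in (0.0, 0.1, 0.2):
            cfg = SimulationConfig(trace_amplitude_cv=cv,
                                   measurement_noise_sd=0.0, n_traces=60,
                                   n_g2m_cells=1, n_g1_cells=1,
                                   n_genes_immediate=1, n_genes_delayed=1,
                                   n_genes_stable=1, n_early_s_cells=0,
                                   qc_spikeins=False, rng_seed=9)
            traces, _ = simulate_fucci_traces(cfg)
            clipped, _ = cal.clip_traces(traces)
            curve = cal.fit_mean_trace_polynomial(clipped)
            table = cal.timing_sd(clipped, curve)
            means.append(table["timing_sd"].mean())
        assert means[0] <= means[1] <= means[2]


@pytest.fixture(scope="module")
def timed(small_traces, small_facs):
    clipped, _ = cal.clip_traces(small_traces)
    curve = cal.fit_mean_trace_polynomial(clipped)
    snap = small_facs.copy()
    snap["g2_corrected"] = cal.correct_crosstalk(snap["g1"], snap["g2_raw"])
    _, es_mean = cal.gate_early_s(snap)
    return cal.assign_times(snap, curve, es_mean), curve, es_mean


class TestAssignTimes:
    def test_raw_equal_to_early_s_mean_normalizes_to_one(self, timed):
        table, curve, es_mean = timed
        out = cal.assign_times(table.head(3).assign(g1=es_mean), curve,
                               es_mean)
        assert np.allclose(out["normalized_g1"], 1.0)

    def test_g2m_cells_keep_record_without_time(self, timed):
        table, _, _ = timed
        g2m = table[table["gate_label"] == "G2M"]
        assert len(g2m) > 0
        assert g2m["cell_cycle_time"].isna().all()
        assert (g2m["time_flag"] == "no_time").all()

    def test_times_within_valid_range_when_ok(self, timed):
        table, curve, _ = timed
        ok = table[table["time_flag"] == "ok"]
        lo, hi = curve.valid_time_range
        assert ok["cell_cycle_time"].between(lo, hi).all()

    def test_rank_correlation_with_true_times(self, timed, small_truth):
        table, _, _ = timed
        merged = table.merge(small_truth.cells, on="cell_id",
                             suffixes=("", "_true"))
        g1 = merged[merged["gate_label"] == "G1"]
        rho = spearmanr(g1["cell_cycle_time"],
                        g1["cell_cycle_time_true"]).statistic
        # ceiling for any calibration at 20% amplitude CV is ~0.948
        assert rho > 0.90

    def test_missing_early_s_mean_rejected(self, timed):
        table, curve, _ = timed
        with pytest.raises(ValueError, match="early-S"):
            cal.assign_times(table, curve, 0.0)

    def test_global_intensity_scaling_leaves_times_unchanged(
            self, timed, small_facs):
        table, curve, es_mean = timed
        snap = small_facs.copy()
        snap["g1"] *= 7.0
        scaled = cal.assign_times(snap, curve, es_mean * 7.0)
        g1 = table["gate_label"] == "G1"
        assert np.allclose(scaled.loc[g1, "cell_cycle_time"],
                           table.loc[g1, "cell_cycle_time"], atol=1e-6)


class TestCurveSerialization:
    def test_json_round_trip(self, tmp_path, small_traces):
        clipped, _ = cal.clip_traces(small_traces)
        curve = cal.fit_mean_trace_polynomial(clipped)
        curve.timing_sd_table = cal.timing_sd(clipped, curve)
        path = tmp_path / "cal.json"
        curve.to_json(path)
        back = cal.CalibrationCurve.from_json(path)
        assert np.allclose(back.coefficients, curve.coefficients)
        assert back.valid_time_range == curve.valid_time_range
        pd.testing.assert_frame_equal(back.timing_sd_table,
                                      curve.timing_sd_table)
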