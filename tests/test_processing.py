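"""Tests of the trace-processing stage: resampling, filtering, plateau
detection, target crossings, per-lesion summaries and geometry."""

import numpy as np
import pandas as pd
import pytest

from rflesion.metrics import IndexSeries
from rflesion.processing import (
    AblationTrace,
    detect_plateau,
    filter_li,
    interlesion_distance,
    mean_tip_position,
    read_traces,
    resample_trace,
    summarize_lesion,
    time_to_target,
    write_traces,
)
from rflesion.synthetic import TraceParams, noiseless_minimum_time, simulate_trace


def make_trace(t, li=None, cf=None, power=None, tip=None, pid="P1", lid="L1"):
    n = len(t)
    return AblationTrace(
        procedure_id=pid, lesion_id=lid, time_s=np.asarray(t, float),
        cf_g=np.asarray(cf if cf is not None else np.full(n, 15.0), float),
        power_w=np.asarray(power if power is not None else np.full(n, 40.0), float),
        li_ohm=np.asarray(li if li is not None else np.full(n, 150.0), float),
        tip_mm=tip if tip is not None else np.zeros((n, 3)),
    )


class TestResample:
    def test_identity_on_uniform_input(self):
        t = np.arange(0, 5, 1 / 997.0)
        tr = make_trace(t, li=150 - 2 * t)
        out = resample_trace(tr, 997.0)
        assert np.allclose(out.time_s, t, atol=1e-12)
        assert np.allclose(out.li_ohm, tr.li_ohm, atol=1e-12)

    def test_linear_signal_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 10, 300))
        t[0] = 0.0
        tr = make_trace(t, li=150 - 2 * t)
        out = resample_trace(tr, 997.0)
        assert np.allclose(out.li_ohm, 150 - 2 * out.time_s, atol=1e-9)

    def test_no_extrapolation(self):
        t = np.linspace(0, 1.0001, 50)
        out = resample_trace(make_trace(t), 997.0)
        assert out.time_s[-1] <= t[-1] + 1e-12

    def test_sine_interpolation_error_bound(self):
        """Linear interpolation error on a 5 Hz sine is bounded by
        (pi f h_max)^2 / 2 times the amplitude."""
        rng = np.random.default_rng(1)
        gaps = (1 / 997.0) * rng.uniform(0.7, 1.3, 3000)
        t = np.concatenate(([0.0], np.cumsum(gaps)))
        amp, f = 3.0, 5.0
        li = 150 + amp * np.sin(2 * np.pi * f * t)
        out = resample_trace(make_trace(t, li=li), 997.0)
        analytic = 150 + amp * np.sin(2 * np.pi * f * out.time_s)
        h_max = np.max(np.diff(t))
        bound = (2 * np.pi * f) ** 2 / 8 * h_max**2 * amp
        assert np.max(np.abs(out.li_ohm - analytic)) <= bound

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            resample_trace(make_trace([0.0]))


class TestFilterLI:
    def test_constant_passes_unchanged(self):
        t = np.arange(0, 6, 1 / 997.0)
        filt = filter_li(make_trace(t))
        assert np.allclose(filt.li_filtered_ohm, 150.0)
        assert filt.trim_offset_s == pytest.approx(1.5, abs=1e-3)

    def test_ramp_exact_on_supported_region(self):
        t = np.arange(0, 6, 1 / 997.0)
        filt = filter_li(make_trace(t, li=150 - 2 * t))
        ts = filt.filtered_time_s
        interior = (ts > 1.6) & (ts < t[-1] - 0.8)
        assert np.allclose(filt.li_filtered_ohm[interior], 150 - 2 * ts[interior],
                           atol=1e-9)

    def test_white_noise_sd_reduction(self):
        # long trace: the filtered series is autocorrelated over one window,
        # so estimating its SD needs many independent windows
        rng = np.random.default_rng(8)
        t = np.arange(0, 120, 1 / 997.0)
        sigma = 2.0
        filt = filter_li(make_trace(t, li=150 + rng.normal(0, sigma, len(t))))
        w = round(1.5 * 997)
        interior = filt.li_filtered_ohm[1000:-1000]
        expected = sigma / np.sqrt(w)
        assert expected * 0.8 < np.std(interior) < expected * 1.2

    def test_output_within_input_range(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 8, 1 / 997.0)
        li = 150 + rng.normal(0, 3, len(t))
        filt = filter_li(make_trace(t, li=li))
        assert filt.li_filtered_ohm.min() >= li.min() - 1e-12
        assert filt.li_filtered_ohm.max() <= li.max() + 1e-12

    def test_short_trace_rejected(self):
        t = np.arange(0, 1.0, 1 / 997.0)
        with pytest.raises(ValueError, match="duration"):
            filter_li(make_trace(t))


class TestDetectPlateau:
    def test_v_shape_vertex(self):
        # symmetric slopes: the centered mean of the V keeps its minimum at
        # the vertex (an asymmetric V shifts it toward the shallower side)
        t = np.arange(0, 24, 1 / 997.0)
        li = 150 - 2 * np.minimum(t, 12.0) + 2.0 * np.maximum(0.0, t - 12.0)
        res = detect_plateau(filter_li(make_trace(t, li=li)))
        assert res.t_plateau_s == pytest.approx(12.0, abs=0.01)
        assert res.li_drop_ohm == pytest.approx(res.li_start_ohm - res.li_at_plateau_ohm)
        assert not res.no_rebound

    def test_strictly_decreasing_flags_no_rebound(self):
        t = np.arange(0, 10, 1 / 997.0)
        res = detect_plateau(filter_li(make_trace(t, li=150 - 2 * t)))
        assert res.no_rebound
        assert res.t_plateau_s == pytest.approx(t[-1], abs=0.01)

    def test_noiseless_synthetic_matches_generator_minimum(self):
        p = TraceParams(noise_sd_ohm=0.0, seed=2)
        filt = filter_li(resample_trace(simulate_trace(p)))
        res = detect_plateau(filt)
        t_star = noiseless_minimum_time(p)
        # centered moving mean of the exponential-plus-linear curve biases
        # the minimum by tau*ln((2 tau / w) sinh(w / 2 tau)); the detection
        # must agree within that analytic bias plus one grid step
        w = 1.5
        bias = p.tau_drop_s * np.log(
            (2 * p.tau_drop_s / w) * np.sinh(w / (2 * p.tau_drop_s))
        )
        assert abs(res.t_plateau_s - t_star) <= bias + 2 / 997.0

    def test_drop_nonnegative(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 6, 1 / 997.0)
        res = detect_plateau(filter_li(make_trace(t, li=150 + rng.normal(0, 1, len(t)))))
        assert res.li_drop_ohm >= 0


class TestTimeToTarget:
    def test_linear_crossing(self):
        t = np.arange(0, 10, 1 / 997.0)
        series = IndexSeries(time_s=t, value=(400.0 / 7.0) * t, kind="AI")
        assert time_to_target(series, 400.0) == pytest.approx(7.0, abs=1.5 / 997.0)

    def test_unreached_target_missing(self):
        t = np.arange(0, 10, 1 / 997.0)
        series = IndexSeries(time_s=t, value=380 * (1 - np.exp(-t)), kind="AI")
        assert np.isnan(time_to_target(series, 400.0))

    def test_invalid_target_rejected(self):
        t = np.arange(0, 1, 0.01)
        series = IndexSeries(time_s=t, value=t, kind="AI")
        with pytest.raises(ValueError):
            time_to_target(series, -1.0)


class TestGeometry:
    def test_static_tip(self):
        t = np.linspace(0, 1, 10)
        tip = np.tile([1.0, 2.0, 3.0], (10, 1))
        assert np.allclose(mean_tip_position(make_trace(t, tip=tip)), [1, 2, 3])

    def test_two_sample_mean(self):
        t = np.array([0.0, 1.0])
        tip = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert np.allclose(mean_tip_position(make_trace(t, tip=tip)), [1, 0, 0])

    def test_gaussian_wobble_clt_bound(self):
        rng = np.random.default_rng(12)
        n = 997
        t = np.arange(n) / 997.0
        centre = np.array([3.0, -1.0, 5.0])
        tip = centre + rng.normal(0, 0.5, (n, 3))
        est = mean_tip_position(make_trace(t, tip=tip))
        assert np.all(np.abs(est - centre) < 4 * 0.5 / np.sqrt(n))

    def test_three_four_five(self):
        pos = pd.DataFrame({
            "procedure_id": ["P1", "P1"], "lesion_id": ["a", "b"],
            "x_mm": [0.0, 3.0], "y_mm": [0.0, 4.0], "z_mm": [0.0, 0.0],
        })
        ild = interlesion_distance(pos)
        assert np.allclose(ild, [5.0, 5.0])

    def test_collinear(self):
        pos = pd.DataFrame({
            "procedure_id": ["P1"] * 3, "lesion_id": list("abc"),
            "x_mm": [0.0, 2.0, 7.0], "y_mm": [0.0] * 3, "z_mm": [0.0] * 3,
        })
        assert np.allclose(interlesion_distance(pos), [2.0, 2.0, 5.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        n = 50
        xyz = rng.uniform(-20, 20, (n, 3))
        pos = pd.DataFrame({
            "procedure_id": "P1", "lesion_id": [f"L{i}" for i in range(n)],
            "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
        })
        ild = interlesion_distance(pos).to_numpy()
        d = np.linalg.norm(xyz[:, None] - xyz[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(ild, d.min(axis=1))

    def test_singleton_procedure_missing(self):
        pos = pd.DataFrame({
            "procedure_id": ["P1", "P2", "P2"], "lesion_id": list("abc"),
            "x_mm": [0.0, 1.0, 2.0], "y_mm": [0.0] * 3, "z_mm": [0.0] * 3,
        })
        ild = interlesion_distance(pos)
        assert np.isnan(ild.iloc[0])
        assert np.allclose(ild.iloc[1:], [1.0, 1.0])


class TestSummarizeLesion:
    def _indexed(self, t, ai_vals, lsi_vals):
        return (IndexSeries(time_s=t, value=ai_vals, kind="AI"),
                IndexSeries(time_s=t, value=lsi_vals, kind="LSI"))

    def test_constant_cf(self):
        t = np.arange(0, 20, 1 / 997.0)
        li = 150 - 2 * np.minimum(t, 10.0) + 2 * np.maximum(0.0, t - 10.0)
        tr = make_trace(t, li=li, cf=np.full_like(t, 18.0))
        filt = filter_li(tr)
        plateau = detect_plateau(filt)
        ai, lsi = self._indexed(t, 60 * t, 0.3 * t)
        s = summarize_lesion(filt, plateau, ai, lsi)
        assert s.cf_mean_g == pytest.approx(18.0)
        assert s.cf_start_g == pytest.approx(18.0)
        assert s.duration_li_s == pytest.approx(10.0, abs=0.05)

    def test_index_at_plateau_read_off(self):
        t = np.arange(0, 20, 1 / 997.0)
        li = 150 - 2 * np.minimum(t, 10.0) + np.maximum(0.0, t - 10.0)
        tr = make_trace(t, li=li)
        filt = filter_li(tr)
        plateau = detect_plateau(filt)
        # construct AI so that AI(t_plateau) = 476.46 exactly
        slope = 476.46 / plateau.t_plateau_s
        ai, lsi = self._indexed(t, slope * t, 0.2 * t)
        s = summarize_lesion(filt, plateau, ai, lsi)
        assert s.ai_at_plateau == pytest.approx(476.46, rel=1e-3)

    def test_grid_mismatch_rejected(self):
        t = np.arange(0, 20, 1 / 997.0)
        li = 150 - 2 * np.minimum(t, 10.0) + np.maximum(0.0, t - 10.0)
        filt = filter_li(make_trace(t, li=li))
        plateau = detect_plateau(filt)
        t2 = np.arange(0, 10, 1 / 997.0)
        ai = IndexSeries(time_s=t2, value=t2, kind="AI")
        lsi = IndexSeries(time_s=t2, value=t2, kind="LSI")
        with pytest.raises(ValueError, match="grid"):
            summarize_lesion(filt, plateau, ai, lsi)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        p = TraceParams(duration_s=3.0, seed=4)
        traces = [simulate_trace(p, procedure_id="P1", lesion_id="L1"),
                  simulate_trace(TraceParams(duration_s=3.0, seed=5),
                                 procedure_id="P1", lesion_id="L2")]
        path = tmp_path / "traces.csv"
        write_traces(traces, path)
        back = read_traces(path)
        assert len(back) == 2
        for a, b in zip(traces, back):
            assert a.lesion_id == b.lesion_id
            assert np.allclose(a.li_ohm, b.li_ohm)
            assert np.allclose(a.tip_mm, b.tip_mm)
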