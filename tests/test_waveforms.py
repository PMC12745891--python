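import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motion4d.errors import NoCyclesError, TraceParseError
from motion4d.waveforms import (
    RespiratoryTrace,
    classify_pattern,
    detect_cycles,
    generate_patient_like,
    generate_sinusoid,
    mean_max_amplitude,
    read_trace_csv,
    scale_to_mean_amplitude,
    write_trace_csv,
)


def piecewise_cycles(pps, period=4.0, dt=0.01):
    """Trace of consecutive sin^2 cycles with per-cycle excursions ``pps``
    (troughs at zero, one peak per cycle)."""
    segs = []
    n = int(round(period / dt))
    tau = np.arange(n) / n
    for pp in pps:
        segs.append(pp * np.sin(np.pi * tau) ** 2)
    a = np.concatenate(segs + [np.zeros(1)])
    t = np.arange(len(a)) * dt
    return RespiratoryTrace(t, a, dt)


class TestGenerateSinusoid:
    def test_peak_to_peak_matches_programmed_displacement(self):
        tr = generate_sinusoid(10, 4, 60, 0.01)
        assert tr.pp == pytest.approx(10.0, abs=1e-9)

    def test_zero_amplitude_gives_constant_trace(self):
        tr = generate_sinusoid(0, 4, 12, 0.01)
        assert np.all(tr.a == 0)

    def test_rectified_time_mean_is_pp_over_pi(self):
        # time-mean of |(pp/2) sin| over whole cycles is pp/pi
        tr = generate_sinusoid(10, 4, 40, 0.001)
        assert np.mean(np.abs(tr.a)) == pytest.approx(10 / np.pi, rel=1e-3)

    def test_zero_mean_over_whole_cycles(self):
        tr = generate_sinusoid(10, 4, 40, 0.001)
        assert np.mean(tr.a[:-1]) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pp_mm=10, period_s=0, duration_s=10, dt=0.01),
            dict(pp_mm=10, period_s=4, duration_s=10, dt=0),
            dict(pp_mm=-1, period_s=4, duration_s=10, dt=0.01),
            dict(pp_mm=10, period_s=4, duration_s=2, dt=0.01),
            dict(pp_mm=10, period_s=4, duration_s=10, dt=1.0),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_sinusoid(**kwargs)


class TestDetectCycles:
    def test_counts_completed_cycles(self, sin10):
        assert detect_cycles(sin10).n_cycles == 15

    def test_constant_trace_has_no_cycles(self):
        tr = RespiratoryTrace(np.arange(100) * 0.1, np.zeros(100), 0.1)
        assert detect_cycles(tr).n_cycles == 0

    def test_robust_to_additive_noise(self, sin10):
        rng = np.random.default_rng(42)
        noisy = RespiratoryTrace(sin10.t, sin10.a + rng.normal(0, 0.2, len(sin10.a)), sin10.dt)
        assert detect_cycles(noisy).n_cycles == 15

    @pytest.mark.parametrize("period", [2.4, 4.0, 12.0])
    def test_count_equals_duration_over_period(self, period):
        tr = generate_sinusoid(10, period, 48, 0.01)
        assert detect_cycles(tr).n_cycles == int(48 / period)


class TestMeanMaxAmplitude:
    def test_pure_sinusoid_equals_programmed_pp(self, sin10):
        assert mean_max_amplitude(sin10) == pytest.approx(10.0, abs=1e-6)

    def test_mixed_cycles_average(self):
        tr = piecewise_cycles([8, 10, 12])
        assert mean_max_amplitude(tr) == pytest.approx(10.0, abs=0.05)

    def test_spike_inflates_mean_less_than_max_scaling(self):
        tr = piecewise_cycles([10, 10, 30, 10])
        mma = mean_max_amplitude(tr)
        assert mma == pytest.approx(15.0, abs=0.1)
        assert mma < tr.pp  # max-amplitude scaling would use 30

    def test_no_cycles_raises(self):
        tr = RespiratoryTrace(np.arange(100) * 0.1, np.zeros(100), 0.1)
        with pytest.raises(NoCyclesError):
            mean_max_amplitude(tr)


class TestScaleToMeanAmplitude:
    def test_identity_when_target_matches(self, sin10):
        out = scale_to_mean_amplitude(sin10, 10.0)
        assert np.allclose(out.a, sin10.a, atol=1e-9)

    def test_linear_scaling_of_sinusoid(self):
        tr = generate_sinusoid(4, 4, 60, 0.01)
        out = scale_to_mean_amplitude(tr, 10.0)
        assert out.pp == pytest.approx(10.0, abs=1e-6)

    def test_mixed_trace_rescales_to_target(self):
        tr = piecewise_cycles([8, 10, 12])
        out = scale_to_mean_amplitude(tr, 6.0)
        assert mean_max_amplitude(out) == pytest.approx(6.0, abs=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(target=st.floats(0.5, 30.0), seed=st.integers(0, 50))
    def test_scaling_is_linear_for_any_cyclic_trace(self, target, seed):
        tr = generate_patient_like("regular", 10.0, seed=seed, duration_s=60)
        out = scale_to_mean_amplitude(tr, target)
        assert mean_max_amplitude(out) == pytest.approx(target, rel=1e-6)


class TestClassifyPattern:
    @pytest.mark.parametrize("pp", [6, 10])
    @pytest.mark.parametrize("period", [2.4, 4.0, 12.0])
    def test_sinusoids_are_regular(self, pp, period):
        assert classify_pattern(generate_sinusoid(pp, period, 60, 0.01)) == "regular"

    def test_amplitude_drift_is_semiregular(self):
        t = np.arange(6001) * 0.01
        envelope = np.linspace(5, 3, len(t))  # pp drifting 10 -> 6
        tr = RespiratoryTrace(t, envelope * np.sin(2 * np.pi * t / 4), 0.01)
        assert classify_pattern(tr) == "semiregular"

    def test_spikes_and_pause_are_irregular(self):
        pps = [10, 10, 30, 10, 30, 10]
        tr = piecewise_cycles(pps)
        assert classify_pattern(tr) == "irregular"

    def test_too_few_cycles_is_unknown(self):
        tr = generate_sinusoid(10, 4, 8, 0.01)
        assert classify_pattern(tr) == "unknown"

    @pytest.mark.parametrize("category", ["regular", "semiregular", "irregular"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generator_produces_its_class(self, category, seed):
        tr = generate_patient_like(category, seed=seed)
        assert classify_pattern(tr) == category
        assert mean_max_amplitude(tr) == pytest.approx(10.0, rel=1e-6)


class TestTraceCsv:
    def test_round_trip(self, sin10, tmp_path):
        path = tmp_path / "trace.csv"
        write_trace_csv(sin10, path)
        back = read_trace_csv(path)
        assert np.allclose(back.t, sin10.t, atol=1e-9)
        assert np.allclose(back.a, sin10.a, atol=1e-9)

    def test_non_monotone_time_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,amp_mm\n0.0,1.0\n0.2,2.0\n0.1,3.0\n")
        with pytest.raises(TraceParseError, match="line"):
            read_trace_csv(path)

    def test_non_numeric_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0.0,1.0\n0.1,oops\n")
        with pytest.raises(TraceParseError, match="line 2"):
            read_trace_csv(path)

    def test_sub_microsecond_jitter_accepted(self, tmp_path):
        rng = np.random.default_rng(0)
        t = np.arange(50) * 0.02 + rng.uniform(-4e-7, 4e-7, 50)
        t.sort()
        a = np.sin(t)
        path = tmp_path / "jitter.csv"
        path.write_text("\n".join(f"{float(ti)!r},{float(ai)!r}" for ti, ai in zip(t, a)))
        tr = read_trace_csv(path)
        assert tr.dt == pytest.approx(0.02, abs=1e-6)
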