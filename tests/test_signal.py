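import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drifttrack import (
    EstimationError,
    PeakSet,
    SimConfig,
    Trace,
    ValidationError,
    compute_baseline,
    detect_peaks,
    estimate_period,
    estimate_velocity,
    simulate_session,
)
from drifttrack.signal import END_EXHALE, END_INHALE

from oracles import detect_peaks_oracle


def _trace(t, y, axis="AP", rate=60.0):
    return Trace(np.asarray(t, float), np.asarray(y, float), axis, rate)


class TestVelocity:
    def test_constant_trace_zero_velocity(self):
        t = np.arange(600) / 60.0
        v = estimate_velocity(_trace(t, np.full_like(t, 3.7)))
        assert np.allclose(v.y, 0.0, atol=1e-12)

    def test_linear_trace_exact_at_interior(self):
        t = np.arange(600) / 60.0
        v = estimate_velocity(_trace(t, 2.0 * t), smooth_win=5)
        interior = slice(3, -3)  # smoothing pad + one-sided endpoint diffs
        assert np.allclose(v.y[interior], 2.0, atol=1e-9)

    def test_sine_peak_velocity_matches_analytic(self):
        t = np.arange(0, 12, 1 / 60.0)
        v = estimate_velocity(_trace(t, 5.0 * np.sin(2 * np.pi * t / 4.0)), smooth_win=5)
        expected = 5.0 * 2 * np.pi / 4.0
        assert np.max(np.abs(v.y[5:-5])) == pytest.approx(expected, rel=0.02)

    def test_time_reversal_negates_interior_velocity(self):
        rng = np.random.default_rng(0)
        t = np.arange(300) / 60.0
        y = np.cumsum(rng.normal(size=300)) * 0.1
        v_fwd = estimate_velocity(_trace(t, y)).y
        v_rev = estimate_velocity(_trace(t, y[::-1])).y
        assert np.allclose(v_fwd[3:-3], -v_rev[::-1][3:-3], atol=1e-9)

    def test_short_trace_rejected(self):
        t = np.arange(4) / 60.0
        with pytest.raises(ValidationError, match="shorter"):
            estimate_velocity(_trace(t, t), smooth_win=5)

    def test_even_smooth_win_rejected(self):
        t = np.arange(100) / 60.0
        with pytest.raises(ValidationError, match="odd"):
            estimate_velocity(_trace(t, t), smooth_win=4)


class TestPeriodEstimation:
    @pytest.mark.parametrize("period", [2.8, 4.0, 6.7])
    def test_recovers_known_period_under_drift(self, period):
        t = np.arange(0, 40, 1 / 60.0)
        y = 5 * (1 - np.cos(np.pi * t / period) ** 4) + 0.05 * t  # drifting
        assert estimate_period(t, y) == pytest.approx(period, rel=0.05)

    def test_too_short_record_raises(self):
        t = np.arange(0, 2, 1 / 60.0)
        with pytest.raises(EstimationError, match="too short"):
            estimate_period(t, np.sin(t))


class TestDetectPeaks:
    def test_pure_cosine_analytic_extrema(self):
        # maxima at t = 1, 5, 9; minima at t = 3, 7, 11
        t = np.arange(0, 12, 1 / 60.0)
        peaks = detect_peaks(_trace(t, np.cos(2 * np.pi * (t - 1) / 4.0)))
        t_in, _ = peaks.select(END_INHALE)
        t_ex, _ = peaks.select(END_EXHALE)
        assert np.allclose(t_in, [1, 5, 9], atol=1.5 / 60)
        assert np.allclose(t_ex, [3, 7, 11], atol=1.5 / 60)

    def test_lujan_dwell_no_duplicate_peaks(self):
        # the long end-exhale dwell must not yield two exhale peaks per cycle
        t = np.arange(0, 16, 1 / 60.0)
        y = 5 * (1 - np.cos(np.pi * t / 4.0) ** 4)
        peaks = detect_peaks(_trace(t, y), period_s=4.0)
        assert peaks.count(END_INHALE) == 4  # crests at 2, 6, 10, 14
        assert peaks.count(END_EXHALE) == 3  # troughs at 4, 8, 12 (edges excluded)

    def test_phases_alternate(self, noisy_pair):
        first, _, _ = noisy_pair
        peaks = detect_peaks(first.ir[0], (0.0, 40.0))
        assert not peaks.empty
        assert all(a != b for a, b in zip(peaks.phases, peaks.phases[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_on_noisy_breathing(self, seed):
        """The detector equals an exhaustive scan + identical filters."""
        cfg = SimConfig(seed=seed, ext_drift_mm_per_min=-0.3)
        session, _ = simulate_session(cfg)
        tr = session.ir[1].slice((0.0, 40.0))
        period = estimate_period(tr.t, tr.y)
        peaks = detect_peaks(tr, period_s=period)
        imax, imin = detect_peaks_oracle(tr.t, tr.y, period)
        t_in, _ = peaks.select(END_INHALE)
        t_ex, _ = peaks.select(END_EXHALE)
        assert np.array_equal(t_in, tr.t[imax])
        assert np.array_equal(t_ex, tr.t[imin])

    def test_oracle_agreement_on_internal_trace_with_cardiac(self):
        session, _ = simulate_session(SimConfig(seed=9, cardiac_amp_mm=0.5))
        tr = session.target["SI"]
        period = estimate_period(tr.t, tr.y)
        peaks = detect_peaks(tr, period_s=period, smooth_win=7)
        imax, imin = detect_peaks_oracle(tr.t, tr.y, period, smooth_win=7)
        assert np.array_equal(np.sort(peaks.times),
                              np.sort(np.concatenate([tr.t[imax], tr.t[imin]])))

    def test_cardiac_jitter_does_not_change_peak_count(self):
        """0.5 mm cardiac jitter on a 15 mm SI trace spawns no extra peaks."""
        base = dict(seed=21, noise_int_mm=0.0)
        clean, _ = simulate_session(SimConfig(cardiac_amp_mm=0.0, **base))
        jitter, _ = simulate_session(SimConfig(cardiac_amp_mm=0.5, **base))
        p_clean = detect_peaks(clean.target["SI"], period_s=4.0, smooth_win=7)
        p_jitter = detect_peaks(jitter.target["SI"], period_s=4.0, smooth_win=7)
        assert p_clean.count(END_INHALE) == p_jitter.count(END_INHALE)
        assert p_clean.count(END_EXHALE) == p_jitter.count(END_EXHALE)

    def test_phase_reference_labels_override_extremum_type(self):
        t = np.arange(0, 12, 0.08)
        y = np.cos(2 * np.pi * (t - 1) / 4.0)
        ref = PeakSet(np.array([1.0, 3.0, 5.0, 7.0, 9.0, 11.0]),
                      np.zeros(6),
                      np.array([END_EXHALE, END_INHALE] * 3, dtype=object),
                      "AP")
        peaks = detect_peaks(_trace(t, y, "SI", 12.5), phase_reference=ref, period_s=4.0)
        # labels follow the (deliberately inverted) reference, not extremum type
        t_ex, _ = peaks.select(END_EXHALE)
        assert np.allclose(t_ex, [1, 5, 9], atol=0.1)

    def test_flat_trace_returns_empty_set(self):
        t = np.arange(0, 12, 1 / 60.0)
        peaks = detect_peaks(_trace(t, np.zeros_like(t)), period_s=4.0)
        assert peaks.empty


class TestBaseline:
    def test_median_of_end_exhale_values(self):
        ps = PeakSet(np.array([0.0, 1.0, 2.0]), np.array([5.0, 5.0, 5.0]),
                     np.array([END_EXHALE] * 3, dtype=object), "AP")
        assert compute_baseline(ps) == 5.0
        ps2 = PeakSet(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 10.0]),
                      np.array([END_EXHALE] * 3, dtype=object), "AP")
        assert compute_baseline(ps2) == 2.0

    def test_requires_end_exhale_peaks(self):
        ps = PeakSet(np.array([0.0]), np.array([1.0]),
                     np.array([END_INHALE], dtype=object), "AP")
        with pytest.raises(EstimationError, match="end-exhale"):
            compute_baseline(ps)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=15), st.randoms())
    def test_invariant_to_peak_ordering(self, values, rnd):
        values = sorted(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        def ps(vals):
            return PeakSet(np.arange(len(vals), dtype=float), np.array(vals),
                           np.array([END_EXHALE] * len(vals), dtype=object), "AP")
        assert compute_baseline(ps(values)) == compute_baseline(ps(shuffled))

    def test_invariant_to_symmetric_duplicates(self):
        vals = [1.0, 2.0, 3.0]
        with_dups = [-10.0, 1.0, 2.0, 3.0, 20.0]
        def ps(vals):
            return PeakSet(np.arange(len(vals), dtype=float), np.array(vals),
                           np.array([END_EXHALE] * len(vals), dtype=object), "AP")
        assert compute_baseline(ps(vals)) == compute_baseline(ps(with_dups))
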