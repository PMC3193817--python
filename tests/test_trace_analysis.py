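"""Feature extraction oracles: closed forms, self-fits and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2x3kin.simulator import CurrentTrace, PulseProtocol, simulate
from p2x3kin.trace_analysis import (
    AnalysisError,
    compare_groups,
    current_density,
    extract_features,
    fit_biexponential,
    peak_and_baseline,
    recovery_ratio,
    rise_time_10_90,
)


def _trace(time, value):
    return CurrentTrace(time=np.asarray(time), value=np.asarray(value))


class TestPeakAndBaseline:
    def test_square_inward_deflection(self):
        t = np.arange(0, 2, 1e-3)
        v = np.where((t >= 0.5) & (t < 1.5), -100.0, 0.0)
        res = peak_and_baseline(_trace(t, v), (0.5, 1.5))
        assert res.baseline == 0.0
        assert res.peak_amplitude == 100.0
        assert res.sign == -1

    def test_flat_trace_flagged_no_response(self):
        t = np.arange(0, 2, 1e-3)
        res = peak_and_baseline(_trace(t, np.zeros_like(t)), (0.5, 1.5))
        assert res.peak_amplitude == 0.0
        assert "no_response" in res.flags

    def test_nonzero_baseline_subtracted(self):
        t = np.arange(0, 2, 1e-3)
        v = -50.0 + np.where((t >= 0.5) & (t < 1.5), -200.0, 0.0)
        res = peak_and_baseline(_trace(t, v), (0.5, 1.5))
        assert res.baseline == pytest.approx(-50.0)
        assert res.peak_amplitude == pytest.approx(200.0)

    def test_empty_window_rejected(self):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(AnalysisError):
            peak_and_baseline(_trace(t, np.zeros_like(t)), (5.0, 6.0))

    def test_simulated_peak_equals_state_maximum(self, control_rates):
        """Trace-level peak agrees with the open-state occupancy solution."""
        protocol = PulseProtocol.single_pulse(
            0.01, 2.0, baseline=0.5, sampling_interval=1e-3
        )
        trace = simulate(control_rates, protocol)
        res = peak_and_baseline(trace, (0.5, 2.5))
        open_occ = trace.states[trace.state_names.index("A3Ro")]
        assert res.peak_amplitude == pytest.approx(open_occ.max(), rel=1e-9)


class TestRiseTime:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(tau=st.floats(2e-3, 0.5))
    def test_monoexponential_closed_form(self, tau):
        """For 1 - exp(-t/tau) the 10-90% rise time is tau * ln 9."""
        t = np.arange(0, 6 * tau, tau / 200)
        v = 1.0 - np.exp(-t / tau)
        res = rise_time_10_90(_trace(t, v), baseline=0.0, peak_amplitude=v.max())
        assert res.seconds == pytest.approx(tau * np.log(9.0), rel=1e-2)

    def test_instantaneous_step_flagged_resolution_limited(self):
        t = np.arange(0, 1, 1e-3)
        v = np.where(t >= 0.5, 1.0, 0.0)
        res = rise_time_10_90(_trace(t, v), baseline=0.0, peak_amplitude=1.0)
        assert res.seconds <= 2e-3
        assert res.resolution_limited

    def test_no_onset_raises(self):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(AnalysisError, match="onset"):
            rise_time_10_90(_trace(t, np.full_like(t, 0.01)),
                            baseline=0.0, peak_amplitude=1.0)

    def test_grid_refinement_consistency(self, control_rates):
        """Rise time at 1 kHz matches a 10x finer recomputation to one sample."""
        values = {}
        for dt in (1e-3, 1e-4):
            protocol = PulseProtocol.single_pulse(0.01, 2.0, sampling_interval=dt)
            trace = simulate(control_rates, protocol, keep_states=False)
            values[dt] = rise_time_10_90(
                trace, baseline=0.0, peak_amplitude=trace.value.max()
            ).seconds
        assert abs(values[1e-3] - values[1e-4]) < 1e-3


class TestBiexponentialFit:
    @pytest.mark.parametrize(
        "amp_f, tau_f, amp_s, tau_s",
        [(0.6, 0.040, 0.4, 0.800), (300.0, 0.120, 80.0, 2.5)],
    )
    def test_noiseless_self_recovery(self, amp_f, tau_f, amp_s, tau_s):
        t = np.arange(0, 2.0, 1e-3)
        v = amp_f * np.exp(-t / tau_f) + amp_s * np.exp(-t / tau_s)
        fit = fit_biexponential(_trace(t, v))
        for got, true in [(fit.amp_fast, amp_f), (fit.tau_fast, tau_f),
                          (fit.amp_slow, amp_s), (fit.tau_slow, tau_s)]:
            assert abs(got / true - 1.0) < 1e-3
        assert fit.tau_fast < fit.tau_slow
        assert fit.r_squared > 0.999999

    def test_monoexponential_input_flagged_degenerate(self):
        t = np.arange(0, 2.0, 1e-3)
        v = 1.0 * np.exp(-t / 0.3)
        fit = fit_biexponential(_trace(t, v))
        assert "effectively_monoexponential" in fit.flags

    def test_noisy_tau_slow_calibration(self):
        """2% additive noise: median tau_slow error across replicates < 5%."""
        rng = np.random.default_rng(42)
        t = np.arange(0, 2.0, 1e-3)
        clean = 0.6 * np.exp(-t / 0.040) + 0.4 * np.exp(-t / 0.800)
        errors = []
        for _ in range(50):
            noisy = clean + rng.normal(0, 0.02 * clean.max(), t.size)
            fit = fit_biexponential(_trace(t, noisy))
            errors.append(abs(fit.tau_slow / 0.800 - 1.0))
        assert np.median(errors) < 0.05

    def test_short_window_rejected(self):
        t = np.arange(0, 0.01, 1e-3)
        with pytest.raises(AnalysisError, match="samples"):
            fit_biexponential(_trace(t, np.exp(-t)))


class TestScalarFeatures:
    def test_recovery_ratio_definition(self):
        assert recovery_ratio(100.0, 24.0) == pytest.approx(24.0)
        assert recovery_ratio(338.0, 338.0) == pytest.approx(100.0)

    def test_recovery_needs_positive_first_peak(self):
        with pytest.raises(AnalysisError):
            recovery_ratio(0.0, 10.0)

    def test_current_density(self):
        assert current_density(338.0, 28.9) == pytest.approx(11.7, abs=0.05)
        assert current_density(0.0, 30.0) == 0.0
        assert current_density(100.0, 10.0) == 10.0
        with pytest.raises(AnalysisError):
            current_density(100.0, 0.0)


class TestCompareGroups:
    def test_identical_groups_rank_sum_p_one(self):
        group = [1.0, 1.0, 1.0, 1.0]
        res = compare_groups(group, group, method="rank-sum")
        assert res.p_value == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(AnalysisError):
            compare_groups([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("method", ["t-test", "rank-sum"])
    def test_power_at_three_sem_separation(self, method):
        """Two-sample detection power at a 3-SEM mean separation.

        For two groups of n = 30 whose means differ by 3 standard errors of
        one group mean, the standardized difference is 3/sqrt(2) ~ 2.12, so
        the two-sided power at alpha = 0.05 is ~0.56.  The simulated hit
        rate must sit in a generous band around that analytic value.
        """
        rng = np.random.default_rng(11)
        n, sd = 30, 1.0
        sep = 3.0 * sd / np.sqrt(n)
        n_rep = 500
        hits = 0
        for _ in range(n_rep):
            a = rng.normal(0.0, sd, n)
            b = rng.normal(sep, sd, n)
            if compare_groups(a, b, method=method).p_value < 0.05:
                hits += 1
        assert 0.40 <= hits / n_rep <= 0.70
        # report matches the mean +/- SEM convention
        res = compare_groups(a, b, method=method)
        assert res.sem_a == pytest.approx(sd / np.sqrt(n), rel=0.5)
        assert res.n_a == n

    def test_strongly_separated_groups_power(self):
        """A 3-SD separation is essentially always detected."""
        rng = np.random.default_rng(5)
        hits = sum(
            compare_groups(rng.normal(0, 1, 30), rng.normal(3, 1, 30)).p_value < 0.05
            for _ in range(100)
        )
        assert hits >= 95


class TestFullExtraction:
    def test_resampling_invariance_on_simulated_trace(self, control_rates):
        """Features at 1 kHz and 2 kHz sampling agree within tolerances."""
        feats = {}
        for dt in (1e-3, 5e-4):
            protocol = PulseProtocol.single_pulse(
                0.01, 2.0, baseline=0.5, sampling_interval=dt
            )
            trace = simulate(control_rates, protocol, keep_states=False)
            feats[dt] = extract_features(trace, 0.5, 2.5)
        a, b = feats[1e-3], feats[5e-4]
        assert a.peak_amplitude == pytest.approx(b.peak_amplitude, rel=1e-4)
        assert a.rise_time_10_90 == pytest.approx(b.rise_time_10_90, abs=1e-3)
        assert a.tau_fast == pytest.approx(b.tau_fast, rel=0.02)
        assert a.tau_slow == pytest.approx(b.tau_slow, rel=0.02)

    def test_recovery_and_density_attached(self, control_rates):
        protocol = PulseProtocol.single_pulse(
            0.01, 2.0, baseline=0.5, sampling_interval=1e-3
        )
        trace = simulate(control_rates, protocol, keep_states=False)
        feats = extract_features(
            trace, 0.5, 2.5, capacitance_pF=2.0,
            second_peak=0.24 * trace.value.max(),
        )
        assert feats.recovery_percent == pytest.approx(24.0)
        assert feats.current_density == pytest.approx(feats.peak_amplitude / 2.0)
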