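"""Spike detection, pulse trains, periodograms and the SNR estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srneuron.experiment_pipeline import make_fixtures
from srneuron.membrane_sim import SimulationTrace
from srneuron.spike_spectral_analysis import (
    PSDEstimate,
    PULSE_AMPLITUDE,
    SpikeTrain,
    adjacent_psd_correlation,
    averaged_psd,
    detect_spikes,
    firing_rate_stats,
    pulse_train,
    snr,
    total_power,
)


def flat_trace(v_value=-65.0, n=10_000, dt=0.01):
    t = np.arange(n) * dt
    v = np.full(n, v_value)
    return SimulationTrace(t=t, v=v, v_total=v.copy(), dt=dt)


def psd_from_matrix(per_run, df=1.0):
    per_run = np.asarray(per_run, dtype=float)
    freqs = np.arange(per_run.shape[1]) * df
    return PSDEstimate(freqs=freqs, mean_psd=per_run.mean(0),
                       se_psd=per_run.std(0, ddof=1) / np.sqrt(len(per_run)),
                       n_runs=len(per_run), per_run=per_run)


class TestDetectSpikes:
    def test_subthreshold_trace_has_no_spikes(self):
        assert detect_spikes(flat_trace()).n_spikes == 0

    def test_known_crossings_recovered(self):
        times = [100.0, 120.0, 140.0]
        trace = make_fixtures("analytic_crossing_trace",
                              {"crossing_times": times})
        detected = detect_spikes(trace)
        assert detected.n_spikes == 3
        np.testing.assert_allclose(detected.times, times, atol=0.02)

    def test_dead_time_suppresses_double_crossings(self):
        trace = flat_trace()
        # two upward excursions 0.5 ms apart -> one spike at 2 ms dead time
        for t0 in (50.0, 50.5):
            idx = int(t0 / trace.dt)
            trace.v[idx:idx + 10] = 20.0
            trace.v[idx + 10:idx + 20] = -65.0
        assert detect_spikes(trace).n_spikes == 1
        assert detect_spikes(trace, dead_time=0.3).n_spikes == 2

    def test_nonfinite_trace_rejected(self):
        trace = flat_trace()
        trace.v[5] = np.nan
        with pytest.raises(ValueError):
            detect_spikes(trace)


class TestPulseTrain:
    def test_empty_train_gives_all_zero_bins(self):
        u = pulse_train(SpikeTrain(np.array([]), 1.0))
        assert u.samples.shape == (2000,)
        assert not u.samples.any()

    def test_each_spike_is_one_full_height_bin(self):
        u = pulse_train(SpikeTrain(np.array([10.0, 30.0, 50.0]), 1.0))
        nz = u.samples[u.samples != 0]
        assert len(nz) == 3
        assert (nz == PULSE_AMPLITUDE).all()

    @given(st.lists(st.integers(0, 1995), min_size=0, max_size=40,
                    unique=True))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nonzero_bins_equal_spike_count(self, bins):
        times = np.sort(np.array(bins, dtype=float) * 0.5) + 0.01
        u = pulse_train(SpikeTrain(times, 1.0))
        assert (u.samples != 0).sum() == len(bins)

    def test_shared_bin_rejected(self):
        with pytest.raises(ValueError):
            pulse_train(SpikeTrain(np.array([10.0, 10.2]), 1.0), bin_width=0.5)


class TestTotalPower:
    def test_zero_and_linearity_in_spike_count(self):
        empty = pulse_train(SpikeTrain(np.array([]), 1.0))
        assert total_power(empty) == 0.0
        one = pulse_train(SpikeTrain(np.array([10.0]), 1.0))
        two = pulse_train(SpikeTrain(np.array([10.0, 500.0]), 1.0))
        assert total_power(two) == pytest.approx(2 * total_power(one))
        assert total_power(one) == pytest.approx(PULSE_AMPLITUDE ** 2 / 2000)


class TestAveragedPSD:
    def test_zero_runs_give_zero_spectrum(self):
        pulses = [pulse_train(SpikeTrain(np.array([]), 1.0))
                  for _ in range(3)]
        psd = averaged_psd(pulses)
        assert not psd.mean_psd.any()
        assert psd.df == pytest.approx(1.0)
        assert psd.freqs[-1] == pytest.approx(1000.0)  # Nyquist of 2 kHz

    def test_periodic_train_concentrates_at_harmonics(self):
        train = make_fixtures("periodic_train", {"frequency": 100.0})
        psd = averaged_psd([pulse_train(train)] * 2)
        harmonics = np.isclose(psd.freqs % 100.0, 0) & (psd.freqs > 0)
        off_peak = psd.mean_psd[~harmonics & (psd.freqs > 0)]
        assert psd.mean_psd[psd.freqs == 100.0][0] > 0
        assert np.abs(off_peak).max() < 1e-12 * psd.mean_psd.max()

    def test_parseval_identity_per_run(self, rng):
        trains = make_fixtures("poisson_trains",
                               {"rate": 30.0, "n_runs": 4}, seed=3)
        pulses = [pulse_train(tr) for tr in trains]
        psd = averaged_psd(pulses)
        for run, pulse in enumerate(pulses):
            spectral = psd.per_run[run].sum() * psd.df
            temporal = (pulse.samples ** 2).mean()
            assert spectral == pytest.approx(temporal, rel=1e-9)

    def test_mismatched_runs_rejected(self):
        a = pulse_train(SpikeTrain(np.array([]), 1.0))
        b = pulse_train(SpikeTrain(np.array([]), 0.5))
        with pytest.raises(ValueError):
            averaged_psd([a, b])


class TestSNR:
    def test_peak_over_background_arithmetic(self):
        per_run = np.tile([1.0, 2.0, 10.0, 2.0, 1.0], (5, 1))
        per_run += np.random.default_rng(0).normal(0, 1e-6, per_run.shape)
        est = snr(psd_from_matrix(per_run), 2.0)
        assert est.snr == pytest.approx(5.0, rel=1e-4)
        assert est.valid

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        per_run = rng.exponential(1.0, (40, 9)) + 0.5
        a = snr(psd_from_matrix(per_run), 4.0)
        b = snr(psd_from_matrix(per_run * 137.0), 4.0)
        assert b.snr == pytest.approx(a.snr, rel=1e-12)
        assert b.se / b.snr == pytest.approx(a.se / a.snr, rel=1e-9)

    def test_silent_batch_flagged_invalid(self):
        est = snr(psd_from_matrix(np.zeros((4, 9))), 4.0)
        assert not est.valid
        assert np.isnan(est.snr)

    def test_no_signal_null_concentrates_at_one(self):
        # independent Poisson trains: flat expected spectrum -> SNR ~ 1
        trains = make_fixtures("poisson_trains",
                               {"rate": 30.0, "n_runs": 300}, seed=8)
        psd = averaged_psd([pulse_train(tr) for tr in trains])
        est = snr(psd, 150.0)
        assert est.snr == pytest.approx(1.0, abs=3 * est.se)
        assert est.snr >= 0

    def test_error_propagation_limits(self):
        rng = np.random.default_rng(4)
        base = np.full(9, 10.0)
        # independent fluctuations on peak and background bins:
        # relative SE of the ratio -> eps * sqrt(2)
        eps_runs = rng.normal(0, 1.0, (400, 9))
        per_run = base + eps_runs
        est = snr(psd_from_matrix(per_run), 4.0)
        sd = 1.0 / np.sqrt(400)
        expected_rel = np.sqrt((sd / 10.0) ** 2
                               + (sd / np.sqrt(2) / 10.0) ** 2)
        assert est.se / est.snr == pytest.approx(expected_rel, rel=0.2)
        # perfectly correlated equal relative fluctuations cancel
        common = rng.normal(0, 1.0, 400)
        per_run = base[None, :] * (1.0 + 0.1 * common[:, None])
        est = snr(psd_from_matrix(per_run), 4.0)
        assert est.snr == pytest.approx(1.0, rel=1e-9)
        assert est.se < 1e-9


class TestAdjacentCorrelation:
    def test_identical_spectra_degenerate(self):
        per_run = np.tile([1.0, 2.0, 3.0, 2.0, 1.0], (12, 1))
        corr = adjacent_psd_correlation(psd_from_matrix(per_run), 2.0)
        assert corr["lo_hi"] is None

    def test_independent_trains_uncorrelated(self):
        trains = make_fixtures("poisson_trains",
                               {"rate": 30.0, "n_runs": 300}, seed=9)
        psd = averaged_psd([pulse_train(tr) for tr in trains])
        corr = adjacent_psd_correlation(psd, 150.0)
        # SE of a null Pearson correlation ~ 1/sqrt(R)
        assert abs(corr["lo_hi"]) < 3 / np.sqrt(300)


class TestFiringRateStats:
    def test_empty_trains_give_zero(self):
        trains = [SpikeTrain(np.array([]), 1.0) for _ in range(5)]
        assert firing_rate_stats(trains) == (0.0, 0.0)

    def test_poisson_rate_recovered(self):
        trains = make_fixtures("poisson_trains",
                               {"rate": 20.0, "n_runs": 300}, seed=10)
        mean, se = firing_rate_stats(trains)
        assert abs(mean - 20.0) < 3 * max(se, np.sqrt(20 / 300))
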