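"""Analysis stack: filtering, phase, PSI, segmentation, STAP, averaging."""

import numpy as np
import pytest
from scipy import signal as sps

from swdsim.analysis import (BandpassSpec, ap_eeg_crosscorrelation,
                             classify_cycle_firing, design_swd_bandpass,
                             hilbert_phase, period_scaled_average,
                             phase_synchronization_index, segment_ictal,
                             stap_histogram)
from swdsim.fixtures import SyntheticSWDSpec, generate_synthetic_eeg

FS = 1000.0


class TestBandpassDesign:
    @pytest.fixture(scope="class")
    def design(self):
        return design_swd_bandpass(BandpassSpec(center_freq=4.0), FS)

    def test_passband_within_half_decibel(self, design):
        mags = design.magnitude_db(np.linspace(2.0, 6.0, 401))
        assert mags.max() - mags.min() <= 0.5 + 1e-6

    def test_stopband_attenuation_at_least_65_db(self, design):
        att = -design.magnitude_db([8.0])  # upper stopband edge
        assert att[0] >= 65.0

    def test_zero_phase_sinusoid_amplitude_preserved(self, design):
        t = np.arange(0, 30.0, 1 / FS)
        x = np.cos(2 * np.pi * 4.0 * t)
        y = design.apply(x)
        mid = slice(int(5 * FS), int(25 * FS))
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.06)

    def test_sampling_rate_prerequisite(self):
        with pytest.raises(ValueError):
            design_swd_bandpass(BandpassSpec(center_freq=7.0), 50.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BandpassSpec(center_freq=4.0, passband_halfwidth=5.0,
                         stopband_halfwidth=4.0)


class TestHilbertPhase:
    def test_cosine_phase_advances_at_signal_frequency(self):
        f = 4.0
        t = np.arange(0, 20.0, 1 / FS)
        phase = hilbert_phase(np.cos(2 * np.pi * f * t))
        mid = slice(int(2 * FS), int(18 * FS))
        fitted = np.polyfit(t[mid], phase[mid], 1)[0] / (2 * np.pi)
        assert fitted == pytest.approx(f, abs=0.01)
        resid = phase[mid] - np.polyval(np.polyfit(t[mid], phase[mid], 1), t[mid])
        assert np.abs(resid).max() < 0.05

    def test_half_period_shift_is_pi(self):
        f = 5.0
        t = np.arange(0, 10.0, 1 / FS)
        a = hilbert_phase(np.cos(2 * np.pi * f * t))
        b = hilbert_phase(np.cos(2 * np.pi * f * t - np.pi))
        mid = slice(int(2 * FS), int(8 * FS))
        d = np.angle(np.exp(1j * (a[mid] - b[mid])))
        assert np.abs(np.abs(d) - np.pi).max() < 0.05

    def test_amplitude_modulation_does_not_distort_phase(self):
        f = 4.0
        t = np.arange(0, 20.0, 1 / FS)
        carrier = np.cos(2 * np.pi * f * t)
        am = (1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)) * carrier
        mid = slice(int(2 * FS), int(18 * FS))
        d = hilbert_phase(am)[mid] - hilbert_phase(carrier)[mid]
        assert np.abs(d - d.mean()).max() < 0.1

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.ones(1000))


class TestPSI:
    def test_constant_phase_offset_gives_unity(self):
        t = np.arange(0, 10.0, 1 / FS)
        a = 2 * np.pi * 4.0 * t
        out = phase_synchronization_index(a, a + 1.234, FS)
        assert np.all(out.psi >= 0) and np.all(out.psi <= 1)
        assert out.psi[int(2 * FS):int(8 * FS)].min() > 0.999

    def test_independent_phases_match_rayleigh_baseline(self):
        """For i.i.d. uniform phase differences the expected windowed PSI
        is sqrt(pi)/2 / sqrt(n); checked against Monte-Carlo within 20%."""
        rng = np.random.default_rng(0)
        n_win = int(FS)
        a = rng.uniform(0, 2 * np.pi, 60000)
        b = rng.uniform(0, 2 * np.pi, 60000)
        out = phase_synchronization_index(a, b, FS)
        expected = np.sqrt(np.pi) / 2.0 / np.sqrt(n_win)
        measured = out.psi[n_win:-n_win].mean()
        assert measured == pytest.approx(expected, rel=0.2)

    def test_transition_detected(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 20.0, 1 / FS)
        a = 2 * np.pi * 4.0 * t
        b = a.copy()
        half = t.size // 2
        b[half:] = rng.uniform(0, 2 * np.pi, t.size - half)
        out = phase_synchronization_index(a, b, FS)
        assert out.psi[int(3 * FS):int(8 * FS)].mean() > 0.95
        assert out.psi[int(12 * FS):int(18 * FS)].mean() < 0.3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            phase_synchronization_index(np.zeros(10), np.zeros(11), FS)

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        a = np.cumsum(rng.normal(0.02, 0.01, 20000))
        b = np.cumsum(rng.normal(0.02, 0.01, 20000))
        p1 = phase_synchronization_index(a, b, FS).psi
        p2 = phase_synchronization_index(a + 2.0, b, FS).psi
        assert np.allclose(p1, p2)


class TestSegmentIctal:
    def test_flat_noise_has_no_ictal_intervals(self):
        rng = np.random.default_rng(3)
        seg = segment_ictal(rng.normal(size=int(60 * FS)), FS)
        assert seg.n_seizures == 0

    def test_single_train_recovered_exactly(self):
        spec = SyntheticSWDSpec(swd_frequency=4.0, n_seizures=1,
                                seizure_durations=(10.0,),
                                interictal_durations=(15.0,), noise_sd=0.0, seed=0)
        eeg, truth = generate_synthetic_eeg(spec)
        seg = segment_ictal(eeg, FS)
        assert seg.n_seizures == 1
        assert seg.dominant_frequency[0] == pytest.approx(4.0, abs=0.2)
        assert abs(len(seg.swd_spike_times[0]) - 40) <= 1

    def test_two_trains_two_intervals(self):
        spec = SyntheticSWDSpec(swd_frequency=4.0, n_seizures=2,
                                seizure_durations=(8.0,),
                                interictal_durations=(12.0,), noise_sd=0.3, seed=1)
        eeg, _ = generate_synthetic_eeg(spec)
        seg = segment_ictal(eeg, FS)
        assert seg.n_seizures == 2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            segment_ictal(np.zeros(int(10 * FS)), FS)

    def test_noisy_recall(self):
        """>= 90% of seizures recovered at spike-amplitude/noise ratio 3."""
        spec = SyntheticSWDSpec(swd_frequency=4.0, n_seizures=5,
                                seizure_durations=(8.0,),
                                interictal_durations=(20.0,),
                                spike_amplitude=5.0, noise_sd=5.0 / 3.0, seed=2)
        eeg, _ = generate_synthetic_eeg(spec)
        seg = segment_ictal(eeg, FS)
        assert seg.n_seizures >= 0.9 * 5


class TestSTAP:
    def test_spikes_at_triggers_fill_zero_lag_bin(self):
        trig = np.arange(1000.0, 11000.0, 250.0)
        hist = stap_histogram([trig.copy()], trig, "all_APs")
        assert hist.peak_lag() == 0.0
        assert hist.density[hist.lags == 0.0][0] == pytest.approx(1.0)

    def test_constructed_lead_recovered(self):
        trig = np.arange(1000.0, 11000.0, 250.0)
        hist = stap_histogram([trig - 30.0], trig, "all_APs")
        assert hist.peak_lag() == -30.0

    def test_poisson_spikes_are_flat(self):
        """Independent Poisson spikes give a uniform histogram (chi^2)."""
        rng = np.random.default_rng(4)
        trig = np.arange(5000.0, 1000000.0, 250.0)
        trains = [np.sort(rng.uniform(0, 1005000.0, 40000)) for _ in range(3)]
        hist = stap_histogram(trains, trig, "all_APs")
        counts = hist.density * trig.size
        expected = counts.mean()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # dof = bins - 1; generous 99.9% bound
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, counts.size - 1)

    def test_first_ap_variant_mass_bounded(self):
        rng = np.random.default_rng(5)
        trig = np.arange(1000.0, 61000.0, 250.0)
        trains = [np.sort(rng.uniform(0, 62000.0, 2000)) for _ in range(5)]
        hist = stap_histogram(trains, trig, "first_AP_per_cycle")
        # at most one first AP per neuron per cycle
        assert hist.density.sum() <= len(trains) + 1e-9

    def test_empty_spikes_zero_histogram(self):
        trig = np.arange(1000.0, 5000.0, 250.0)
        hist = stap_histogram([np.empty(0)], trig, "all_APs")
        assert np.all(hist.density == 0)

    def test_no_triggers_rejected(self):
        with pytest.raises(ValueError):
            stap_histogram([np.array([1.0])], np.empty(0))


class TestCycleFiring:
    def test_labels_follow_criteria(self):
        bounds = [0.0, 100.0, 200.0, 300.0]
        trains = [
            np.array([]),                        # silent everywhere
            np.array([10.0, 14.0, 18.0]),        # burst in cycle 0
            np.array([110.0, 160.0, 250.0]),     # tonic in cycles 1 and 2
        ]
        out = classify_cycle_firing(trains, bounds)
        assert list(out.labels[0]) == ["silent", "silent", "silent"]
        assert out.labels[1][0] == "burst"
        assert out.labels[2][1] == "tonic" and out.labels[2][2] == "tonic"
        assert out.proportions["silent"] == pytest.approx(
            1.0 - out.proportions["burst"] - out.proportions["tonic"])

    def test_two_spaced_spikes_are_tonic(self):
        out = classify_cycle_firing([np.array([10.0, 60.0])], [0.0, 100.0])
        assert out.labels[0][0] == "tonic"


class TestPeriodScaledAverage:
    def test_identical_periods_average_to_themselves(self):
        p = np.sin(np.linspace(0, np.pi, 100))
        mean, lo, hi = period_scaled_average([p.copy(), p.copy(), p.copy()])
        assert np.allclose(mean, p, atol=1e-12)

    def test_two_period_toy_matches_closed_form(self):
        a = np.full(100, 2.0)
        b = np.full(200, 4.0)
        mean, _, _ = period_scaled_average([a, b])
        assert mean.size == 150
        assert np.allclose(mean, 3.0)

    def test_constant_rate_invariant_under_scaling(self):
        periods = [np.full(n, 7.0) for n in (80, 120, 160)]
        mean, _, _ = period_scaled_average(periods)
        assert np.allclose(mean, 7.0)

    def test_event_count_preserved_within_two_percent(self):
        rng = np.random.default_rng(6)
        periods = [rng.poisson(5.0, n).astype(float) for n in (400, 500, 600)]
        mean, _, _ = period_scaled_average(periods)
        mean_count = np.mean([p.sum() / p.size for p in periods])
        assert mean.mean() == pytest.approx(mean_count, rel=0.02)

    def test_single_period_warns(self):
        with pytest.warns(UserWarning):
            period_scaled_average([np.arange(10.0)])


class TestAPEEGCrossCorrelation:
    def _eeg_and_locked_spikes(self, sign=1.0):
        t = np.arange(0, 60.0, 1 / FS)
        eeg = sign * np.cos(2 * np.pi * 4.0 * t)
        peaks = np.arange(0.0, 60000.0, 250.0)
        return eeg, peaks

    def test_spikes_locked_to_peaks_peak_at_zero_lag(self):
        eeg, spikes = self._eeg_and_locked_spikes()
        lags, corr, _ = ap_eeg_crosscorrelation(spikes, eeg, FS, max_lag_ms=200.0)
        assert abs(lags[np.argmax(corr)]) <= 2.0

    def test_spikes_locked_to_troughs_negative_peak(self):
        eeg, spikes = self._eeg_and_locked_spikes(sign=-1.0)
        lags, corr, _ = ap_eeg_crosscorrelation(spikes, eeg, FS, max_lag_ms=200.0)
        assert corr[np.argmin(np.abs(lags))] < 0

    def test_shuffled_spikes_within_confidence_band(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 60.0, 1 / FS)
        eeg = np.cos(2 * np.pi * 4.0 * t)
        spikes = rng.uniform(0, 60000.0, 600)
        lags, corr, (lo, hi) = ap_eeg_crosscorrelation(spikes, eeg, FS,
                                                       max_lag_ms=200.0)
        assert np.abs(corr).max() <= hi * 1.5
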