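"""Detector behavior: injected-event recovery, explicit criteria, invariants."""

import numpy as np
import pytest
from scipy import signal as sps

import hfokit as hk
from hfokit.detect import DetectorConfig, HfoEvent, event_rate
from hfokit.simulate import _hfo_waveform, _ied_waveform

from conftest import check_hfo_event, check_hfo_events


def _pink(rng, n, fs, rms=50.0):
    """1/f^1.5 background via the generator (single channel)."""
    cfg = hk.GeneratorConfig(
        fs=fs, n_channels=1, duration_s=n / fs, seed=int(rng.integers(2**31)),
        line_noise_rms_uv=0.0,
    )
    return hk.generate_background(cfg)


class TestIed:
    def test_injected_spikes_recovered(self):
        """20 well-separated high-SNR spikes are all found within 50 ms."""
        fs = 2000.0
        rec = _pink(np.random.default_rng(1), int(120 * fs), fs)
        truth = []
        for k in range(20):
            onset = int((5.0 + 5.0 * k) * fs)
            w = _ied_waveform(fs, 0.04, 350.0)
            rec.signal[0, onset : onset + len(w)] += w
            truth.append(onset / fs + 0.02)  # biphasic peak near the center
        events = hk.detect_ied(rec, 0)
        assert len(events) == 20
        for t, ev in zip(truth, events):
            assert abs(ev.onset / fs - t) <= 0.05

    def test_refractory_excludes_second_spike(self):
        """Two spikes 0.5 s apart yield a single accepted event."""
        fs = 2000.0
        rec = _pink(np.random.default_rng(2), int(60 * fs), fs)
        for onset_s in (30.0, 30.5):
            w = _ied_waveform(fs, 0.04, 350.0)
            s = int(onset_s * fs)
            rec.signal[0, s : s + len(w)] += w
        events = hk.detect_ied(rec, 0)
        assert len(events) == 1
        assert abs(events[0].onset / fs - 30.0) < 0.1

    def test_refractory_invariant(self, busy_session):
        """No two accepted IEDs start within 1 s of each other."""
        rec, _truth, _cfg = busy_session
        events = hk.detect_ied(rec, 0)
        onsets = np.array([e.onset for e in events]) / rec.fs
        assert len(onsets) > 5
        assert np.all(np.diff(onsets) >= 1.0)

    def test_false_positive_bound_on_gaussian_noise(self):
        """<= 2 detections/min on 600 s of pure Gaussian noise at defaults."""
        rng = np.random.default_rng(3)
        rec = hk.Recording(signal=50.0 * rng.standard_normal((1, int(600 * 2000))), fs=2000.0)
        events = hk.detect_ied(rec, 0)
        assert len(events) / 10.0 <= 2.0

    def test_short_recording_raises(self):
        rec = hk.Recording(signal=np.zeros((1, 2000)), fs=1000.0)
        with pytest.raises(ValueError, match="10 s"):
            hk.detect_ied(rec, 0)

    def test_fully_masked_channel_warns_empty(self):
        rng = np.random.default_rng(4)
        rec = hk.Recording(signal=rng.standard_normal((1, 30000)), fs=1000.0)
        with pytest.warns(UserWarning, match="masked"):
            rec = hk.mask_artifacts(rec, [(0, 0.0, 30.0)])
        with pytest.warns(UserWarning, match="masked"):
            assert hk.detect_ied(rec, 0) == []


@pytest.fixture(scope="module")
def seizure_session():
    cfg = hk.GeneratorConfig(
        fs=2000.0, n_channels=1, duration_s=600.0, seed=8,
        seizure_times_s=(300.0,), seizure_duration_s=30.0,
    )
    return hk.generate_session(cfg)


class TestSeizure:
    def test_injected_seizure_recovered(self, seizure_session):
        """One 30 s seizure in 10 min: one event, boundaries within 2 s."""
        rec, truth = seizure_session
        events = hk.detect_seizure(rec, 0)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.onset / rec.fs - 300.0) <= 2.0
        assert abs(ev.offset / rec.fs - 330.0) <= 2.0
        assert 12.0 <= ev.duration_s(rec.fs) <= 45.0

    def test_peak_frequency_histogram_populated(self, seizure_session):
        rec, _ = seizure_session
        ev = hk.detect_seizure(rec, 0)[0]
        hist = np.asarray(ev.features["peak_freq_hist"])
        assert hist.sum() > 0
        # the injected rhythmic discharge sweeps 7 -> 3 Hz
        assert 1.0 <= ev.features["dominant_freq_hz"] <= 10.0

    def test_stationary_noise_no_events(self):
        cfg = hk.GeneratorConfig(fs=2000.0, n_channels=1, duration_s=600.0, seed=9)
        rec = hk.generate_background(cfg)
        assert hk.detect_seizure(rec, 0) == []

    def test_zero_signal_no_events(self):
        rec = hk.Recording(signal=np.zeros((1, int(120 * 500))), fs=500.0)
        with pytest.warns(UserWarning, match="rolling"):
            assert hk.detect_seizure(rec, 0) == []

    def test_specificity_across_seeds(self):
        """Baseline recordings yield no seizure detections in >= 95% of seeds."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = hk.GeneratorConfig(fs=1000.0, n_channels=1, duration_s=360.0, seed=900 + seed)
            rec = hk.generate_background(cfg)
            clean += len(hk.detect_seizure(rec, 0)) == 0
        assert clean / n_seeds >= 0.95

    def test_short_context_raises(self):
        rec = hk.Recording(signal=np.zeros((1, 500 * 30)), fs=500.0)
        with pytest.raises(ValueError, match="60 s"):
            hk.detect_seizure(rec, 0)


class TestHfo:
    def test_injected_ripples_recovered(self):
        """10 hand-placed 140 Hz ripples at SNR 3: >= 9 found within 20 ms, all valid."""
        fs = 2000.0
        cfg = hk.GeneratorConfig(fs=fs, n_channels=1, duration_s=600.0, seed=12, line_noise_rms_uv=0.0)
        rec = hk.generate_background(cfg)
        from hfokit.simulate import band_rms_background

        floor = band_rms_background(cfg, (100.0, 0.45 * fs))
        rng = np.random.default_rng(1)
        truth = []
        for k in range(10):
            onset = int((30.0 + 55.0 * k) * fs)
            w = _hfo_waveform(fs, 140.0, 6.0, 3.0 * floor / 0.384, rng)
            rec.signal[0, onset : onset + len(w)] += w
            truth.append(onset / fs)
        dc = DetectorConfig()
        events = hk.detect_hfo(rec, 0, dc)
        matched = sum(
            1 for t in truth if any(abs(e.onset / fs - t) <= 0.02 + 6.0 / 140.0 for e in events)
        )
        assert matched >= 9
        for ev in events:
            assert ev.duration_s(fs) >= 0.006
            assert ev.n_rectified_peaks >= 6
            assert check_hfo_event(rec, ev, dc) == []

    def test_short_burst_rejected(self):
        """A strong ~4 ms burst fails the 6 ms minimum-duration criterion."""
        fs = 4000.0
        cfg = hk.GeneratorConfig(fs=fs, n_channels=1, duration_s=120.0, seed=5, line_noise_rms_uv=0.0)
        rec = hk.generate_background(cfg)
        from hfokit.simulate import band_rms_background

        floor = band_rms_background(cfg, (100.0, 500.0))
        rng = np.random.default_rng(5)
        w = _hfo_waveform(fs, 250.0, 1.0, 8.0 * floor, rng)  # one cycle, 4 ms
        rec.signal[0, int(60 * fs) : int(60 * fs) + len(w)] += w
        assert hk.detect_hfo(rec, 0) == []

    def test_too_few_peaks_rejected(self):
        """A supra-threshold burst with only ~4 rectified peaks is rejected."""
        fs = 4000.0
        cfg = hk.GeneratorConfig(fs=fs, n_channels=1, duration_s=120.0, seed=6, line_noise_rms_uv=0.0)
        rec = hk.generate_background(cfg)
        from hfokit.simulate import band_rms_background

        floor = band_rms_background(cfg, (100.0, 500.0))
        rng = np.random.default_rng(6)
        w = _hfo_waveform(fs, 200.0, 2.0, 15.0 * floor, rng)  # two cycles, 10 ms
        rec.signal[0, int(60 * fs) : int(60 * fs) + len(w)] += w
        assert hk.detect_hfo(rec, 0) == []

    def test_detector_agrees_with_independent_checker(self, busy_session, detector_config):
        """Every emitted event passes the independent validity checker."""
        rec, _truth, _cfg = busy_session
        events = hk.detect_hfo(rec, 0, detector_config)
        assert len(events) > 50
        assert all(v == [] for v in check_hfo_events(rec, 0, events, detector_config))

    def test_threshold_monotonicity(self, busy_session):
        """Raising the RMS threshold never increases the detection count."""
        rec, _truth, _cfg = busy_session
        counts = []
        for sd in (3.0, 4.0, 5.0, 6.0, 8.0):
            cfg = DetectorConfig(hfo_rms_sd=sd)
            counts.append(len(hk.detect_hfo(rec, 0, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        """Shifting the input shifts detected boundaries, away from the edges."""
        fs = 2000.0
        cfg = hk.GeneratorConfig(
            fs=fs, n_channels=1, duration_s=120.0, seed=14,
            hfo_per_min={"hippocampus": 6.0}, line_noise_rms_uv=0.0,
        )
        rec, _ = hk.generate_session(cfg)
        k = int(0.5 * fs)
        shifted = hk.Recording(signal=np.roll(rec.signal, k, axis=1), fs=fs)
        ev0 = hk.detect_hfo(rec, 0)
        ev1 = hk.detect_hfo(shifted, 0)
        on0 = [e.onset for e in ev0 if k < e.onset < rec.n_samples - 2 * k]
        on1 = [e.onset - k for e in ev1 if k < e.onset - k < rec.n_samples - 2 * k]
        assert len(on0) > 3
        for a in on0:
            assert min(abs(a - b) for b in on1) <= 2

    def test_low_fs_raises(self):
        rec = hk.Recording(signal=np.zeros((1, 10000)), fs=500.0)
        with pytest.raises(ValueError, match="1000"):
            hk.detect_hfo(rec, 0)

    def test_band_clipped_with_warning(self):
        rng = np.random.default_rng(7)
        rec = hk.Recording(signal=rng.standard_normal((1, 60000)), fs=1000.0)
        with pytest.warns(UserWarning, match="clipped"):
            hk.detect_hfo(rec, 0)


class TestPeakFrequency:
    @pytest.mark.parametrize("freq", [140.0, 200.0])
    def test_pure_ripple_frequency(self, freq):
        fs = 4000.0
        cfg = hk.GeneratorConfig(fs=fs, n_channels=1, duration_s=60.0, seed=15, line_noise_rms_uv=0.0)
        rec = hk.generate_background(cfg)
        rng = np.random.default_rng(2)
        onset = int(30 * fs)
        w = _hfo_waveform(fs, freq, 8.0, 300.0, rng)
        rec.signal[0, onset : onset + len(w)] += w
        ev = HfoEvent(
            kind="HFO", channel=0, onset=onset, offset=onset + len(w), peak_amplitude=300.0
        )
        assert hk.hfo_peak_frequency(ev, rec) == pytest.approx(freq, abs=2.0)

    def test_population_mean_recovered(self, busy_session):
        """Detected peak frequencies recover the generator's ripple-frequency mean."""
        rec, truth, cfg = busy_session
        events = hk.detect_hfo(rec, 0) + hk.detect_hfo(rec, 1)
        assert len(events) >= 100
        det_mean = np.mean([e.peak_frequency for e in events])
        true_mean = np.mean([e.freq_hz for e in truth.events if e.kind == "HFO"])
        assert abs(det_mean - true_mean) <= 5.0


class TestEventRate:
    def test_basic_rate(self):
        assert event_rate(range(28), 2.0) == pytest.approx(14.0)
        assert event_rate([], 5.0) == 0.0

    def test_mask_adjusted_denominator(self):
        rng = np.random.default_rng(8)
        rec = hk.Recording(signal=rng.standard_normal((1, 60000)), fs=1000.0)
        rec = hk.mask_artifacts(rec, [(0, 0.0, 30.0)])
        minutes = rec.analyzable_duration(0) / 60.0
        assert event_rate(range(10), minutes) == pytest.approx(20.0)

    def test_zero_duration_raises(self):
        with pytest.raises(ZeroDivisionError):
            event_rate([1], 0.0)


def test_events_never_overlap_masked_intervals(busy_session):
    rec, _truth, _cfg = busy_session
    masked = hk.mask_artifacts(rec, [(0, 100.0, 140.0)])
    for detector in (hk.detect_ied, hk.detect_hfo):
        for ev in detector(masked, 0):
            assert not (ev.onset < 140.0 * rec.fs and 100.0 * rec.fs < ev.offset)
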