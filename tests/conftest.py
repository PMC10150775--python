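"""Shared fixtures: small synthetic recordings and an independent HFO checker."""

import numpy as np
import pytest
from scipy import signal as sps

import hfokit as hk
from hfokit.detect import DetectorConfig, _bandpass_sos


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def baseline_2ch():
    """120 s, 2-channel, 1 kHz baseline background (4 + 10 Hz peaks, 1/f)."""
    cfg = hk.GeneratorConfig(fs=1000.0, n_channels=2, duration_s=120.0, seed=21)
    return hk.generate_background(cfg), cfg


@pytest.fixture(scope="session")
def postka_2ch():
    cfg = hk.GeneratorConfig(fs=1000.0, n_channels=2, duration_s=120.0, seed=21, state="postka")
    return hk.generate_background(cfg), cfg


@pytest.fixture(scope="session")
def busy_session():
    """10-min, 2-channel, 4 kHz post-insult session with IEDs + ripples and truth."""
    cfg = hk.GeneratorConfig(
        fs=4000.0,
        n_channels=2,
        duration_s=600.0,
        state="postka",
        seed=37,
        hfo_per_min={"hippocampus": 10.0},
        ied_per_min=3.0,
    )
    rec, truth = hk.generate_session(cfg)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """Desk-scale study dataset: 3 E+ / 2 E- animals, 2-min sessions."""
    root = tmp_path_factory.mktemp("study")
    manifest = hk.default_study_manifest(
        n_eplus=3, n_eminus=2, seed=11, session_duration_s=120.0
    )
    with np.errstate(all="ignore"):
        data = hk.generate_study(manifest, seed=11, outdir=root)
    return data


def _hfo_channel_context(recording, channel, config: DetectorConfig):
    """Independent per-channel transforms for the ripple checker.

    Uses direct convolution for the RMS (not the detector's filter routine)
    and shares only the band-pass filter definition.
    """
    fs = recording.fs
    sos = _bandpass_sos(
        (config.hfo_band[0], min(config.hfo_band[1], 0.9 * fs / 2)), fs, config.filter_order
    )
    bp = sps.sosfiltfilt(sos, np.asarray(recording.signal[channel], dtype=np.float64))
    win = max(1, int(round(config.hfo_rms_window_ms * 1e-3 * fs)))
    kernel = np.ones(win) / win
    rms = np.sqrt(np.convolve(bp**2, kernel, mode="same"))
    rect = np.abs(bp)
    analyzable = recording.analyzable_mask(channel)
    rms_thr = rms[analyzable].mean() + config.hfo_rms_sd * rms[analyzable].std()
    rect_thr = rect[analyzable].mean() + config.hfo_peak_sd * rect[analyzable].std()
    return rms, rect, rms_thr, rect_thr


def check_hfo_events(recording, channel, events, config: DetectorConfig):
    """Independent re-verification of the published ripple criteria.

    For every event on one channel, re-checks with its own implementation:
      * duration >= the minimum, with >= one contiguous supra-threshold RMS
        run of that length inside the event,
      * RMS exceeding channel mean + 5 SD within the event,
      * >= 6 rectified peaks above channel mean + 3 SD in the event context.
    Returns a list (one entry per event) of violated-criteria lists.
    """
    fs = recording.fs
    rms, rect, rms_thr, rect_thr = _hfo_channel_context(recording, channel, config)
    min_len = config.hfo_min_duration_ms * 1e-3 * fs
    pad = int(round(config.hfo_peak_context_ms * 1e-3 * fs))
    out = []
    for event in events:
        violations = []
        if event.offset - event.onset < min_len:
            violations.append("duration")
        above = rms[event.onset : event.offset] >= rms_thr
        run, best = 0, 0
        for flag in above:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best < min_len:
            violations.append("rms_run")
        lo = max(0, event.onset - pad)
        hi = min(len(rect), event.offset + pad)
        seg = rect[lo:hi]
        n_peaks = sum(
            1
            for i in range(1, len(seg) - 1)
            if seg[i] > rect_thr and seg[i] >= seg[i - 1] and seg[i] > seg[i + 1]
        )
        if n_peaks < config.hfo_min_peaks:
            violations.append("peaks")
        out.append(violations)
    return out


def check_hfo_event(recording, event, config: DetectorConfig):
    """Single-event convenience wrapper around :func:`check_hfo_events`."""
    return check_hfo_events(recording, event.channel, [event], config)[0]
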