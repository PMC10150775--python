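"""Event detectors for intracranial LFP: interictal discharges, seizures, HFOs.

Three detectors, each a thresholding scheme on a band-limited transform of
one channel:

* **IED** (interictal epileptiform discharge): band-pass 25-80 Hz, analytic
  (Hilbert) envelope, threshold at twice the ongoing background amplitude,
  and a 1 s refractory rule — an IED within 1 s of an accepted IED is
  discarded so runs of spikes are not over-counted.
* **Seizure**: continuous-wavelet (Morlet) soft-threshold denoising, 1-25 Hz
  band energy in a sliding 1 s window, and a dynamic threshold of two
  standard deviations above a rolling (5 min) robust baseline.  Events also
  carry a peak-frequency histogram of the rhythmic discharge.
* **HFO** (high-frequency oscillation / ripple): band-pass 100-500 Hz,
  root-mean-square in a 3 ms window, events where successive RMS values
  exceed the channel mean by 5 SD for at least 6 ms, that additionally
  contain at least 6 rectified-signal peaks above mean + 3 SD.

Onsets/offsets are 0-based sample indices at the recording's native rate,
half-open ``[onset, offset)``.  Events overlapping artifact-masked intervals
are never emitted, and masked samples never enter threshold statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .edf import Recording

__all__ = [
    "DetectorConfig",
    "DetectedEvent",
    "HfoEvent",
    "detect_ied",
    "detect_seizure",
    "detect_hfo",
    "hfo_peak_frequency",
    "event_rate",
    "events_to_frame",
]


@dataclass
class DetectorConfig:
    """All detector parameters, in the units given.

    The defaults implement the study protocol: IED band 25-80 Hz with a
    2x-baseline threshold and 1 s refractory; seizure band 1-25 Hz with a
    2 SD dynamic threshold; HFO band 100-500 Hz, 3 ms RMS window, 5 SD RMS
    threshold, >= 6 ms duration and >= 6 rectified peaks above 3 SD.
    """

    ied_band: tuple[float, float] = (25.0, 80.0)
    ied_threshold_factor: float = 2.0
    ied_refractory_s: float = 1.0
    ied_analysis_fs: float = 400.0  # internal decimation target for the 25-80 Hz band

    seizure_band: tuple[float, float] = (1.0, 25.0)
    seizure_threshold_sd: float = 2.0
    seizure_min_duration_s: float = 10.0
    seizure_rolling_s: float = 300.0
    seizure_energy_window_s: float = 1.0
    seizure_n_scales: int = 32
    seizure_analysis_fs: float = 125.0

    hfo_band: tuple[float, float] = (100.0, 500.0)
    hfo_rms_window_ms: float = 3.0
    hfo_rms_sd: float = 5.0
    hfo_min_duration_ms: float = 6.0
    hfo_peak_sd: float = 3.0
    hfo_min_peaks: int = 6
    hfo_merge_gap_ms: float = 10.0
    hfo_peak_context_ms: float = 15.0  # padding around the RMS run for peak counting

    filter_order: int = 4

    def __post_init__(self):
        for name in ("ied_band", "seizure_band", "hfo_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < low < high")
        for name in (
            "ied_threshold_factor",
            "seizure_threshold_sd",
            "hfo_rms_sd",
            "hfo_peak_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DetectedEvent:
    """One detected interval event on one channel."""

    kind: str  # "IED" | "seizure" | "HFO"
    channel: int
    onset: int  # sample index, inclusive
    offset: int  # sample index, exclusive
    peak_amplitude: float  # uV, max |signal| within the event
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.onset >= self.offset:
            raise ValueError("event onset must precede offset")

    def duration_s(self, fs: float) -> float:
        return (self.offset - self.onset) / fs


@dataclass
class HfoEvent(DetectedEvent):
    peak_frequency: float = float("nan")  # Hz
    n_rectified_peaks: int = 0
    rms_trace: np.ndarray | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _bandpass_sos(band, fs, order):
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    return sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _runs(mask: np.ndarray):
    """Half-open [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask)]])
    return list(zip(starts.tolist(), ends.tolist()))


def _overlaps_any(onset, offset, intervals):
    return any(onset < e and s < offset for s, e in intervals)


def _decimate(x, fs, target_fs):
    q = max(1, int(fs // target_fs))
    if q == 1:
        return x, fs, 1
    return sps.resample_poly(x, 1, q), fs / q, q


def _check_channel(recording: Recording, channel: int):
    if not 0 <= channel < recording.n_channels:
        raise ValueError(f"channel {channel} out of range")
    if channel in recording.bad_channels:
        raise ValueError(f"channel {channel} is marked bad")


# ---------------------------------------------------------------------------
# IED detector
# ---------------------------------------------------------------------------

def detect_ied(
    recording: Recording, channel: int, config: DetectorConfig | None = None
) -> list[DetectedEvent]:
    """Interictal epileptiform discharge detection on one channel.

    The 25-80 Hz analytic envelope is compared against twice the ongoing
    background amplitude.  "Background amplitude" is estimated robustly as
    the median over 1 s windows of the per-window envelope maximum, so the
    estimate tracks the typical peak excursion of the band-limited
    background rather than its variance, and is insensitive to the events
    themselves.  Accepted events suppress later events starting within the
    refractory period (earliest-first).
    """
    config = config or DetectorConfig()
    _check_channel(recording, channel)
    if recording.duration < 10.0:
        raise ValueError("IED detection needs >= 10 s of data for baseline estimation")
    if recording.analyzable_samples(channel) == 0:
        warnings.warn(f"channel {channel} fully masked; no IED detection performed")
        return []

    x, fs_d, q = _decimate(
        np.asarray(recording.signal[channel], dtype=np.float64),
        recording.fs,
        config.ied_analysis_fs,
    )
    sos = _bandpass_sos(config.ied_band, fs_d, config.filter_order)
    bp = sps.sosfiltfilt(sos, x)
    env = np.abs(sps.hilbert(bp))

    mask_ivs = [
        (s // q, -(-e // q)) for s, e in recording.artifact_mask.get(channel, [])
    ]
    win = int(round(fs_d))
    maxima = []
    for s in range(0, len(env) - win + 1, win):
        if _overlaps_any(s, s + win, mask_ivs):
            continue
        maxima.append(env[s : s + win].max())
    if not maxima:
        warnings.warn("no artifact-free 1 s windows; no IED detection performed")
        return []
    baseline = float(np.median(maxima))
    threshold = config.ied_threshold_factor * baseline

    events: list[DetectedEvent] = []
    last_onset = -np.inf
    refractory = config.ied_refractory_s * recording.fs
    for s_d, e_d in _runs(env > threshold):
        onset, offset = int(s_d * q), int(min(e_d * q, recording.n_samples))
        if _overlaps_any(onset, offset, recording.artifact_mask.get(channel, [])):
            continue
        if onset - last_onset < refractory:
            continue  # excluded: within 1 s of the previous accepted IED
        seg = recording.signal[channel, onset:offset]
        events.append(
            DetectedEvent(
                kind="IED",
                channel=channel,
                onset=onset,
                offset=offset,
                peak_amplitude=float(np.max(np.abs(seg))),
                features={"envelope_peak": float(env[s_d:e_d].max()), "threshold": threshold},
            )
        )
        last_onset = onset
    return events


# ---------------------------------------------------------------------------
# Seizure detector
# ---------------------------------------------------------------------------

def _cwt_denoise(x: np.ndarray, fs: float, n_scales: int, band):
    """Morlet CWT soft-threshold denoising, reconstructed over log-spaced scales."""
    freqs = np.logspace(np.log10(band[0]), np.log10(band[1]), n_scales)
    fc = pywt.central_frequency("morl")
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, "morl", method="fft")
    mad = np.median(np.abs(coeffs), axis=1, keepdims=True)
    thr = 2.0 * mad / 0.6745
    coeffs = np.sign(coeffs) * np.maximum(np.abs(coeffs) - thr, 0.0)
    # inverse transform up to scale: log-spaced Morlet reconstruction sum
    return (coeffs / np.sqrt(scales)[:, None]).sum(axis=0)


def detect_seizure(
    recording: Recording, channel: int, config: DetectorConfig | None = None
) -> list[DetectedEvent]:
    """Electrographic seizure detection on one channel.

    CWT denoising followed by the 1-25 Hz sliding 1 s energy and a dynamic
    threshold: rolling 5 min robust mean + 2 SD.  Energy samples far above
    the channel's global robust level are capped before the rolling statistics
    so a seizure does not raise its own detection threshold.  Events shorter
    than ``seizure_min_duration_s`` (default 10 s) are discarded; each event
    carries a peak-frequency histogram of the discharge.
    """
    config = config or DetectorConfig()
    _check_channel(recording, channel)
    if recording.duration < 60.0:
        raise ValueError("seizure detection needs >= 60 s of context")
    if recording.analyzable_samples(channel) == 0:
        warnings.warn(f"channel {channel} fully masked; no seizure detection performed")
        return []

    x, fs_d, q = _decimate(
        np.asarray(recording.signal[channel], dtype=np.float64),
        recording.fs,
        config.seizure_analysis_fs,
    )
    den = _cwt_denoise(x, fs_d, config.seizure_n_scales, config.seizure_band)
    sos = _bandpass_sos(config.seizure_band, fs_d, config.filter_order)
    den = sps.sosfiltfilt(sos, den)

    e_win = max(1, int(round(config.seizure_energy_window_s * fs_d)))
    energy = sps.convolve(den**2, np.ones(e_win), mode="same")

    med = float(np.median(energy))
    mad_sigma = float(np.median(np.abs(energy - med))) / 0.6745
    capped = np.minimum(energy, med + 5.0 * mad_sigma)
    roll = int(round(config.seizure_rolling_s * fs_d))
    if roll > len(capped):
        warnings.warn(
            "recording shorter than the rolling-threshold context; using global statistics"
        )
        mean = np.full_like(capped, capped.mean())
        sd = np.full_like(capped, capped.std())
    else:
        from scipy.ndimage import uniform_filter1d

        mean = uniform_filter1d(capped, size=roll, mode="nearest")
        sq = uniform_filter1d(capped**2, size=roll, mode="nearest")
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
    threshold = mean + config.seizure_threshold_sd * sd

    events: list[DetectedEvent] = []
    min_len = config.seizure_min_duration_s * fs_d
    for s_d, e_d in _runs(energy > threshold):
        if e_d - s_d < min_len:
            continue
        onset, offset = int(s_d * q), int(min(e_d * q, recording.n_samples))
        if _overlaps_any(onset, offset, recording.artifact_mask.get(channel, [])):
            continue
        seg = den[s_d:e_d]
        peaks, _ = sps.find_peaks(seg)
        if len(peaks) > 1:
            inst_freq = fs_d / np.diff(peaks)
            hist, edges = np.histogram(inst_freq, bins=24, range=config.seizure_band)
        else:
            hist, edges = np.histogram([], bins=24, range=config.seizure_band)
        raw_seg = recording.signal[channel, onset:offset]
        events.append(
            DetectedEvent(
                kind="seizure",
                channel=channel,
                onset=onset,
                offset=offset,
                peak_amplitude=float(np.max(np.abs(raw_seg))),
                features={
                    "peak_freq_hist": hist.tolist(),
                    "peak_freq_bin_edges": edges.tolist(),
                    "dominant_freq_hz": float(edges[np.argmax(hist)]) if hist.sum() else float("nan"),
                },
            )
        )
    return events


# ---------------------------------------------------------------------------
# HFO detector
# ---------------------------------------------------------------------------

def _hfo_band(config: DetectorConfig, fs: float):
    lo, hi = config.hfo_band
    limit = 0.9 * fs / 2
    if hi > limit:
        warnings.warn(f"HFO band clipped to [{lo:g}, {limit:g}] Hz at fs={fs:g}")
        hi = limit
    return lo, hi


def detect_hfo(
    recording: Recording,
    channel: int,
    config: DetectorConfig | None = None,
    exclude_intervals=(),
) -> list[HfoEvent]:
    """High-frequency-oscillation (ripple) detection on one channel.

    ``exclude_intervals`` (sample intervals, e.g. detected seizures) are
    removed from the RMS/rectified-amplitude statistics and no HFO is emitted
    inside them: the reported events are interictal by construction.
    """
    config = config or DetectorConfig()
    _check_channel(recording, channel)
    if recording.fs < 1000:
        raise ValueError("HFO detection requires fs >= 1000 Hz")
    if recording.analyzable_samples(channel) == 0:
        warnings.warn(f"channel {channel} fully masked; no HFO detection performed")
        return []

    lo, hi = _hfo_band(config, recording.fs)
    sos = _bandpass_sos((lo, hi), recording.fs, config.filter_order)
    bp = sps.sosfiltfilt(sos, np.asarray(recording.signal[channel], dtype=np.float64))

    from scipy.ndimage import uniform_filter1d

    win = max(1, int(round(config.hfo_rms_window_ms * 1e-3 * recording.fs)))
    rms = np.sqrt(uniform_filter1d(bp**2, size=win, mode="nearest"))
    rect = np.abs(bp)

    analyzable = recording.analyzable_mask(channel)
    for s, e in exclude_intervals:
        analyzable[max(0, int(s)) : max(0, int(e))] = False
    if not analyzable.any():
        warnings.warn("no analyzable samples after exclusions; no HFO detection performed")
        return []
    rms_mu, rms_sd = float(rms[analyzable].mean()), float(rms[analyzable].std())
    rect_mu, rect_sd = float(rect[analyzable].mean()), float(rect[analyzable].std())
    rms_thr = rms_mu + config.hfo_rms_sd * rms_sd
    rect_thr = rect_mu + config.hfo_peak_sd * rect_sd

    above = rms > rms_thr
    cands = _runs(above)
    # merge candidates separated by < merge gap
    gap = config.hfo_merge_gap_ms * 1e-3 * recording.fs
    merged: list[list[int]] = []
    for s, e in cands:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_run = config.hfo_min_duration_ms * 1e-3 * recording.fs
    fs = recording.fs
    events: list[HfoEvent] = []
    for s, e in merged:
        if e - s < min_run:
            continue
        # require >= one contiguous supra-threshold RMS run of the minimum duration
        runs = _runs(above[s:e])
        if not runs or max(re - rs for rs, re in runs) < min_run:
            continue
        if not analyzable[s:e].all():
            continue
        # the oscillation extends beyond the supra-RMS run: count rectified
        # peaks over the event context, not just the run itself
        pad = int(round(config.hfo_peak_context_ms * 1e-3 * fs))
        cs, ce = max(0, s - pad), min(len(rect), e + pad)
        peaks, _ = sps.find_peaks(rect[cs:ce], height=rect_thr)
        if len(peaks) < config.hfo_min_peaks:
            continue
        pf = _segment_peak_frequency(bp[s:e], fs, (lo, hi))
        events.append(
            HfoEvent(
                kind="HFO",
                channel=channel,
                onset=int(s),
                offset=int(e),
                peak_amplitude=float(np.max(np.abs(recording.signal[channel, s:e]))),
                features={"rms_threshold": rms_thr, "rect_threshold": rect_thr},
                peak_frequency=pf,
                n_rectified_peaks=int(len(peaks)),
                rms_trace=rms[s:e].copy(),
            )
        )
    return events


def _segment_peak_frequency(segment: np.ndarray, fs: float, band) -> float:
    """Frequency of maximum power of a band-passed segment (zero-padded FFT, <= 2 Hz bins)."""
    from scipy.fft import next_fast_len

    nfft = int(next_fast_len(max(len(segment), int(fs / 2.0))))
    spec = np.abs(np.fft.rfft(segment, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        return float("nan")
    return float(freqs[sel][np.argmax(spec[sel])])


def hfo_peak_frequency(event: DetectedEvent, recording: Recording, config: DetectorConfig | None = None) -> float:
    """Peak frequency (Hz) of an event's 100-500 Hz band-passed segment."""
    config = config or DetectorConfig()
    lo, hi = _hfo_band(config, recording.fs)
    sos = _bandpass_sos((lo, hi), recording.fs, config.filter_order)
    pad = int(0.05 * recording.fs)
    s = max(0, event.onset - pad)
    e = min(recording.n_samples, event.offset + pad)
    bp = sps.sosfiltfilt(sos, np.asarray(recording.signal[event.channel, s:e], dtype=np.float64))
    return _segment_peak_frequency(bp[event.onset - s : event.offset - s], recording.fs, (lo, hi))


# ---------------------------------------------------------------------------
# rates and export
# ---------------------------------------------------------------------------

def event_rate(events, analyzable_duration_min: float) -> float:
    """Events per minute of analyzable (unmasked) recording time."""
    if analyzable_duration_min <= 0:
        raise ZeroDivisionError("undefined rate: analyzable duration is zero")
    return len(events) / analyzable_duration_min


def events_to_annotations(events, fs: float):
    """Events as ``(onset_s, duration_s, label)`` triples for EDF+ export.

    Written next to the signal (``hfokit.write_edf(..., extra_annotations=...)``)
    the detections can be reviewed in any standard EDF viewer.
    """
    return [
        (ev.onset / fs, (ev.offset - ev.onset) / fs, f"{ev.kind} ch={ev.channel}")
        for ev in sorted(events, key=lambda e: (e.onset, e.channel))
    ]


def events_to_frame(events, fs: float, animal: str = "", session: str = "") -> "pd.DataFrame":
    """Tidy CSV-ready table of events (onset/offset in seconds)."""
    import pandas as pd

    rows = []
    for ev in events:
        rows.append(
            {
                "animal": animal,
                "session": session,
                "channel": ev.channel,
                "kind": ev.kind,
                "onset_s": ev.onset / fs,
                "offset_s": ev.offset / fs,
                "peak_freq_hz": getattr(ev, "peak_frequency", float("nan")),
                "peak_amp_uv": ev.peak_amplitude,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal",
            "session",
            "channel",
            "kind",
            "onset_s",
            "offset_s",
            "peak_freq_hz",
            "peak_amp_uv",
        ],
    )
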