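"""Ground-truthed synthetic SEEG generator.

Emulates the signal structure of bilateral 16-channel swine hippocampal /
sensorimotor depth recordings so the whole pipeline is testable without
animal data:

* 1/f^alpha Gaussian background (spectral shaping; default alpha = 1.5,
  ~50 uV RMS) with hemisphere-correlated components and 50 Hz line noise;
* baseline state: narrow-band delta (4 Hz) and alpha (10 Hz) spectral
  peaks, the NREM-like profile seen under mild anesthesia;
* post-injection ("postka") state: suppressed delta, no alpha peak, and
  bursty 18-20 Hz activity on hippocampal channels;
* injected events with exact ground truth: biphasic interictal spikes
  (20-50 ms, 5-8x background RMS), Gaussian-windowed ripple tones
  (frequency ~ N(147.3, 20.45^2) Hz truncated to [100, 200], >= 8 cycles,
  SNR defined against the 100-500 Hz background floor), rhythmic seizures
  of 12-45 s, and masked motion artifacts;
* multi-animal study datasets with per-week rate trajectories for an E+
  group (rates elevated after the insult) and an E- group (baseline-like),
  at desk scale (10 min sessions standing in for 2 h; rates in events/min
  are duration-invariant, and the scaling factor is recorded).

Event amplitudes are phenomenological placeholders (no published amplitude
scale exists for porcine SEEG events); they are chosen to sit well above
the detectors' thresholds at the configured SNR.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import Recording, apply_montage, default_montage, write_edf

__all__ = [
    "OscillationSpec",
    "GeneratorConfig",
    "TruthEvent",
    "GroundTruth",
    "AnimalSpec",
    "StudyManifest",
    "StudyData",
    "Score",
    "generate_background",
    "inject_events",
    "generate_session",
    "default_study_manifest",
    "generate_study",
    "score_detections",
]


@dataclass
class OscillationSpec:
    """A narrow-band spectral component: Gaussian bump at ``center_hz``.

    ``channels=None`` targets every channel.  ``bursty`` components are
    gated by an on/off envelope (on 0.5-2 s, off 1-4 s), producing the
    spindle-like bursts seen after the insult.
    """

    center_hz: float
    bandwidth_hz: float
    rms_uv: float
    channels: tuple[int, ...] | None = None
    bursty: bool = False


def _default_oscillations(state: str):
    if state == "baseline":
        return [
            OscillationSpec(4.0, 1.0, 35.0),
            OscillationSpec(10.0, 1.0, 25.0),
        ]
    hippocampal = tuple([0, 1, 2, 8, 9, 10])
    return [
        OscillationSpec(4.0, 1.0, 15.0),  # suppressed delta
        OscillationSpec(19.0, 1.5, 22.0, channels=hippocampal, bursty=True),
    ]


@dataclass
class GeneratorConfig:
    """All generator knobs; defaults reproduce the study's signal conditions."""

    fs: float = 4000.0
    n_channels: int = 16
    duration_s: float = 600.0
    state: str = "baseline"  # "baseline" | "postka"
    seed: int = 0

    background_exponent: float = 1.5
    background_rms_uv: float = 50.0
    hemisphere_mixing: float = 0.3
    oscillations: list[OscillationSpec] | None = None
    line_noise_hz: float = 50.0
    line_noise_rms_uv: float = 4.0

    ied_per_min: float = 0.0
    ied_width_range_s: tuple[float, float] = (0.02, 0.05)
    ied_amp_factor_range: tuple[float, float] = (5.0, 8.0)
    ied_min_separation_s: float = 2.0

    hfo_per_min: dict | float = field(default_factory=dict)  # region -> rate
    hfo_freq_mean: float = 147.3
    hfo_freq_sd: float = 20.45
    hfo_freq_range: tuple[float, float] = (100.0, 200.0)
    hfo_cycles: float = 8.0
    hfo_snr: float = 3.0

    n_seizures: int = 0
    seizure_times_s: tuple[float, ...] | None = None
    seizure_duration_range_s: tuple[float, float] = (12.0, 45.0)
    seizure_amp_factor: float = 6.0
    seizure_duration_s: float | None = None  # fix the duration instead of drawing

    artifact_per_min: float = 0.0
    artifact_duration_range_s: tuple[float, float] = (0.5, 2.0)
    artifact_amp_uv: float = 800.0

    def __post_init__(self):
        if self.state not in ("baseline", "postka"):
            raise ValueError("state must be 'baseline' or 'postka'")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("fs and duration must be positive")
        for osc in self.oscillations or []:
            if osc.center_hz >= self.fs / 2:
                raise ValueError(f"oscillation at {osc.center_hz} Hz >= Nyquist")
        rates = [self.ied_per_min, self.artifact_per_min]
        rates += list(self.hfo_rates().values())
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")

    def hfo_rates(self) -> dict:
        if isinstance(self.hfo_per_min, dict):
            return dict(self.hfo_per_min)
        return {"hippocampus": float(self.hfo_per_min)}

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        if d["oscillations"] is not None:
            for osc in d["oscillations"]:
                if osc.get("channels") is not None:
                    osc["channels"] = list(osc["channels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("oscillations") is not None:
            d["oscillations"] = [
                OscillationSpec(
                    center_hz=o["center_hz"],
                    bandwidth_hz=o["bandwidth_hz"],
                    rms_uv=o["rms_uv"],
                    channels=tuple(o["channels"]) if o.get("channels") is not None else None,
                    bursty=o.get("bursty", False),
                )
                for o in d["oscillations"]
            ]
        for key, val in list(d.items()):
            if isinstance(val, list) and key != "oscillations":
                d[key] = tuple(val)
        return cls(**d)

    def resolved_oscillations(self):
        return self.oscillations if self.oscillations is not None else _default_oscillations(self.state)


@dataclass
class TruthEvent:
    kind: str
    channel: int
    onset: int
    offset: int
    freq_hz: float = float("nan")
    amplitude_uv: float = float("nan")


@dataclass
class GroundTruth:
    """Every injected event plus the session conditions that produced them."""

    events: list[TruthEvent] = field(default_factory=list)
    state: str = "baseline"
    rates: dict = field(default_factory=dict)

    def sort(self):
        self.events.sort(key=lambda ev: (ev.onset, ev.channel))

    def of_kind(self, kind: str, channel: int | None = None):
        return [
            ev
            for ev in self.events
            if ev.kind == kind and (channel is None or ev.channel == channel)
        ]

    def to_frame(self, fs: float) -> pd.DataFrame:
        rows = [
            {
                "kind": ev.kind,
                "channel": ev.channel,
                "onset_s": ev.onset / fs,
                "offset_s": ev.offset / fs,
                "freq_hz": ev.freq_hz,
                "amplitude_uv": ev.amplitude_uv,
            }
            for ev in self.events
        ]
        return pd.DataFrame(
            rows, columns=["kind", "channel", "onset_s", "offset_s", "freq_hz", "amplitude_uv"]
        )


# ---------------------------------------------------------------------------
# spectral-shaping synthesis
# ---------------------------------------------------------------------------

def _background_shape(freqs: np.ndarray, alpha: float) -> np.ndarray:
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 0.5) ** (-alpha)
    return shape


def _bump_shape(freqs: np.ndarray, center: float, bandwidth: float) -> np.ndarray:
    sigma = bandwidth / 2.355  # FWHM -> sigma
    return np.exp(-0.5 * ((freqs - center) / sigma) ** 2)


def _normalize_shape(shape: np.ndarray, df: float, rms: float) -> np.ndarray:
    total = shape.sum() * df
    if total <= 0:
        return shape * 0.0
    return shape * (rms**2 / total)


def _synth_from_psd(rng: np.random.Generator, psd: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Time series whose one-sided PSD is ``psd`` (uV^2/Hz), via random phases."""
    from scipy.fft import irfft

    n_freq = len(psd)
    scale = np.sqrt(psd.astype(np.float32, copy=False) * np.float32(fs * n / 4.0))
    X = np.empty(n_freq, dtype=np.complex64)
    X.real = rng.standard_normal(n_freq, dtype=np.float32) * scale
    X.imag = rng.standard_normal(n_freq, dtype=np.float32) * scale
    X[0] = 0.0
    if n % 2 == 0:
        X[-1] = X[-1].real * np.sqrt(2.0)
    return irfft(X, n=n)


def _burst_envelope(rng: np.random.Generator, n_low: int, fs_low: float) -> np.ndarray:
    """On/off gate at a low internal rate (upsampled later); ~100 ms edges."""
    env = np.zeros(n_low)
    pos = 0
    while pos < n_low:
        off = int(rng.uniform(1.0, 4.0) * fs_low)
        on = int(rng.uniform(0.5, 2.0) * fs_low)
        env[pos + off : pos + off + on] = 1.0
        pos += off + on
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(env, size=max(1, int(0.1 * fs_low)), mode="nearest")


def _synth_narrowband_upsampled(
    rng: np.random.Generator,
    osc: "OscillationSpec",
    n: int,
    fs: float,
    bursty: bool,
) -> np.ndarray:
    """Narrow-band (and optionally burst-gated) component.

    Synthesized at a reduced internal rate (the component lives far below
    Nyquist) and linearly upsampled — numerically equivalent for bands a
    few Hz wide, and much cheaper than full-rate synthesis.
    """
    dec = 1
    top = osc.center_hz + 3 * osc.bandwidth_hz
    while fs / (2 * dec) > 8 * top and dec < 16:
        dec *= 2
    n_low = -(-n // dec)
    fs_low = fs / dec
    freqs = np.fft.rfftfreq(n_low, 1.0 / fs_low)
    df = freqs[1] - freqs[0]
    psd = _normalize_shape(_bump_shape(freqs, osc.center_hz, osc.bandwidth_hz), df, osc.rms_uv)
    x = _synth_from_psd(rng, psd, n_low, fs_low)
    if bursty:
        x = x * _burst_envelope(rng, n_low, fs_low)
    if dec == 1:
        return x[:n].astype(np.float32)
    t_hi = np.arange(n, dtype=np.float64) / fs
    t_lo = np.arange(n_low, dtype=np.float64) / fs_low
    return np.interp(t_hi, t_lo, x).astype(np.float32)


def band_rms_background(config: GeneratorConfig, band: tuple[float, float]) -> float:
    """Analytic RMS of the configured 1/f background inside a band.

    This is the noise floor against which the ripple SNR is defined.
    """
    n = int(round(config.duration_s * config.fs))
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    df = freqs[1] - freqs[0]
    shape = _normalize_shape(
        _background_shape(freqs, config.background_exponent), df, config.background_rms_uv
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sqrt(shape[sel].sum() * df))


def generate_background(config: GeneratorConfig, rng: np.random.Generator | None = None) -> Recording:
    """Multichannel background: shaped 1/f + oscillations + line noise.

    Channels within a hemisphere share a common component weighted by
    ``hemisphere_mixing``.  For 16-channel recordings the default study
    montage is attached (hippocampal/sensorimotor labels, outside-brain
    contacts marked bad).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = int(round(config.duration_s * config.fs))
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    df = freqs[1] - freqs[0]

    bg_psd = _normalize_shape(
        _background_shape(freqs, config.background_exponent), df, config.background_rms_uv
    ).astype(np.float32)
    steady_psds = []
    bursty = []
    for osc in config.resolved_oscillations():
        if osc.bursty:
            bursty.append((osc, None))
            continue
        psd = _normalize_shape(
            _bump_shape(freqs, osc.center_hz, osc.bandwidth_hz), df, osc.rms_uv
        ).astype(np.float32)
        steady_psds.append((osc, psd))

    mix = config.hemisphere_mixing
    half = config.n_channels // 2
    shared = {
        "left": _synth_from_psd(rng, bg_psd, n, config.fs),
        "right": _synth_from_psd(rng, bg_psd, n, config.fs),
    }
    signal = np.empty((config.n_channels, n), dtype=np.float32)
    for ch in range(config.n_channels):
        hemi = "left" if ch < half else "right"
        # channel-private part: background (shared-component share removed) +
        # its steady oscillations, synthesized in a single pass
        psd = np.float32(1.0 - mix**2) * bg_psd
        for osc, opsd in steady_psds:
            if osc.channels is None or ch in osc.channels:
                psd = psd + opsd
        signal[ch] = _synth_from_psd(rng, psd, n, config.fs) + mix * shared[hemi]
    for osc, _opsd in bursty:
        channels = range(config.n_channels) if osc.channels is None else osc.channels
        for ch in channels:
            if ch >= config.n_channels:
                continue
            signal[ch] += _synth_narrowband_upsampled(rng, osc, n, config.fs, bursty=True)
    if config.line_noise_rms_uv > 0:
        t = np.arange(n, dtype=np.float64) / config.fs
        phase = rng.uniform(0, 2 * np.pi)
        line = (
            np.sqrt(2.0) * config.line_noise_rms_uv
            * np.sin(2 * np.pi * config.line_noise_hz * t + phase)
        ).astype(np.float32)
        signal += line

    rec = Recording(
        signal=signal,
        fs=config.fs,
        start_time=_dt.datetime(2023, 1, 1, 8, 0, 0),
    )
    if config.n_channels == 16:
        # fresh object: attach the study montage without the defensive copy
        for c in default_montage().contacts:
            rec.channel_regions[c.channel] = c.region
            rec.channel_hemispheres[c.channel] = c.hemisphere
            if c.region == "outside-brain":
                rec.bad_channels.add(c.channel)
    return rec


# ---------------------------------------------------------------------------
# event injection
# ---------------------------------------------------------------------------

def _draw_onsets(rng, n_events, n_samples, fs, min_len, occupied, min_sep_s):
    """Rejection-sample event start samples avoiding occupied intervals.

    Raises when a single event cannot fit; if the recording is too crowded
    for the full requested count, places what fits and warns.
    """
    margin = int(0.5 * fs)
    if min_len + 2 * margin > n_samples:
        raise ValueError("requested event longer than the recording")
    onsets = []
    sep = int(min_sep_s * fs)
    attempts = 0
    while len(onsets) < n_events and attempts < 200 * max(1, n_events):
        attempts += 1
        s = int(rng.integers(margin, max(margin + 1, n_samples - min_len - margin)))
        e = s + min_len
        if any(s - sep < oe and os_ < e + sep for os_, oe in occupied):
            continue
        occupied.append((s, e))
        onsets.append(s)
    if len(onsets) < n_events:
        warnings.warn(
            f"placed {len(onsets)}/{n_events} events; recording too crowded for the requested rate"
        )
    return onsets


def _ied_waveform(fs, width_s, amp_uv):
    sigma = width_s / 6.0
    t = np.arange(-width_s / 2, width_s / 2, 1.0 / fs)
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    return amp_uv * w / np.abs(w).max()


def _hfo_waveform(fs, freq, cycles, amp_uv, rng):
    dur = cycles / freq
    sigma = dur / 6.0
    t = np.arange(-dur / 2, dur / 2, 1.0 / fs)
    phase = rng.uniform(0, 2 * np.pi)
    return amp_uv * np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * freq * t + phase)


def _seizure_waveform(fs, duration_s, amp_uv, rng):
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    f0, f1 = 7.0, 3.0  # rhythmic discharge slows over the event
    inst = f0 + (f1 - f0) * t / duration_s
    phase = 2 * np.pi * np.cumsum(inst) / fs
    wave = np.cos(phase) + 0.5 * np.cos(2 * phase + rng.uniform(0, 2 * np.pi))
    ramp = min(1.0, duration_s / 10.0)
    env = np.ones(n)
    k = int(ramp * fs)
    env[:k] = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
    env[-k:] = env[:k][::-1]
    env *= 1.0 + 0.25 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    return amp_uv * env * wave / np.abs(wave).max()


def _truncnorm(rng, mean, sd, lo, hi):
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v


def inject_events(
    recording: Recording,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    copy: bool = True,
) -> tuple[Recording, GroundTruth]:
    """Inject artifacts, IEDs, ripples, and seizures; log exact ground truth.

    Event counts are Poisson at the configured per-minute rates; HFO rates
    are per anatomical region (hippocampal channels by default carry the
    high rate).  Injected events never overlap scheduled artifact intervals
    or each other on the same channel.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rec = recording.copy() if copy else recording
    n_samples, fs = rec.n_samples, rec.fs
    minutes = config.duration_s / 60.0
    truth = GroundTruth(state=config.state, rates={"ied_per_min": config.ied_per_min, **config.hfo_rates()})

    # --- motion artifacts: common to all channels, masked everywhere
    occupied_global: list[tuple[int, int]] = []
    if config.artifact_per_min > 0:
        n_art = rng.poisson(config.artifact_per_min * minutes)
        for _ in range(n_art):
            dur = rng.uniform(*config.artifact_duration_range_s)
            length = int(dur * fs)
            try:
                (s,) = _draw_onsets(rng, 1, n_samples, fs, length, occupied_global, 1.0)
            except ValueError:
                break
            lurch = np.cumsum(rng.standard_normal(length))
            lurch -= np.linspace(lurch[0], lurch[-1], length)
            denom = np.abs(lurch).max() or 1.0
            wave = config.artifact_amp_uv * lurch / denom
            for ch in range(rec.n_channels):
                rec.signal[ch, s : s + length] += wave
                rec.artifact_mask.setdefault(ch, []).append((s, s + length))
            truth.events.append(TruthEvent("artifact", -1, s, s + length))
    from .edf import merge_intervals

    rec.artifact_mask = {ch: merge_intervals(v) for ch, v in rec.artifact_mask.items()}

    regions = rec.channel_regions or {ch: "hippocampus" for ch in range(rec.n_channels)}
    good = [ch for ch in range(rec.n_channels) if ch not in rec.bad_channels]
    occupied_by_ch = {ch: list(occupied_global) for ch in range(rec.n_channels)}

    # --- seizures: hippocampal channels of the left hemisphere, common onset
    sz_channels = [ch for ch in good if regions.get(ch) == "hippocampus" and ch < rec.n_channels // 2]
    if not sz_channels:
        sz_channels = good[:1]
    seizure_onsets = []
    if config.seizure_times_s is not None:
        seizure_onsets = [int(t * fs) for t in config.seizure_times_s]
    elif config.n_seizures > 0:
        max_len = int(config.seizure_duration_range_s[1] * fs)
        occ = list(occupied_global)
        sep = max(5.0, min(30.0, config.duration_s / 10.0))
        seizure_onsets = _draw_onsets(rng, config.n_seizures, n_samples, fs, max_len, occ, sep)
    for s in seizure_onsets:
        dur = (
            config.seizure_duration_s
            if config.seizure_duration_s is not None
            else rng.uniform(*config.seizure_duration_range_s)
        )
        amp = config.seizure_amp_factor * config.background_rms_uv
        wave = _seizure_waveform(fs, dur, amp, rng)
        e = min(n_samples, s + len(wave))
        for ch in sz_channels:
            rec.signal[ch, s:e] += wave[: e - s] * rng.uniform(0.8, 1.0)
            occupied_by_ch[ch].append((s, e))
            truth.events.append(TruthEvent("seizure", ch, s, e, freq_hz=5.0, amplitude_uv=amp))

    # --- interictal spikes
    if config.ied_per_min > 0:
        for ch in good:
            n_ev = rng.poisson(config.ied_per_min * minutes)
            max_len = int(config.ied_width_range_s[1] * fs) + 1
            onsets = _draw_onsets(
                rng, n_ev, n_samples, fs, max_len, occupied_by_ch[ch], config.ied_min_separation_s
            )
            for s in onsets:
                width = rng.uniform(*config.ied_width_range_s)
                amp = rng.uniform(*config.ied_amp_factor_range) * config.background_rms_uv
                wave = _ied_waveform(fs, width, amp)
                e = min(n_samples, s + len(wave))
                rec.signal[ch, s:e] += wave[: e - s]
                truth.events.append(TruthEvent("IED", ch, s, e, amplitude_uv=amp))

    # --- ripples (HFOs), rate per region, SNR against the 100-500 Hz floor
    rates = config.hfo_rates()
    if any(r > 0 for r in rates.values()):
        floor = band_rms_background(config, (100.0, min(500.0, 0.45 * fs)))
        for ch in good:
            rate = rates.get(regions.get(ch, "hippocampus"), 0.0)
            if rate <= 0:
                continue
            n_ev = rng.poisson(rate * minutes)
            max_len = int(config.hfo_cycles / config.hfo_freq_range[0] * fs) + 1
            onsets = _draw_onsets(rng, n_ev, n_samples, fs, max_len, occupied_by_ch[ch], 0.2)
            for s in onsets:
                freq = _truncnorm(
                    rng, config.hfo_freq_mean, config.hfo_freq_sd, *config.hfo_freq_range
                )
                # event RMS over its duration = snr * band floor (Gaussian envelope)
                amp = config.hfo_snr * floor / 0.384
                wave = _hfo_waveform(fs, freq, config.hfo_cycles, amp, rng)
                e = min(n_samples, s + len(wave))
                rec.signal[ch, s:e] += wave[: e - s]
                truth.events.append(
                    TruthEvent("HFO", ch, s, e, freq_hz=freq, amplitude_uv=amp)
                )

    truth.sort()
    return rec, truth


def generate_session(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Background + events, fully determined by ``config.seed``."""
    ss = np.random.SeedSequence([config.seed])
    bg_rng, ev_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    rec = generate_background(config, bg_rng)
    return inject_events(rec, config, ev_rng, copy=False)


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

@dataclass
class AnimalSpec:
    """Per-animal weekly rate trajectory (week 0 = baseline)."""

    animal_id: str
    group: str  # "E+" | "E-"
    hfo_rate_by_week: dict[int, float]
    ied_rate_by_week: dict[int, float] = field(default_factory=dict)
    seizures_by_week: dict[int, int] = field(default_factory=dict)
    sensorimotor_hfo_per_min: float = 0.4


@dataclass
class StudyManifest:
    animals: list[AnimalSpec]
    sessions_per_week: int = 1
    session_duration_s: float = 600.0
    fs: float = 4000.0
    n_channels: int = 16
    artifact_per_min: float = 0.1
    full_scale_duration_s: float = 7200.0

    def __post_init__(self):
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate animal ids in manifest")


def default_study_manifest(
    n_eplus: int = 8, n_eminus: int = 4, seed: int = 0, **kwargs
) -> StudyManifest:
    """The study's group design: 8 E+ and 4 E- animals, baseline + 4 weeks.

    E+ hippocampal HFO rates rise after the insult (weekly means around
    8/14/10/12 per min, the scale reported for epileptogenic hippocampus);
    E- animals stay at their baseline rate or drift slightly down.  Four E+
    animals carry 1-2 electrographic seizures in weeks 2-4.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    animals = []
    eplus_weekly_means = {1: 8.0, 2: 14.0, 3: 10.0, 4: 12.0}
    for i in range(n_eplus):
        base = float(rng.uniform(1.0, 2.5))
        # stable per-animal rate level: the subject effect the ICC measures
        animal_effect = float(rng.normal(0.0, 2.5))
        rates = {0: base}
        for w, mu in eplus_weekly_means.items():
            rates[w] = float(max(base + 4.0, rng.normal(mu + animal_effect, 1.5)))
        ied = {0: 0.0, **{w: float(rng.uniform(1.0, 3.0)) for w in range(1, 5)}}
        seiz = {}
        if i < 4:  # half the E+ animals show electrographic seizures
            for w in (2, 3, 4):
                seiz[w] = int(rng.integers(0, 2))
            if sum(seiz.values()) == 0:
                seiz[4] = 1
        animals.append(
            AnimalSpec(f"E{i + 101}", "E+", rates, ied_rate_by_week=ied, seizures_by_week=seiz)
        )
    for i in range(n_eminus):
        base = float(rng.uniform(0.8, 3.2))
        rates = {0: base}
        for w in range(1, 5):
            rates[w] = float(base * rng.uniform(0.7, 1.0))  # flat or slightly decreasing
        animals.append(AnimalSpec(f"N{i + 201}", "E-", rates))
    return StudyManifest(animals=animals, **kwargs)


@dataclass
class StudyData:
    root: Path
    manifest_csv: Path
    truth_csv: Path
    sessions: pd.DataFrame


def generate_study(
    manifest: StudyManifest, seed: int, outdir, full_scale: bool = False
) -> StudyData:
    """Write one EDF per animal/week/session plus truth and manifest CSVs.

    Week 0 is the pre-insult baseline.  E- animals keep baseline-like
    spectra and rates in every week (they develop no epileptiform activity);
    E+ animals switch to the post-insult state from week 1.  Deterministic:
    the same manifest and seed reproduce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    duration = manifest.full_scale_duration_s if full_scale else manifest.session_duration_s
    scale_factor = manifest.full_scale_duration_s / duration
    rows = []
    truth_frames = []
    for ai, spec in enumerate(manifest.animals):
        for week in sorted(spec.hfo_rate_by_week):
            for sess in range(manifest.sessions_per_week):
                state = "postka" if (week > 0 and spec.group == "E+") else "baseline"
                child_seed = int(
                    np.random.SeedSequence([seed, ai, week, sess]).generate_state(1)[0] // 2
                )
                config = GeneratorConfig(
                    fs=manifest.fs,
                    n_channels=manifest.n_channels,
                    duration_s=duration,
                    state=state,
                    seed=child_seed,
                    ied_per_min=spec.ied_rate_by_week.get(week, 0.0),
                    hfo_per_min={
                        "hippocampus": spec.hfo_rate_by_week[week],
                        "sensorimotor": spec.sensorimotor_hfo_per_min,
                    },
                    n_seizures=spec.seizures_by_week.get(week, 0),
                    artifact_per_min=manifest.artifact_per_min,
                )
                rec, truth = generate_session(config)
                rec.start_time = _dt.datetime(2023, 1, 2, 8, 0, 0) + _dt.timedelta(
                    days=7 * week + sess, minutes=5 * ai
                )
                session_id = f"{spec.animal_id}_w{week}_s{sess}"
                path = outdir / f"{session_id}.edf"
                write_edf(rec, path)
                tf = truth.to_frame(rec.fs)
                tf.insert(0, "session", session_id)
                tf.insert(1, "animal", spec.animal_id)
                tf.insert(2, "week", week)
                truth_frames.append(tf)
                rows.append(
                    {
                        "session": session_id,
                        "animal": spec.animal_id,
                        "group": spec.group,
                        "week": week,
                        "path": path.name,
                        "state": state,
                        "duration_min": duration / 60.0,
                        "scale_factor": scale_factor,
                    }
                )
    sessions = pd.DataFrame(rows)
    manifest_csv = outdir / "manifest.csv"
    truth_csv = outdir / "truth.csv"
    sessions.to_csv(manifest_csv, index=False, float_format="%.6g")
    pd.concat(truth_frames, ignore_index=True).to_csv(
        truth_csv, index=False, float_format="%.6f"
    )
    return StudyData(root=outdir, manifest_csv=manifest_csv, truth_csv=truth_csv, sessions=sessions)


# ---------------------------------------------------------------------------
# detection scoring
# ---------------------------------------------------------------------------

@dataclass
class Score:
    n_truth: int
    n_detected: int
    tp: int
    sensitivity: float
    precision: float
    fp_rate_per_min: float


def score_detections(detected_onsets_s, truth_onsets_s, tolerance_s: float, duration_min: float) -> Score:
    """Greedy one-to-one onset matching within a tolerance.

    Candidate (detected, truth) pairs within tolerance are accepted in
    order of increasing onset distance, each onset used at most once.
    With no detections the sensitivity is 0 and, vacuously, the precision
    is reported as 1 (there are no false positives).
    """
    det = np.asarray(sorted(detected_onsets_s), dtype=float)
    tru = np.asarray(sorted(truth_onsets_s), dtype=float)
    pairs = [
        (abs(d - t), i, j)
        for i, d in enumerate(det)
        for j, t in enumerate(tru)
        if abs(d - t) <= tolerance_s
    ]
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    fp = len(det) - tp
    sensitivity = tp / len(tru) if len(tru) else 1.0
    precision = tp / len(det) if len(det) else 1.0
    fp_rate = fp / duration_min if duration_min > 0 else 0.0
    return Score(
        n_truth=len(tru),
        n_detected=len(det),
        tp=tp,
        sensitivity=sensitivity,
        precision=precision,
        fp_rate_per_min=fp_rate,
    )
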