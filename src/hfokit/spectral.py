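"""Multi-taper time-frequency analysis and the 1/f log-log quality screen.

The spectrogram column for the i-th window is computed literally as

    P_i = (1/m) * sum_j  z .* conj(z),      z = 2 * fft(d_i * T_j) / n

where ``d_i`` is the raw window, ``T_j`` the j-th unit-norm orthogonal DPSS
taper, ``m`` the taper count and ``n`` the window length in samples.  Only
the one-sided frequency axis [0, fs/2] is kept; the factor 2 is applied to
every bin including DC and Nyquist (the stated convention is reproduced
as written rather than Parseval-exact).

Recording quality is screened by an ordinary least-squares fit of
log10(power) against log10(frequency) over 0.5-100 Hz: broadband intracranial
LFP shows a near-linear decrease (a 1/f spectrum), so a negative slope with
high R-squared marks a good recording.  Bins near the 50 Hz mains notch are
excluded from the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import windows as _windows

from .edf import Recording

__all__ = [
    "MultitaperConfig",
    "Spectrogram",
    "Psd",
    "ChannelQc",
    "make_tapers",
    "multitaper_spectrogram",
    "compute_psd",
    "qc_one_over_f",
    "qc_recording",
]


@dataclass
class MultitaperConfig:
    """Multitaper parameters.

    window_length / step are in seconds (defaults 30 s windows, 1 s step for
    a heavily overlapped sleep-style spectrogram).  ``time_bandwidth`` is the
    half-bandwidth product NW; ``n_tapers`` defaults to the usual 2NW-1 rule.
    ``taper_family`` may be "dpss" or "rect" (a single 1/sqrt(n) flat taper,
    which reduces the estimate to a plain periodogram).
    """

    window_length: float = 30.0
    step: float = 1.0
    time_bandwidth: float = 4.0
    n_tapers: int = 7
    taper_family: str = "dpss"

    def __post_init__(self):
        if not 0 < self.step <= self.window_length:
            raise ValueError("require 0 < step <= window_length")
        if self.n_tapers < 1:
            raise ValueError("need at least one taper")
        if self.taper_family not in ("dpss", "rect"):
            raise ValueError(f"unknown taper family {self.taper_family!r}")

    def n_per_window(self, fs: float) -> int:
        return int(round(self.window_length * fs))


@dataclass
class Spectrogram:
    """Time-frequency power matrix ``P`` (frequency x time-bin)."""

    P: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # window-center seconds
    config: MultitaperConfig = field(default_factory=MultitaperConfig)

    @property
    def n_columns(self) -> int:
        return self.P.shape[1]


class Psd(NamedTuple):
    freqs: np.ndarray
    power: np.ndarray


@dataclass
class ChannelQc:
    """Per-channel 1/f screen result."""

    channel: int
    slope: float
    intercept: float
    r2: float
    n_bins: int
    passed: bool


from functools import lru_cache


@lru_cache(maxsize=8)
def _dpss_cached(n: int, nw: float, m: int) -> np.ndarray:
    tapers = _windows.dpss(n, nw, Kmax=m, sym=True, norm=2)
    return np.atleast_2d(tapers)


def make_tapers(config: MultitaperConfig, fs: float) -> np.ndarray:
    """Taper matrix, shape (m, n): unit-norm, pairwise orthogonal rows.

    DPSS (Slepian) tapers by default.  Requesting more than 2NW-1 tapers
    emits a leakage warning; m > n is an error.
    """
    n = config.n_per_window(fs)
    m = config.n_tapers
    if m > n:
        raise ValueError(f"cannot build {m} tapers of length {n}")
    if config.taper_family == "rect":
        return np.full((m, n), 1.0 / np.sqrt(n))
    if m > 2 * config.time_bandwidth - 1:
        warnings.warn(
            f"{m} tapers exceeds 2NW-1 = {2 * config.time_bandwidth - 1:g}; "
            "higher-order tapers leak"
        )
    return _dpss_cached(n, float(config.time_bandwidth), m)


def _window_starts(n_samples: int, fs: float, config: MultitaperConfig) -> np.ndarray:
    n = config.n_per_window(fs)
    step = int(round(config.step * fs))
    if n_samples < n:
        raise ValueError("duration shorter than the analysis window")
    return np.arange(0, n_samples - n + 1, step)


def _mt_columns(x: np.ndarray, fs: float, starts, tapers: np.ndarray):
    from scipy.fft import rfft

    n = tapers.shape[1]
    n_freq = n // 2 + 1
    P = np.empty((n_freq, len(starts)))
    for col, s in enumerate(starts):
        d = x[s : s + n]
        z = 2.0 * rfft(tapers * d, axis=1) / n
        P[:, col] = np.mean(z.real**2 + z.imag**2, axis=0)
    return P


def multitaper_spectrogram(
    recording: Recording, channel: int, config: MultitaperConfig | None = None
) -> Spectrogram:
    """Multitaper spectrogram of one channel.

    Windows overlapping an artifact-masked interval are dropped entirely.
    Column count for clean data is ``floor((duration - window)/step) + 1``.
    """
    config = config or MultitaperConfig()
    if channel in recording.bad_channels:
        raise ValueError(f"channel {channel} is marked bad")
    n = config.n_per_window(recording.fs)
    starts = _window_starts(recording.n_samples, recording.fs, config)
    mask_ivs = recording.artifact_mask.get(channel, [])
    if mask_ivs:
        keep = [
            s
            for s in starts
            if not any(s < e and ms < s + n for ms, e in mask_ivs)
        ]
        starts = np.asarray(keep, dtype=int)
    if len(starts) == 0:
        raise ValueError("no analyzable windows (masking removed everything)")
    tapers = make_tapers(config, recording.fs)
    P = _mt_columns(np.asarray(recording.signal[channel], dtype=np.float64), recording.fs, starts, tapers)
    freqs = np.fft.rfftfreq(n, 1.0 / recording.fs)
    times = (starts + n / 2) / recording.fs
    return Spectrogram(P=P, freqs=freqs, times=np.asarray(times, dtype=float), config=config)


def compute_psd(
    recording: Recording,
    channel: int,
    band: tuple[float, float] | None = None,
    config: MultitaperConfig | None = None,
) -> Psd:
    """Welch-style PSD: multitaper estimates averaged over windows.

    By default windows do not overlap (step = window length); masked windows
    are excluded.  ``band`` optionally crops the frequency axis.
    """
    if config is None:
        config = MultitaperConfig(step=MultitaperConfig.window_length)
        config.step = config.window_length
    spec = multitaper_spectrogram(recording, channel, config)
    power = spec.P.mean(axis=1)
    freqs = spec.freqs
    if band is not None:
        sel = (freqs >= band[0]) & (freqs <= band[1])
        freqs, power = freqs[sel], power[sel]
    return Psd(freqs=freqs, power=power)


def qc_one_over_f(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_band: tuple[float, float] = (0.5, 100.0),
    notch: float = 50.0,
    notch_halfwidth: float = 2.0,
    r2_threshold: float = 0.8,
    channel: int = 0,
) -> ChannelQc:
    """OLS fit of log10(power) on log10(frequency); pass iff R^2 >= threshold and slope < 0.

    Bins within ``notch_halfwidth`` of the mains notch and non-positive power
    bins (excluded with a warning) do not enter the fit.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    sel = (freqs >= fit_band[0]) & (freqs <= fit_band[1])
    sel &= np.abs(freqs - notch) > notch_halfwidth
    if np.any(power[sel] <= 0):
        warnings.warn("non-positive power bins excluded from 1/f fit")
        sel &= power > 0
    if sel.sum() < 3:
        raise ValueError("spectrum does not cover the fit band")
    x = np.log10(freqs[sel])
    y = np.log10(power[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    passed = bool(r2 >= r2_threshold and slope < 0)
    return ChannelQc(
        channel=channel,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        n_bins=int(sel.sum()),
        passed=passed,
    )


def qc_recording(
    recording: Recording,
    config: MultitaperConfig | None = None,
    epoch_s: float | None = None,
    **qc_kwargs,
) -> pd.DataFrame:
    """Run the 1/f screen on every good channel; returns a tidy report.

    ``epoch_s`` screens only the leading epoch of that length (the screen is
    a spot check on selected epochs, not a full-session statistic).
    """
    rec = recording
    if epoch_s is not None and epoch_s < recording.duration:
        rec = recording.copy()
        rec.signal = rec.signal[:, : int(round(epoch_s * rec.fs))]
        rec.artifact_mask = {
            ch: [(s, min(e, rec.n_samples)) for s, e in ivs if s < rec.n_samples]
            for ch, ivs in rec.artifact_mask.items()
        }
    if config is not None and config.step != config.window_length:
        # the screen needs a PSD, not a dense spectrogram: non-overlapping windows
        config = MultitaperConfig(
            window_length=config.window_length,
            step=config.window_length,
            time_bandwidth=config.time_bandwidth,
            n_tapers=config.n_tapers,
            taper_family=config.taper_family,
        )
    rows = []
    for ch in rec.good_channels():
        psd = compute_psd(rec, ch, config=config)
        qc = qc_one_over_f(psd.freqs, psd.power, channel=ch, **qc_kwargs)
        rows.append(
            {
                "channel": ch,
                "label": rec.channel_labels[ch],
                "slope": qc.slope,
                "r2": qc.r2,
                "n_bins": qc.n_bins,
                "pass": qc.passed,
            }
        )
    return pd.DataFrame(rows, columns=["channel", "label", "slope", "r2", "n_bins", "pass"])
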