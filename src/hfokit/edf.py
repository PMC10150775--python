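"""EDF/EDF+ input-output, SEEG montage handling and artifact masks.

The central container is :class:`Recording`: a channels x samples matrix of
local field potentials in microvolts, with sampling rate, channel labels and
per-channel artifact masks.  Every downstream stage (spectral analysis, event
detection, rate statistics) consumes this object.

EDF here is the classic 16-bit European Data Format; EDF+ continuous files
are supported with a single annotation channel used to serialize artifact
masks (``ARTIFACT ch=<n>`` annotations).  All ordinary signals must share one
sampling rate — multi-rate EDF dialects are rejected.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Montage",
    "Contact",
    "EdfFormatError",
    "UnsupportedEdfError",
    "MontageError",
    "read_edf",
    "write_edf",
    "apply_montage",
    "mask_artifacts",
    "default_montage",
    "read_montage_csv",
    "write_montage_csv",
    "read_mask_csv",
    "write_mask_csv",
    "merge_intervals",
]

# 0.1 uV quantization: +/-3276.7 uV over +/-32767 digital counts
DEFAULT_PHYSICAL_MAX_UV = 3276.7
_DIGITAL_MAX = 32767
_ANNOT_LABEL = "EDF Annotations"
_ARTIFACT_PREFIX = "ARTIFACT"


class EdfFormatError(ValueError):
    """Unreadable, truncated or internally inconsistent EDF file."""


class UnsupportedEdfError(ValueError):
    """Valid EDF, but a dialect this package does not support (e.g. per-channel sampling rates)."""


class MontageError(ValueError):
    """Montage refers to channels absent from the recording."""


def merge_intervals(intervals):
    """Union of half-open integer intervals ``[start, end)``.

    Returns a sorted list of disjoint intervals; touching intervals merge.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class Contact:
    """One electrode contact of the SEEG montage (0-based channel index)."""

    contact: str
    channel: int
    hemisphere: str  # "left" | "right"
    region: str  # "hippocampus" | "sensorimotor" | "outside-brain"


@dataclass
class Montage:
    """Maps SEEG contacts to hemisphere and anatomical region.

    The study electrode geometry: 2.0 mm contact length, 1.5 mm inter-contact
    gap, 0.78 mm diameter, 8 contacts per electrode, one electrode per
    hemisphere (left = channels 1-8, right = 9-16 in 1-based display names).
    """

    contacts: list[Contact]
    contact_length_mm: float = 2.0
    contact_gap_mm: float = 1.5
    contact_diameter_mm: float = 0.78

    def __post_init__(self):
        idx = [c.channel for c in self.contacts]
        if len(set(idx)) != len(idx):
            raise MontageError("montage channel indices must be unique")

    def channels_in_region(self, region: str) -> list[int]:
        return [c.channel for c in self.contacts if c.region == region]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contact": c.contact,
                    "channel": c.channel,
                    "hemisphere": c.hemisphere,
                    "region": c.region,
                }
                for c in self.contacts
            ]
        )


def default_montage() -> Montage:
    """The study's bilateral 16-channel montage.

    Channels 1-3 (left) and 9-11 (right) lie in the hippocampus, 4-6 and
    12-14 in sensorimotor cortex; the two rearmost contacts of each electrode
    (7-8 and 15-16) typically remain outside the brain and are flagged bad.
    All indices here are 0-based; display names keep the 1-based convention.
    """
    contacts = []
    for hemi, offset in (("left", 0), ("right", 8)):
        for i in range(8):
            ch = offset + i
            if i < 3:
                region = "hippocampus"
            elif i < 6:
                region = "sensorimotor"
            else:
                region = "outside-brain"
            contacts.append(Contact(f"ch{ch + 1:02d}", ch, hemi, region))
    return Montage(contacts)


@dataclass
class Recording:
    """Multichannel intracranial EEG block in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in uV.
    fs : float
        Sampling rate in Hz (the study records at 4000 Hz).
    channel_labels : list of str
        Display names, 1-based by convention ("ch01".."ch16").
    start_time : datetime
        Recording start.
    artifact_mask : dict
        channel index -> sorted disjoint half-open sample intervals excluded
        from every downstream statistic.
    bad_channels : set of int
        Channels excluded entirely (never interpolated).
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 0, 0, 0)
    )
    artifact_mask: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    bad_channels: set[int] = field(default_factory=set)
    channel_regions: dict[int, str] = field(default_factory=dict)
    channel_hemispheres: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        if not self.bad_channels <= set(range(self.n_channels)):
            raise ValueError("bad_channels outside channel range")
        for ch, ivs in self.artifact_mask.items():
            for s, e in ivs:
                if not (0 <= s < e <= self.n_samples):
                    raise ValueError(f"artifact interval {(s, e)} out of bounds on channel {ch}")
            self.artifact_mask[ch] = merge_intervals(ivs)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.fs

    def good_channels(self) -> list[int]:
        return [c for c in range(self.n_channels) if c not in self.bad_channels]

    def analyzable_mask(self, channel: int) -> np.ndarray:
        """Boolean per-sample mask: True where the channel is analyzable."""
        good = np.ones(self.n_samples, dtype=bool)
        for s, e in self.artifact_mask.get(channel, []):
            good[s:e] = False
        return good

    def analyzable_samples(self, channel: int) -> int:
        masked = sum(e - s for s, e in self.artifact_mask.get(channel, []))
        return self.n_samples - masked

    def analyzable_duration(self, channel: int) -> float:
        """Analyzable (unmasked) duration of a channel, in seconds."""
        return self.analyzable_samples(channel) / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            signal=self.signal.copy(),
            channel_labels=list(self.channel_labels),
            artifact_mask={c: list(v) for c, v in self.artifact_mask.items()},
            bad_channels=set(self.bad_channels),
            channel_regions=dict(self.channel_regions),
            channel_hemispheres=dict(self.channel_hemispheres),
        )


def apply_montage(recording: Recording, montage: Montage) -> Recording:
    """Attach hemisphere/region labels; outside-brain contacts become bad channels.

    Idempotent: applying the same montage twice yields the same recording.
    """
    out = recording.copy()
    for c in montage.contacts:
        if not 0 <= c.channel < out.n_channels:
            raise MontageError(
                f"montage contact {c.contact} refers to channel {c.channel} "
                f"but recording has {out.n_channels} channels"
            )
    for c in montage.contacts:
        out.channel_regions[c.channel] = c.region
        out.channel_hemispheres[c.channel] = c.hemisphere
        if c.region == "outside-brain":
            out.bad_channels.add(c.channel)
    return out


def mask_artifacts(recording: Recording, intervals) -> Recording:
    """Mark ``(channel, start_s, end_s)`` intervals as artifacts (seconds, half-open).

    Overlapping intervals merge into their union; masked samples are excluded
    from every downstream statistic and from rate denominators.
    """
    out = recording.copy()
    for ch, start_s, end_s in intervals:
        if end_s <= start_s:
            raise ValueError(f"inverted interval ({start_s}, {end_s})")
        s = max(0, int(round(start_s * out.fs)))
        e = min(out.n_samples, int(round(end_s * out.fs)))
        if not 0 <= ch < out.n_channels:
            raise ValueError(f"channel {ch} out of range")
        if e <= s:
            raise ValueError(f"interval ({start_s}, {end_s}) outside recording")
        out.artifact_mask.setdefault(ch, []).append((s, e))
    for ch in out.artifact_mask:
        out.artifact_mask[ch] = merge_intervals(out.artifact_mask[ch])
        if out.analyzable_samples(ch) == 0:
            warnings.warn(f"channel {ch} fully masked; detectors will return empty")
    return out


# ---------------------------------------------------------------------------
# EDF reader / writer (16-bit, single sampling rate, EDF+C annotations)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise EdfFormatError(f"header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    recording: Recording,
    path,
    physical_max_uv: float = DEFAULT_PHYSICAL_MAX_UV,
    extra_annotations=(),
) -> None:
    """Write a Recording as 16-bit EDF (EDF+C when annotations are present).

    The physical range is symmetric ``+/-physical_max_uv`` over digital
    ``+/-32767``, i.e. a quantization step of ``physical_max_uv / 32767``
    (0.1 uV at the default).  Amplitudes outside the physical range raise.
    A trailing partial second is truncated with a warning (EDF records are
    1 s long here).

    ``extra_annotations`` is a list of ``(onset_s, duration_s, text)``
    triples (e.g. detected events for review in a standard EDF viewer);
    they are serialized alongside the ``ARTIFACT`` mask annotations.
    """
    if recording.n_samples == 0 or recording.n_channels == 0:
        raise EdfFormatError("cannot write an empty recording")
    fs_int = int(round(recording.fs))
    if abs(recording.fs - fs_int) > 1e-9:
        raise UnsupportedEdfError("writer supports integer sampling rates only")
    peak = float(np.max(np.abs(recording.signal))) if recording.signal.size else 0.0
    if peak > physical_max_uv:
        raise ValueError(
            f"amplitude {peak:.1f} uV exceeds physical range +/-{physical_max_uv} uV"
        )
    n_records = recording.n_samples // fs_int
    if n_records == 0:
        raise EdfFormatError("recording shorter than one 1-s EDF record")
    if n_records * fs_int != recording.n_samples:
        warnings.warn("truncating trailing partial second for EDF export")
    extra_annotations = list(extra_annotations)
    has_annotations = any(recording.artifact_mask.values()) or bool(extra_annotations)
    n_ord = recording.n_channels
    n_sig = n_ord + (1 if has_annotations else 0)

    annot_records: list[bytes] = []
    annot_spr = 0
    if has_annotations:
        tals = [b""] * n_records
        events = []
        for ch, ivs in sorted(recording.artifact_mask.items()):
            for s, e in ivs:
                events.append((s / recording.fs, (e - s) / recording.fs, f"{_ARTIFACT_PREFIX} ch={ch}"))
        for onset, dur, text in extra_annotations:
            events.append((float(onset), float(dur), str(text)))
        events.sort()
        for onset, dur, text in events:
            rec = min(int(onset), n_records - 1)
            tals[rec] += (
                f"+{onset:.4f}\x15{dur:.4f}\x14{text}\x14\x00"
            ).encode("ascii")
        for i in range(n_records):
            annot_records.append(f"+{i}\x14\x14\x00".encode("ascii") + tals[i])
        annot_spr = max(8, -(-max(len(r) for r in annot_records) // 2))
        annot_records = [r.ljust(annot_spr * 2, b"\x00") for r in annot_records]

    st = recording.start_time
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(st.strftime("%d.%m.%y"), 8),
            _pad(st.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("EDF+C" if has_annotations else "", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )
    labels = list(recording.channel_labels) + ([_ANNOT_LABEL] if has_annotations else [])
    phys_dims = ["uV"] * n_ord + ([""] if has_annotations else [])
    phys_mins = [f"{-physical_max_uv:g}"] * n_ord + (["-1"] if has_annotations else [])
    phys_maxs = [f"{physical_max_uv:g}"] * n_ord + (["1"] if has_annotations else [])
    dig_mins = [str(-_DIGITAL_MAX)] * n_ord + (["-32768"] if has_annotations else [])
    dig_maxs = [str(_DIGITAL_MAX)] * n_ord + (["32767"] if has_annotations else [])
    sprs = [str(fs_int)] * n_ord + ([str(annot_spr)] if has_annotations else [])
    for vals, width in [
        (labels, 16),
        ([""] * n_sig, 80),
        (phys_dims, 8),
        (phys_mins, 8),
        (phys_maxs, 8),
        (dig_mins, 8),
        (dig_maxs, 8),
        ([""] * n_sig, 80),
        (sprs, 8),
        ([""] * n_sig, 32),
    ]:
        header += b"".join(_pad(v, width) for v in vals)

    scale = _DIGITAL_MAX / physical_max_uv
    data = recording.signal[:, : n_records * fs_int]
    work = np.multiply(data, scale, dtype=np.float32)
    np.rint(work, out=work)
    digital = work.astype("<i2")
    # records x channels x samples-per-record layout
    interleaved = np.ascontiguousarray(
        digital.reshape(n_ord, n_records, fs_int).transpose(1, 0, 2)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        if has_annotations:
            buf = interleaved.reshape(n_records, -1)
            for i in range(n_records):
                fh.write(buf[i].tobytes())
                fh.write(annot_records[i])
        else:
            interleaved.tofile(fh)


def _parse_annotations(raw: bytes, fs: float, n_samples: int):
    mask: dict[int, list[tuple[int, int]]] = {}
    for tal in raw.split(b"\x00"):
        if not tal.strip(b"\x00 "):
            continue
        try:
            text = tal.decode("ascii", errors="replace")
            head, *notes = text.split("\x14")
            if "\x15" in head:
                onset_s, dur_s = head.split("\x15")
                onset, dur = float(onset_s), float(dur_s)
            else:
                onset, dur = float(head), 0.0
        except ValueError:
            continue
        for note in notes:
            if note.startswith(_ARTIFACT_PREFIX):
                ch = 0
                for tok in note.split():
                    if tok.startswith("ch="):
                        ch = int(tok[3:])
                s = max(0, int(round(onset * fs)))
                e = min(n_samples, int(round((onset + dur) * fs)))
                if e > s:
                    mask.setdefault(ch, []).append((s, e))
    return {ch: merge_intervals(ivs) for ch, ivs in mask.items()}


def read_edf(path, dtype=np.float64) -> Recording:
    """Read an EDF/EDF+ file into a Recording (amplitudes in uV).

    ``ARTIFACT``-prefixed EDF+ annotations populate the artifact mask.
    Raises :class:`EdfFormatError` for truncated files and
    :class:`UnsupportedEdfError` when ordinary signals have unequal
    sampling rates.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise EdfFormatError("truncated EDF header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_dur = float(fixed[244:252].decode("ascii").strip())
            n_sig = int(fixed[252:256].decode("ascii").strip())
            date = fixed[168:176].decode("ascii").strip()
            time = fixed[176:184].decode("ascii").strip()
        except ValueError as exc:
            raise EdfFormatError(f"malformed EDF header: {exc}") from None
        sig_hdr = fh.read(256 * n_sig)
        if len(sig_hdr) < 256 * n_sig:
            raise EdfFormatError("truncated EDF signal header")

        def fields(offset, width):
            base = offset * n_sig
            return [
                sig_hdr[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_sig)
            ]

        labels = fields(0, 16)
        pmin = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmax = [float(v) for v in fields(16 + 80 + 16, 8)]
        dmin = [float(v) for v in fields(16 + 80 + 24, 8)]
        dmax = [float(v) for v in fields(16 + 80 + 32, 8)]
        spr = [int(v) for v in fields(16 + 80 + 40 + 80, 8)]

        annot_idx = [i for i, lab in enumerate(labels) if lab == _ANNOT_LABEL]
        ord_idx = [i for i in range(n_sig) if i not in annot_idx]
        if not ord_idx:
            raise EdfFormatError("EDF file contains no ordinary signals")
        if len({spr[i] for i in ord_idx}) != 1:
            raise UnsupportedEdfError("per-channel sampling rates are not supported")
        spr0 = spr[ord_idx[0]]
        fs = spr0 / record_dur
        rec_len = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")
        if raw.size < rec_len * n_records:
            raise EdfFormatError("truncated EDF data section")
        raw = raw[: rec_len * n_records].reshape(n_records, rec_len)

    offsets = np.concatenate([[0], np.cumsum(spr)])
    n_samples = spr0 * n_records
    signal = np.empty((len(ord_idx), n_samples), dtype=dtype)
    for row, i in enumerate(ord_idx):
        block = raw[:, offsets[i] : offsets[i + 1]].astype(dtype)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        signal[row] = (block * gain + (pmin[i] - dmin[i] * gain)).ravel()

    mask: dict[int, list[tuple[int, int]]] = {}
    for i in annot_idx:
        raw_annot = raw[:, offsets[i] : offsets[i + 1]].tobytes()
        for ch, ivs in _parse_annotations(raw_annot, fs, n_samples).items():
            mask.setdefault(ch, []).extend(ivs)
    mask = {ch: merge_intervals(ivs) for ch, ivs in mask.items()}

    try:
        d, m, y = (int(v) for v in date.split("."))
        hh, mm, ss = (int(v) for v in time.split("."))
        y += 2000 if y < 85 else 1900
        start = _dt.datetime(y, m, d, hh, mm, ss)
    except ValueError:
        start = _dt.datetime(2000, 1, 1)

    return Recording(
        signal=signal,
        fs=fs,
        channel_labels=[labels[i] for i in ord_idx],
        start_time=start,
        artifact_mask=mask,
    )


# ---------------------------------------------------------------------------
# Sidecar CSV formats
# ---------------------------------------------------------------------------

def write_montage_csv(montage: Montage, path) -> None:
    montage.to_frame().to_csv(path, index=False)


def read_montage_csv(path) -> Montage:
    df = pd.read_csv(path)
    return Montage(
        [
            Contact(str(r.contact), int(r.channel), str(r.hemisphere), str(r.region))
            for r in df.itertuples()
        ]
    )


def write_mask_csv(recording: Recording, path) -> None:
    rows = [
        {"channel": ch, "start_s": s / recording.fs, "end_s": e / recording.fs}
        for ch, ivs in sorted(recording.artifact_mask.items())
        for s, e in ivs
    ]
    pd.DataFrame(rows, columns=["channel", "start_s", "end_s"]).to_csv(path, index=False)


def read_mask_csv(path):
    df = pd.read_csv(path)
    return [(int(r.channel), float(r.start_s), float(r.end_s)) for r in df.itertuples()]
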