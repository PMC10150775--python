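"""Study-level orchestration: QC -> detection -> rates -> statistics -> ICC.

``run_pipeline`` consumes a session manifest (CSV: one row per EDF with
animal, group, week) and produces, deterministically for a fixed seed and
config:

* ``qc.csv`` — per session x channel 1/f screen results;
* ``events.csv`` — every detected event (IED / seizure / HFO);
* ``counts.csv`` / ``rates.csv`` — per session and per week event rates,
  with analyzable minutes (artifact-masked time excluded) as denominators;
* ``stats_tests.csv`` / ``stats.json`` — within-group (weeks vs baseline)
  and between-group (E+ vs E-) comparisons with Bonferroni correction;
* ``icc.json`` — ICC(1,k) test-retest reliability of weekly hippocampal
  HFO rates, pooled and per group;
* ``spectrograms/`` — one coarse multitaper spectrogram per session
  (representative hippocampal channel, exported as CSV);
* ``log.txt`` — config hash, seed, versions, and per-session notes.

Every statistic is recomputable from the emitted CSVs alone.  Channels
failing QC are excluded from detection with a logged reason.  Reruns
refuse to overwrite an existing output directory unless ``force`` is set;
with ``force`` and the same inputs the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import DetectorConfig, detect_hfo, detect_ied, detect_seizure, events_to_frame
from .edf import Recording, apply_montage, default_montage, read_edf
from .spectral import MultitaperConfig, multitaper_spectrogram, qc_recording
from .stats import build_rate_table, compare_rates, icc_1k, rate_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    manifest: str = "manifest.csv"
    outdir: str = "pipeline_out"
    seed: int = 0
    channel_scope: str = "hippocampus"  # "hippocampus" | "in-brain" | "all"
    seizure_reference_only: bool = True  # one reference channel per hemisphere
    qc_epoch_s: float = 60.0
    qc_r2_threshold: float = 0.8
    alpha: float = 0.05
    bonferroni: bool = True
    export_spectrograms: bool = True
    spectrogram_step_s: float = 30.0
    spectrogram_max_hz: float = 100.0
    icc_weeks: tuple[int, ...] = (1, 2, 3, 4)
    force: bool = False
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    multitaper: MultitaperConfig = field(default_factory=MultitaperConfig)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.channel_scope not in ("hippocampus", "in-brain", "all"):
            raise ValueError("channel_scope must be hippocampus | in-brain | all")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self, include_paths: bool = False) -> dict:
        """Analysis parameters as a plain dict.

        The run locations (manifest, outdir) and the overwrite flag are
        environment, not analysis parameters: they are excluded by default
        so the recorded config and its hash are identical wherever the same
        analysis runs.
        """
        d = dataclasses.asdict(self)
        d["icc_weeks"] = list(self.icc_weeks)
        if not include_paths:
            for key in ("manifest", "outdir", "force"):
                d.pop(key, None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        det = d.pop("detector", {})
        mt = d.pop("multitaper", {})
        if "icc_weeks" in d:
            d["icc_weeks"] = tuple(d["icc_weeks"])
        for key in ("ied_band", "seizure_band", "hfo_band"):
            if key in det:
                det[key] = tuple(det[key])
        return cls(**d, detector=DetectorConfig(**det), multitaper=MultitaperConfig(**mt))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path, include_paths: bool = False) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(include_paths=include_paths), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    qc: pd.DataFrame
    events: pd.DataFrame
    counts: pd.DataFrame
    rates: pd.DataFrame
    icc: dict
    stats: dict
    log: list[str]


def _scope_channels(rec: Recording, scope: str) -> list[int]:
    good = rec.good_channels()
    if scope == "all":
        return good
    if scope == "in-brain":
        return [c for c in good if rec.channel_regions.get(c) != "outside-brain"]
    return [c for c in good if rec.channel_regions.get(c) == "hippocampus"]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _analyze_session(row, config: PipelineConfig, manifest_dir: Path, log: list[str]):
    """QC + detection for one manifest row; returns (qc_df, events_df, counts_df)."""
    path = manifest_dir / row["path"]
    rec = read_edf(path, dtype=np.float32)
    if rec.n_channels == 16:
        rec = apply_montage(rec, default_montage())
    session = row["session"]

    qc = qc_recording(
        rec,
        config=config.multitaper,
        epoch_s=config.qc_epoch_s,
        r2_threshold=config.qc_r2_threshold,
    )
    qc.insert(0, "session", session)
    failed = set(qc.loc[~qc["pass"], "channel"])
    for ch in sorted(failed):
        log.append(f"WARN {session}: channel {ch} failed 1/f QC; excluded from detection")

    channels = [c for c in _scope_channels(rec, config.channel_scope) if c not in failed]
    if not channels:
        raise RuntimeError(f"no analyzable channels in scope for session {session}")

    det = config.detector
    half = rec.n_channels // 2
    if config.seizure_reference_only:
        left = [c for c in channels if c < half]
        right = [c for c in channels if c >= half]
        refs = [min(side) for side in (left, right) if side]
    else:
        refs = channels
    seizures_by_hemi: dict[bool, list] = {True: [], False: []}
    all_events = []
    for ref in refs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            szs = detect_seizure(rec, ref, det)
        seizures_by_hemi[ref < half].extend(szs)
        all_events.extend(szs)

    counts_rows = []
    for ch in channels:
        sz_iv = [(e.onset, e.offset) for e in seizures_by_hemi[ch < half]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hfos = detect_hfo(rec, ch, det, exclude_intervals=sz_iv)
            ieds = detect_ied(rec, ch, det)
        all_events.extend(hfos)
        all_events.extend(ieds)
        minutes = rec.analyzable_duration(ch) / 60.0
        region = rec.channel_regions.get(ch, "unknown")
        for kind, evs in (("HFO", hfos), ("IED", ieds)):
            counts_rows.append(
                {
                    "session": session,
                    "animal": row["animal"],
                    "week": int(row["week"]),
                    "channel": ch,
                    "region": region,
                    "kind": kind,
                    "n_events": len(evs),
                    "minutes": minutes,
                }
            )
        counts_rows.append(
            {
                "session": session,
                "animal": row["animal"],
                "week": int(row["week"]),
                "channel": ch,
                "region": region,
                "kind": "seizure",
                "n_events": sum(1 for e in seizures_by_hemi[ch < half] if e.channel == ch),
                "minutes": minutes,
            }
        )

    events = events_to_frame(all_events, rec.fs, animal=row["animal"], session=session)
    events = events.sort_values(["onset_s", "channel", "kind"], kind="stable").reset_index(drop=True)

    spec_df = None
    if config.export_spectrograms:
        ch0 = channels[0]
        mt = MultitaperConfig(
            window_length=config.multitaper.window_length,
            step=config.spectrogram_step_s,
            time_bandwidth=config.multitaper.time_bandwidth,
            n_tapers=config.multitaper.n_tapers,
        )
        spec = multitaper_spectrogram(rec, ch0, mt)
        sel = spec.freqs <= config.spectrogram_max_hz
        spec_df = pd.DataFrame(
            spec.P[sel], index=np.round(spec.freqs[sel], 4), columns=np.round(spec.times, 2)
        )
        spec_df.index.name = "freq_hz"
    return qc, events, pd.DataFrame(counts_rows), spec_df


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis for every session in the manifest.

    Failures are isolated per session (logged, analysis continues); the run
    aborts only if no session passes QC with analyzable channels.
    """
    outdir = Path(config.outdir)
    sentinel = outdir / "log.txt"
    if sentinel.exists() and not config.force:
        raise FileExistsError(
            f"{outdir} already contains pipeline outputs; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(config.manifest)
    manifest = pd.read_csv(manifest_path)
    if len(manifest) == 0:
        raise ValueError("manifest lists no sessions")
    manifest_dir = manifest_path.parent

    log: list[str] = [
        f"hfokit {__version__} | numpy {np.__version__} | pandas {pd.__version__}",
        f"seed {config.seed} | config hash {config.content_hash()}",
        f"manifest {manifest_path.name} with {len(manifest)} sessions",
    ]
    qc_frames, event_frames, count_frames = [], [], []
    spec_dir = outdir / "spectrograms"
    if config.export_spectrograms:
        spec_dir.mkdir(exist_ok=True)
    n_ok = 0
    for _, row in manifest.iterrows():
        try:
            qc, events, counts, spec_df = _analyze_session(row, config, manifest_dir, log)
        except Exception as exc:  # isolate per-session failures
            log.append(f"ERROR {row['session']}: {exc}")
            continue
        qc_frames.append(qc)
        event_frames.append(events)
        count_frames.append(counts)
        if spec_df is not None:
            spec_df.to_csv(spec_dir / f"{row['session']}.csv", float_format="%.5e")
        n_ok += 1
        log.append(f"INFO {row['session']}: {len(events)} events on {counts['channel'].nunique()} channels")
    if n_ok == 0:
        raise RuntimeError("pipeline aborted: no session passed QC with analyzable channels\n" + "\n".join(log))

    qc_all = pd.concat(qc_frames, ignore_index=True)
    events_all = pd.concat(event_frames, ignore_index=True)
    counts_all = pd.concat(count_frames, ignore_index=True)

    man_groups = manifest[["animal", "group"]].drop_duplicates()
    rate_frames = []
    for kind, sub in counts_all.groupby("kind"):
        rt = build_rate_table(sub.drop(columns=["kind", "session"]), man_groups)
        rt.insert(0, "kind", kind)
        rate_frames.append(rt)
    rates_all = pd.concat(rate_frames, ignore_index=True)

    # --- statistics on hippocampal HFO rates
    hfo = rates_all[(rates_all["kind"] == "HFO") & (rates_all["region"] == "hippocampus")]
    per_animal_week = (
        hfo.groupby(["animal", "group", "week"], as_index=False)["rate_per_min"].mean()
    )
    stats: dict = {"alpha": config.alpha, "bonferroni": config.bonferroni}
    tests_frames = []
    post = per_animal_week[per_animal_week["week"] > 0]
    try:
        between = compare_rates(post, design="between", bonferroni_correct=config.bonferroni)
        stats["between_groups"] = {
            "anova_F": between.anova_F,
            "anova_p": between.anova_p,
            "group_means": between.group_stats.to_dict(orient="records"),
        }
        tf = between.tests.copy()
        tf.insert(0, "family", "between_groups")
        tests_frames.append(tf)
    except ValueError as exc:
        log.append(f"WARN between-group comparison skipped: {exc}")
    for grp, sub in per_animal_week.groupby("group"):
        try:
            within = compare_rates(sub, design="within", bonferroni_correct=config.bonferroni)
        except ValueError as exc:
            log.append(f"WARN within-group comparison for {grp} skipped: {exc}")
            continue
        stats[f"within_{grp}"] = {"anova_F": within.anova_F, "anova_p": within.anova_p}
        tf = within.tests.copy()
        tf.insert(0, "family", f"within_{grp}")
        tests_frames.append(tf)

    # --- ICC(1,k) on weekly hippocampal HFO rates
    icc_report: dict = {"weeks": list(config.icc_weeks), "subject": "animal"}
    for name, sub in [("pooled", hfo)] + [
        (str(g), hfo[hfo["group"] == g]) for g in sorted(hfo["group"].unique())
    ]:
        try:
            mat, subjects = rate_matrix(sub, weeks=config.icc_weeks)
            res = icc_1k(mat)
            icc_report[name] = {**res.to_dict(), "subjects": [str(s) for s in subjects]}
        except (ValueError, ZeroDivisionError) as exc:
            icc_report[name] = {"error": str(exc)}
            log.append(f"WARN ICC ({name}) not computed: {exc}")

    _write_csv(qc_all, outdir / "qc.csv")
    _write_csv(events_all, outdir / "events.csv")
    _write_csv(counts_all, outdir / "counts.csv")
    _write_csv(rates_all, outdir / "rates.csv")
    if tests_frames:
        _write_csv(pd.concat(tests_frames, ignore_index=True), outdir / "stats_tests.csv")
    _write_json(stats, outdir / "stats.json")
    _write_json(icc_report, outdir / "icc.json")
    config.to_yaml(outdir / "config_used.yaml")
    (outdir / "log.txt").write_text("\n".join(log) + "\n")

    return PipelineResult(
        outdir=outdir,
        qc=qc_all,
        events=events_all,
        counts=counts_all,
        rates=rates_all,
        icc=icc_report,
        stats=stats,
        log=log,
    )
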