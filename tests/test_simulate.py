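"""Generator determinism, spectral structure, ground-truth bookkeeping, scoring."""

import hashlib
import itertools

import numpy as np
import pandas as pd
import pytest

import hfokit as hk
from hfokit.simulate import Score, score_detections


def _bandpower(psd, lo, hi):
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    return psd.power[sel].sum()


class TestBackground:
    def test_same_seed_identical(self):
        cfg = hk.GeneratorConfig(fs=1000.0, n_channels=2, duration_s=30.0, seed=77)
        a = hk.generate_background(cfg)
        b = hk.generate_background(cfg)
        assert np.array_equal(a.signal, b.signal)

    def test_different_seed_differs(self):
        a = hk.generate_background(hk.GeneratorConfig(fs=1000.0, n_channels=1, duration_s=30.0, seed=1))
        b = hk.generate_background(hk.GeneratorConfig(fs=1000.0, n_channels=1, duration_s=30.0, seed=2))
        assert not np.array_equal(a.signal, b.signal)

    def test_baseline_passes_qc(self, baseline_2ch):
        rec, _ = baseline_2ch
        report = hk.qc_recording(rec)
        assert report["pass"].all()

    def test_postka_spectral_contrast(self, baseline_2ch, postka_2ch):
        """After the insult: 18-20 Hz burst power appears, the alpha peak vanishes."""
        base, _ = baseline_2ch
        post, _ = postka_2ch
        pb = hk.compute_psd(base, 0)
        pp = hk.compute_psd(post, 0)
        assert _bandpower(pp, 18, 20) > 3.0 * _bandpower(pb, 18, 20)
        assert _bandpower(pb, 9.5, 10.5) > 3.0 * _bandpower(pp, 9.5, 10.5)

    def test_line_noise_peak(self, baseline_2ch):
        rec, _ = baseline_2ch
        psd = hk.compute_psd(rec, 0)
        sel = np.abs(psd.freqs - 50.0) <= 0.2
        near = psd.power[np.abs(psd.freqs - 47.0) <= 0.5].mean()
        assert psd.power[sel].max() > 10.0 * near

    def test_oscillation_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            hk.GeneratorConfig(
                fs=200.0, duration_s=10.0,
                oscillations=[hk.simulate.OscillationSpec(150.0, 1.0, 10.0)],
            )

    def test_hemisphere_correlation(self):
        """Channels within a hemisphere correlate more than across hemispheres."""
        cfg = hk.GeneratorConfig(fs=1000.0, n_channels=4, duration_s=60.0, seed=4, hemisphere_mixing=0.5)
        rec = hk.generate_background(cfg)
        x = rec.signal.astype(np.float64)
        within = np.corrcoef(x[0], x[1])[0, 1]
        across = np.corrcoef(x[0], x[2])[0, 1]
        assert within > across + 0.05


class TestInjection:
    def test_truth_counts_near_rate(self, busy_session):
        """~rate x minutes ripples injected on each hippocampal channel, all logged."""
        _rec, truth, cfg = busy_session
        for ch in (0, 1):
            n = len(truth.of_kind("HFO", ch))
            lam = 10.0 * 10.0  # rate x minutes
            assert abs(n - lam) <= 4 * np.sqrt(lam)

    def test_truth_sorted_and_in_bounds(self, busy_session):
        rec, truth, _ = busy_session
        onsets = [ev.onset for ev in truth.events]
        assert onsets == sorted(onsets)
        assert all(0 <= ev.onset < ev.offset <= rec.n_samples for ev in truth.events)

    def test_zero_rate_no_events(self):
        cfg = hk.GeneratorConfig(fs=1000.0, n_channels=1, duration_s=30.0, seed=5)
        _rec, truth = hk.generate_session(cfg)
        assert truth.of_kind("IED") == []
        assert truth.of_kind("HFO") == []

    def test_events_avoid_artifacts(self):
        cfg = hk.GeneratorConfig(
            fs=2000.0, n_channels=2, duration_s=300.0, seed=6,
            ied_per_min=4.0, hfo_per_min={"hippocampus": 8.0}, artifact_per_min=1.0,
        )
        _rec, truth = hk.generate_session(cfg)
        artifacts = [(e.onset, e.offset) for e in truth.events if e.kind == "artifact"]
        assert artifacts, "artifact schedule should be non-empty at 1/min"
        for ev in truth.events:
            if ev.kind == "artifact":
                continue
            assert not any(ev.onset < ae and as_ < ev.offset for as_, ae in artifacts)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            hk.GeneratorConfig(fs=1000.0, duration_s=10.0, ied_per_min=-1.0)

    def test_event_longer_than_recording_rejected(self):
        cfg = hk.GeneratorConfig(
            fs=1000.0, n_channels=1, duration_s=20.0, seed=1,
            seizure_times_s=None, n_seizures=1, seizure_duration_range_s=(30.0, 40.0),
        )
        with pytest.raises(ValueError, match="longer than the recording"):
            hk.generate_session(cfg)

    def test_population_parameters_stable_across_seeds(self):
        """Changing only the seed preserves the configured rates within sampling error."""
        counts = []
        for seed in range(50):
            cfg = hk.GeneratorConfig(
                fs=1000.0, n_channels=1, duration_s=60.0, seed=seed,
                hfo_per_min={"hippocampus": 10.0},
            )
            _rec, truth = hk.generate_session(cfg)
            counts.append(len(truth.of_kind("HFO")))
        mean = np.mean(counts)
        assert abs(mean - 10.0) < 3 * np.sqrt(10.0 / 50)


class TestStudy:
    def test_structure_and_files(self, small_study):
        sessions = small_study.sessions
        assert len(sessions) == 5 * 5  # 5 animals x (baseline + 4 weeks)
        assert set(sessions["group"]) == {"E+", "E-"}
        for p in sessions["path"]:
            assert (small_study.root / p).exists()
        truth = pd.read_csv(small_study.truth_csv)
        assert {"session", "kind", "channel", "onset_s"} <= set(truth.columns)

    def test_eplus_truth_rates_exceed_baseline(self, small_study):
        truth = pd.read_csv(small_study.truth_csv)
        sessions = small_study.sessions
        hippocampal = {0, 1, 2, 8, 9, 10}
        hfo = truth[(truth["kind"] == "HFO") & truth["channel"].isin(hippocampal)]
        counts = hfo.groupby(["animal", "week"]).size()
        for animal in sessions.loc[sessions["group"] == "E+", "animal"].unique():
            base = counts.get((animal, 0), 0)
            for week in (1, 2, 3, 4):
                assert counts.get((animal, week), 0) > base

    def test_seeded_study_reproducible(self, tmp_path):
        man = hk.default_study_manifest(n_eplus=1, n_eminus=1, seed=3, session_duration_s=60.0)
        digests = []
        for sub in ("a", "b"):
            data = hk.generate_study(man, seed=3, outdir=tmp_path / sub)
            h = hashlib.sha256()
            for p in sorted(data.root.iterdir()):
                h.update(p.name.encode())
                h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_duplicate_animal_ids_rejected(self):
        spec = hk.simulate.AnimalSpec("A", "E+", {0: 1.0})
        with pytest.raises(ValueError, match="duplicate"):
            hk.StudyManifest(animals=[spec, spec])

    def test_generator_config_yaml_roundtrip(self, tmp_path):
        cfg = hk.GeneratorConfig(
            fs=1000.0, n_channels=2, duration_s=30.0, state="postka", seed=9,
            hfo_per_min={"hippocampus": 5.0},
            oscillations=[hk.simulate.OscillationSpec(12.0, 1.0, 10.0, channels=(0,), bursty=True)],
        )
        cfg.to_yaml(tmp_path / "g.yaml")
        back = hk.GeneratorConfig.from_yaml(tmp_path / "g.yaml")
        assert back == cfg
        a = hk.generate_background(cfg)
        b = hk.generate_background(back)
        assert np.array_equal(a.signal, b.signal)

    def test_default_group_sizes(self):
        man = hk.default_study_manifest(seed=0)
        groups = [a.group for a in man.animals]
        assert groups.count("E+") == 8 and groups.count("E-") == 4
        for a in man.animals:
            assert set(a.hfo_rate_by_week) == {0, 1, 2, 3, 4}
            if a.group == "E-":
                assert all(a.hfo_rate_by_week[w] <= a.hfo_rate_by_week[0] for w in (1, 2, 3, 4))


def _max_matching(det, tru, tol):
    """Exhaustive maximum one-to-one assignment (oracle for small n)."""
    best = 0
    det = list(det)
    for perm in itertools.permutations(range(len(tru)), min(len(tru), len(det))):
        used = set()
        count = 0
        for di, tj in enumerate(perm):
            if tj in used:
                continue
            if abs(det[di] - tru[tj]) <= tol:
                used.add(tj)
                count += 1
        best = max(best, count)
    return best


class TestScoring:
    def test_perfect_detection(self):
        s = score_detections([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.05, 10.0)
        assert s.sensitivity == 1.0 and s.precision == 1.0 and s.fp_rate_per_min == 0.0

    def test_empty_detections(self):
        s = score_detections([], [1.0, 2.0], 0.05, 10.0)
        assert s.sensitivity == 0.0 and s.fp_rate_per_min == 0.0

    def test_greedy_matches_bruteforce_oracle(self):
        """On well-separated events the greedy matcher equals exhaustive assignment."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            tru = np.sort(rng.choice(np.arange(5, 300, 3), size=6, replace=False)).astype(float)
            det = list(tru[rng.random(6) < 0.8] + rng.uniform(-0.4, 0.4, size=None))
            det += list(rng.uniform(400, 500, size=2))  # far false positives
            s = score_detections(det, tru, tolerance_s=1.0, duration_min=10.0)
            assert s.tp == _max_matching(sorted(det), list(tru), 1.0)

    def test_one_to_one(self):
        """Two detections near one truth event: only one is credited."""
        s = score_detections([10.0, 10.1], [10.0], 0.5, 1.0)
        assert s.tp == 1
        assert s.fp_rate_per_min == 1.0
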