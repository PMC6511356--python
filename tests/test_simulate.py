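"""Simulator: acoustics, frame-grid ground truth, corpus statistics."""

import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import binom

from ausculta.phenomena import CLASSES, SPECS, ConstraintViolation, PhenomenonEvent, RecordingLabels
from ausculta.simulate import (
    BreathCycleSpec,
    _plan_events,
    compose_recording,
    frame_truth_from_events,
    generate_breath_track,
    generate_corpus,
    synthesize_event,
)

SR = 8000


class TestBreathTrack:
    def test_deterministic_under_fixed_seed(self):
        a = generate_breath_track(3.0, seed=1)
        b = generate_breath_track(3.0, seed=1)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, generate_breath_track(3.0, seed=2))

    def test_band_limited_by_periodogram_oracle(self):
        x = generate_breath_track(6.0, seed=1)
        f, p = periodogram(x, fs=SR)
        in_band = p[(f >= 50) & (f <= 2500)].sum()
        total = p.sum()
        assert in_band / total >= 0.99
        # out-of-band power at least 30 dB below in-band power
        assert (total - in_band) <= in_band * 1e-3

    def test_inspiration_louder_than_expiration(self):
        spec = BreathCycleSpec(inspiration_fraction=0.4)
        x = generate_breath_track(9.0, spec, seed=5)
        t = np.arange(len(x)) / SR
        phase = np.mod(t, spec.cycle_duration) / spec.cycle_duration
        insp = x[phase < spec.inspiration_fraction]
        expi = x[phase >= spec.inspiration_fraction]
        assert np.sqrt(np.mean(insp**2)) > np.sqrt(np.mean(expi**2))

    @pytest.mark.parametrize("duration", [0.0, -1.0, 2.0])
    def test_invalid_duration_rejected(self, duration):
        with pytest.raises(ValueError):
            generate_breath_track(duration, BreathCycleSpec(cycle_duration=3.0), seed=0)

    def test_cycle_spec_invariants(self):
        with pytest.raises(ValueError):
            BreathCycleSpec(inspiration_fraction=0.6)  # expiration must be longer
        with pytest.raises(ValueError):
            BreathCycleSpec(inspiration_level_db=0.0, expiration_level_db=0.0)


class TestSynthesizeEvent:
    @pytest.mark.parametrize("f0", [150.0, 400.0, 800.0])
    def test_wheeze_spectral_peak_at_f0(self, f0):
        ev = PhenomenonEvent("wheeze", 0.0, 0.5, f0=f0)
        x = synthesize_event(SPECS["wheeze"], ev, SR, seed=2)
        spectrum = np.abs(np.fft.rfft(x))
        peak = np.fft.rfftfreq(len(x), 1 / SR)[np.argmax(spectrum)]
        bin_width = SR / len(x)
        assert abs(peak - f0) <= bin_width

    def test_wheeze_below_80ms_rejected(self):
        ev = PhenomenonEvent("wheeze", 0.0, 0.05, f0=400.0)
        with pytest.raises(ConstraintViolation):
            synthesize_event(SPECS["wheeze"], ev, SR, seed=0)

    def test_rhonchus_below_100ms_rejected(self):
        ev = PhenomenonEvent("rhonchus", 0.0, 0.09, f0=150.0)
        with pytest.raises(ConstraintViolation):
            synthesize_event(SPECS["rhonchus"], ev, SR, seed=0)

    def test_offset_must_exceed_onset(self):
        with pytest.raises(ConstraintViolation):
            PhenomenonEvent("fine_crackle", 1.0, 1.0).validate()

    def test_rhonchus_fundamental_below_300(self):
        with pytest.raises(ConstraintViolation):
            PhenomenonEvent("rhonchus", 0.0, 0.5, f0=400.0).validate()

    @pytest.mark.parametrize("cls,nominal", [("fine_crackle", 0.005), ("coarse_crackle", 0.015)])
    def test_crackle_energy_concentrated_near_onset(self, cls, nominal):
        ev = PhenomenonEvent(cls, 0.0, nominal, f0=700.0)
        x = synthesize_event(SPECS[cls], ev, SR, seed=4)
        # cumulative-energy oracle: >= 90% of energy within 10 ms of onset
        energy = np.cumsum(x**2)
        n10ms = min(len(x), round(0.010 * SR))
        assert energy[n10ms - 1] / energy[-1] >= 0.90


class TestComposeRecording:
    def test_empty_plan_gives_all_false_truth(self):
        rec = compose_recording(4.0, event_plan=[], seed=0)
        assert rec.frame_truth.shape == (400, 4)
        assert not rec.frame_truth.any()
        assert not rec.labels.any_pathology

    def test_wheeze_frame_grid_arithmetic(self, wheeze_recording):
        truth = wheeze_recording.frame_truth
        col = list(CLASSES).index("wheeze")
        active = np.nonzero(truth[:, col])[0]
        assert active.tolist() == list(range(100, 120))
        assert truth[:, [c != col for c in range(4)]].sum() == 0

    def test_event_past_duration_rejected(self):
        ev = PhenomenonEvent("wheeze", 3.9, 4.2, f0=300.0)
        with pytest.raises(ValueError):
            compose_recording(4.0, event_plan=[ev], seed=0)

    def test_frame_truth_matches_bruteforce_overlap(self, rng):
        """50 random event plans against a per-frame interval-overlap oracle."""
        hop = 0.010
        for _ in range(50):
            duration = float(rng.uniform(1.0, 6.0))
            events = []
            for _ in range(rng.integers(0, 8)):
                cls = str(rng.choice(CLASSES))
                lo = SPECS[cls].min_duration or 0.005
                dur = float(rng.uniform(lo, min(lo + 1.0, duration)))
                onset = float(rng.uniform(0, duration - dur))
                events.append(PhenomenonEvent(cls, round(onset, 6), round(onset + dur, 6)))
            truth = frame_truth_from_events(events, duration)
            n = int(np.floor(round(duration * 1e6) / 1e4))
            expected = np.zeros((n, 4), dtype=bool)
            for i in range(n):
                f_lo, f_hi = i * hop, (i + 1) * hop
                for ev in events:
                    # half-open interval overlap at microsecond resolution
                    if round(ev.onset * 1e6) < round(f_hi * 1e6) and round(ev.offset * 1e6) > round(f_lo * 1e6):
                        expected[i, list(CLASSES).index(ev.class_name)] = True
            np.testing.assert_array_equal(truth, expected)

    def test_polyphony_allowed(self):
        evs = [PhenomenonEvent("wheeze", 1.0, 1.5, f0=400.0),
               PhenomenonEvent("rhonchus", 1.2, 1.6, f0=150.0)]
        rec = compose_recording(4.0, event_plan=evs, seed=0)
        both = rec.frame_truth[:, 0] & rec.frame_truth[:, 1]
        assert both.any()

    def test_interference_changes_audio_not_truth(self):
        ev = [PhenomenonEvent("wheeze", 1.0, 1.3, f0=400.0)]
        clean = compose_recording(4.0, event_plan=ev, seed=5, interference_level=0.0)
        noisy = compose_recording(4.0, event_plan=ev, seed=5, interference_level=1.0)
        assert not np.array_equal(clean.samples, noisy.samples)
        np.testing.assert_array_equal(clean.frame_truth, noisy.frame_truth)


class TestCorpus:
    def test_observed_prevalence_within_binomial_band(self):
        _, manifest = generate_corpus(100, {"wheeze": 0.24}, seed=11, duration=3.0)
        k = int(manifest["wheeze"].sum())
        lo, hi = binom.ppf([0.005, 0.995], 100, 0.24)
        assert lo <= k <= hi

    def test_zero_prevalence_gives_pathology_free_corpus(self):
        recs, manifest = generate_corpus(10, {c: 0.0 for c in CLASSES}, seed=3, duration=3.0)
        assert manifest[list(CLASSES)].to_numpy().sum() == 0
        assert all(not r.labels.any_pathology for r in recs)

    def test_same_seed_byte_identical_manifests(self, tmp_path):
        for sub in ("a", "b"):
            generate_corpus(4, seed=9, duration=3.0, out_dir=tmp_path / sub)
        a = (tmp_path / "a" / "manifest.csv").read_bytes()
        b = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert a == b
        wav_a = (tmp_path / "a" / "rec_0000.wav").read_bytes()
        wav_b = (tmp_path / "b" / "rec_0000.wav").read_bytes()
        assert wav_a == wav_b

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_corpus(0, seed=0)
        with pytest.raises(ValueError):
            generate_corpus(2, {"wheeze": 1.5}, seed=0)
        with pytest.raises(ValueError):
            generate_corpus(2, {"sneeze": 0.5}, seed=0)

    def test_ground_truth_consistency(self, tiny_corpus):
        """Recording label for a class iff >= 1 event of it iff any frame true."""
        recordings, manifest = tiny_corpus
        for rec, (_, row) in zip(recordings, manifest.iterrows()):
            for j, c in enumerate(CLASSES):
                has_event = any(e.class_name == c for e in rec.events)
                assert bool(row[c]) == has_event == bool(rec.frame_truth[:, j].any())

    def test_sampled_events_respect_definitions(self, rng):
        """Duration and fundamental-frequency bounds over 1,000 planned events."""
        events = []
        while len(events) < 1000:
            labels = RecordingLabels(**{c: bool(rng.random() < 0.5) for c in CLASSES})
            events.extend(_plan_events(labels, 15.0, rng))
        for ev in events[:1000]:
            ev.validate()
            if ev.class_name == "wheeze":
                assert ev.duration >= 0.080 and 100 <= ev.f0 <= 1000
            elif ev.class_name == "rhonchus":
                assert ev.duration >= 0.100 and ev.f0 < 300
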