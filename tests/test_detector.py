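"""Window encoding, detector training, oracle detection, reconciliation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgnorm import detector as det
from ppgnorm import synthetic as syn
from ppgnorm.signal_io import AnalysisWindow, PPGRecord


def _window(x, start=0):
    v = np.append(np.diff(x), 0.0)
    return AnalysisWindow(start, np.asarray(x, float), v)


class TestEncoding:
    def test_constant_window_maps_to_half_with_zero_flags(self):
        enc = det.encode_window(_window(np.full(75, 9.0)))
        assert len(enc) == det.ENCODING_LENGTH == 210
        np.testing.assert_array_equal(enc[:150], 0.5)
        np.testing.assert_array_equal(enc[150:], 0.0)

    def test_central_maximum_sets_its_peak_flag(self):
        x = np.zeros(75)
        x[38] = 1.0  # central-region PPG max at bin (38-28)=10 -> flag bin 7
        enc = det.encode_window(_window(x))
        flags = enc[150:165]
        assert flags[(10 * 15) // 20] == 1.0
        assert flags.sum() == 1.0

    def test_random_window_has_length_210_and_unit_range(self):
        rng = np.random.default_rng(0)
        enc = det.encode_window(_window(rng.normal(size=75)))
        assert enc.shape == (210,)
        assert enc.min() >= 0.0 and enc.max() <= 1.0

    def test_affine_amplitude_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=75)
        a = det.encode_window(_window(x))
        b = det.encode_window(_window(5.2 * x + 300.0))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_batch_encoding_matches_single_windows(self, clean_recording):
        rec, _ = clean_recording
        X, starts = det.encode_record(rec)
        from ppgnorm.signal_io import sliding_windows

        wins = sliding_windows(rec)
        for i in (0, 100, 777, len(wins) - 1):
            np.testing.assert_allclose(X[i], det.encode_window(wins[i]), atol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(det.DetectorError):
            det.encode_matrix(np.zeros((1, 60)), np.zeros((1, 60)))


class TestWindowTargets:
    def test_positions_map_to_bins_or_absent(self):
        starts = np.arange(50)
        targets = det.window_targets(starts, {"W": np.array([40])})
        # window start s sees sample 40 when 28 <= 40 - s < 48
        for s in starts:
            expected = 40 - s - 28 if 0 <= 40 - s - 28 < 20 else det.ABSENT
            assert targets["W"][s] == expected
        assert np.all(targets["S"] == det.ABSENT)


class TestTraining:
    def test_training_is_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(300, det.ENCODING_LENGTH))
        y = rng.integers(0, 21, size=300)
        targets = {f: y for f in det.FEATURES}
        cfg = det.TrainingConfig(seed=1, max_iter=15, n_iter_no_change=5)
        a = det.train_detectors(X, targets, cfg)
        b = det.train_detectors(X, targets, cfg)
        assert a.holdout_accuracy == b.holdout_accuracy
        np.testing.assert_array_equal(
            a.detectors["W"].coefs_[0], b.detectors["W"].coefs_[0]
        )

    def test_all_absent_labels_learn_the_constant_function(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(400, det.ENCODING_LENGTH))
        targets = {f: np.full(400, det.ABSENT) for f in det.FEATURES}
        bank = det.train_detectors(
            X, targets, det.TrainingConfig(seed=0, max_iter=10, n_iter_no_change=3)
        )
        assert bank.holdout_accuracy["W"] >= 0.99
        assert any("positive" in w for w in bank.warnings)

    def test_too_few_windows_rejected(self):
        X = np.zeros((50, det.ENCODING_LENGTH))
        targets = {f: np.zeros(50, int) for f in det.FEATURES}
        with pytest.raises(det.DetectorError):
            det.train_detectors(X, targets)


class TestDetect:
    def test_exactly_six_candidates_per_window(self, clean_bank, clean_recording):
        rec, _ = clean_recording
        from ppgnorm.signal_io import sliding_windows

        cands = det.detect(sliding_windows(rec)[500], clean_bank)
        assert len(cands) == 6
        assert {c.feature for c in cands} == set(det.FEATURES)
        assert all(0.0 <= c.confidence <= 1.0 for c in cands)

    def test_clean_windows_have_w_near_truth(self, clean_bank, clean_recording):
        rec, truth = clean_recording
        res = det.detect_record(rec, clean_bank)
        starts, cls, _ = res["W"]
        targets = det.window_targets(starts, truth.feature_positions())["W"]
        positive = targets != det.ABSENT
        near = np.abs(cls[positive] - targets[positive]) <= 1
        assert near.mean() >= 0.95

    def test_serialization_roundtrip_preserves_predictions(
        self, clean_bank, clean_recording, tmp_path
    ):
        rec, _ = clean_recording
        path = tmp_path / "bank.json"
        det.save_detectors(clean_bank, path)
        back = det.load_detectors(path)
        assert back.holdout_accuracy == clean_bank.holdout_accuracy
        X, _ = det.encode_record(rec)
        for f in det.FEATURES:
            p1 = clean_bank.detectors[f].predict_proba(X[:200])
            p2 = back.detectors[f].predict_proba(X[:200])
            np.testing.assert_allclose(p1, p2, atol=1e-12)


@pytest.fixture(scope="module")
def dropout_recordings():
    out = []
    for s in (78, 79):
        profile = syn.draw_subject_profile("group1", np.random.default_rng(s))
        out.append(syn.generate_recording(profile, 40.0, (0.0, 0.15), seed=s))
    return out


class TestNoiseDetection:
    def test_dropout_boundaries_fire_the_noise_detectors(
        self, mixed_bank, dropout_recordings
    ):
        hit = tot = 0
        for rec, truth in dropout_recordings:
            res = det.detect_record(rec, mixed_bank)
            pos = truth.feature_positions()
            for f in ("noise_start", "noise_end"):
                starts, cls, _ = res[f]
                for p in pos[f]:
                    covering = (starts + det.CENTRAL_START <= p) & (
                        p < starts + det.CENTRAL_START + det.DECODE_BINS
                    )
                    if not covering.any():
                        continue
                    tot += 1
                    hit += (cls[covering] != det.ABSENT).mean() >= 0.5
        assert tot >= 10
        assert hit / tot >= 0.80

    def test_fiducials_absent_inside_dropouts(self, mixed_bank, dropout_recordings):
        rates = []
        for rec, truth in dropout_recordings:
            res = det.detect_record(rec, mixed_bank)
            starts = res["W"][0]
            inside = np.zeros(len(starts), bool)
            for s, e in truth.noise_intervals:
                inside |= (starts + det.CENTRAL_START >= s) & (
                    starts + det.CENTRAL_START + det.DECODE_BINS <= e
                )
            for f in ("O", "S", "W", "Z"):
                rates.append((res[f][1][inside] == det.ABSENT).mean())
        assert np.mean(rates) >= 0.90

    def test_detected_intervals_cover_true_dropouts(self, mixed_bank, dropout_recordings):
        for rec, truth in dropout_recordings:
            pts = det.detect_and_reconcile(rec, mixed_bank)
            lo, hi = det.coverable_region(rec.n_samples)
            for s, e in truth.noise_intervals:
                s, e = max(s, lo), min(e, hi)
                mid = (s + e) // 2
                assert any(a <= mid < b for a, b in pts.noise_intervals)


class TestOracle:
    def test_matches_ground_truth_on_clean_recordings(self):
        totals = {"W": [0, 0], "S": [0, 0], "O": [0, 0], "Z": [0, 0]}
        tol = {"W": 1, "S": 1, "O": 2, "Z": 2}
        for seed, group in [(3, "group1"), (11, "group2"), (42, "group1"), (7, "group2")]:
            profile = syn.draw_subject_profile(group, np.random.default_rng(seed))
            rec, truth = syn.generate_recording(profile, 40.0, seed=seed + 100)
            pts = det.oracle_detect(rec)
            for f in totals:
                tp = np.array([getattr(b, f) for b in truth.beats
                               if getattr(b, f) is not None])
                op = np.array([getattr(b, f) for b in pts.beats
                               if getattr(b, f) is not None])
                if len(tp) == 0 or len(op) == 0:
                    continue
                totals[f][0] += sum(1 for t in tp if np.min(np.abs(op - t)) <= tol[f])
                totals[f][1] += len(tp)
        for f in ("W", "S", "O"):
            assert totals[f][0] / totals[f][1] >= 0.99, f
        assert totals["Z"][0] / totals["Z"][1] >= 0.95

    def test_constant_record_has_no_beats(self):
        with pytest.raises(det.DetectorError, match="no beats"):
            det.oracle_detect(PPGRecord(np.full(2000, 3.0), 62.5))

    def test_single_beat_record(self):
        w, _ = syn.generate_beat(syn.BeatTemplateParams(beat_duration=1.2))
        pts = det.oracle_detect(PPGRecord(w, 62.5))
        assert len(pts.beats) == 1
        b = pts.beats[0]
        assert b.O <= b.W <= b.S


class TestReconcile:
    def _perfect_candidates(self, rec, truth):
        _, starts = det.encode_record(rec)
        targets = det.window_targets(starts, truth.feature_positions())
        return {f: (starts, targets[f], np.ones(len(starts))) for f in det.FEATURES}

    def test_perfect_votes_reproduce_the_truth(self, clean_recording):
        rec, truth = clean_recording
        pts = det.reconcile(self._perfect_candidates(rec, truth), rec.n_samples)
        lo, hi = det.coverable_region(rec.n_samples)
        expected = [b for b in truth.beats if lo <= b.W < hi]
        assert list(pts.w_points) == [b.W for b in expected]
        by_w = {b.W: b for b in pts.beats}
        for b in expected:
            got = by_w[b.W]
            assert got.O == b.O and got.S == b.S

    def test_single_spurious_vote_is_discarded(self):
        n = 400
        starts = np.arange(n - 74)
        cls = np.full(len(starts), det.ABSENT)
        true_w = 200
        covering = (starts + det.CENTRAL_START <= true_w) & (
            true_w < starts + det.CENTRAL_START + det.DECODE_BINS
        )
        cls[covering] = true_w - starts[covering] - det.CENTRAL_START
        # one window votes elsewhere
        idx = np.flatnonzero(covering)[0]
        cls[idx] = 5
        cands = {f: (starts, np.full(len(starts), det.ABSENT), np.ones(len(starts)))
                 for f in det.FEATURES}
        cands["W"] = (starts, cls, np.ones(len(starts)))
        pts = det.reconcile(cands, n)
        assert list(pts.w_points) == [true_w]

    def test_heart_rate_constraint_keeps_the_stronger_w(self):
        n = 500
        starts = np.arange(n - 74)
        cls = np.full(len(starts), det.ABSENT)
        conf = np.ones(len(starts))
        # full support at 200, weaker support at 212 (0.19 s later)
        for w, share in ((200, 1.0), (212, 0.6)):
            covering = np.flatnonzero(
                (starts + det.CENTRAL_START <= w)
                & (w < starts + det.CENTRAL_START + det.DECODE_BINS)
            )
            take = covering[: int(share * len(covering))]
            cls[take] = w - starts[take] - det.CENTRAL_START
        cands = {f: (starts, np.full(len(starts), det.ABSENT), conf) for f in det.FEATURES}
        cands["W"] = (starts, cls, conf)
        pts = det.reconcile(cands, n)
        assert 200 in pts.w_points
        assert 212 not in pts.w_points

    def test_empty_input_rejected(self):
        with pytest.raises(det.DetectorError):
            det.reconcile({}, 100)

    @settings(max_examples=25)
    @given(st.data())
    def test_output_always_ordered_and_rate_constrained(self, data):
        n = 600
        starts = np.arange(n - 74)
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        cands = {}
        for f in det.FEATURES:
            cls = np.full(len(starts), det.ABSENT)
            for _ in range(rng.integers(0, 6)):
                w = int(rng.integers(0, len(starts)))
                run = slice(w, min(w + int(rng.integers(1, 25)), len(starts)))
                cls[run] = rng.integers(0, det.DECODE_BINS)
            cands[f] = (starts, cls, rng.uniform(0.5, 1.0, len(starts)))
        pts = det.reconcile(cands, n)
        ws = list(pts.w_points)
        assert all(b - a >= 25 for a, b in zip(ws, ws[1:]))
        for b in pts.beats:
            present = [p for p in (b.O, b.W, b.S, b.Z) if p is not None]
            assert all(x <= y for x, y in zip(present, present[1:]))
        for s, e in pts.noise_intervals:
            assert 0 <= s < e <= n
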