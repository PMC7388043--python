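"""Postprocessing rules, epoch grouping, detection matching."""

import numpy as np
import pytest

from nightcough.segmentation import (CoughDetection, ProbabilitySeries,
                                     derive_epochs, match_detections,
                                     postprocess)
from nightcough.audio_io import LabelEvent, LabelTrack

STRIDE = 0.065
WINDOW = 0.650


def _series(probs, stride=STRIDE, silent=None):
    probs = np.asarray(probs, dtype=float)
    times = np.arange(probs.size) * stride
    if silent is None:
        silent = probs == 0.0
    return ProbabilitySeries(times, probs, np.asarray(silent, bool),
                             stride=stride, window=WINDOW)


def brute_force_rules(probs, t, stride=STRIDE, window=WINDOW):
    """Literal scan of the three postprocessing rules (independent oracle)."""
    above = [p >= t for p in probs]
    coughs = []
    i, n = 0, len(probs)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        length = j - i + 1
        center = lambda a, b: (a * stride + b * stride + window) / 2
        if length == 1:
            if i + 1 < n and (probs[i] + probs[i + 1]) / 2 > 0.9:
                coughs.append(center(i, i))
        elif length <= 8:
            coughs.append(center(i, j))
        else:
            mid = i + length // 2
            coughs.append(center(i, mid - 1))
            coughs.append(center(mid, j))
        i = j + 1
    return coughs


class TestPostprocess:
    def test_run_of_nine_yields_two_coughs(self):
        probs = [0.1] + [0.99] * 9 + [0.1]
        dets = postprocess(_series(probs), 0.95)
        assert len(dets) == 2
        assert all(d.rule == "long-run-split" for d in dets)

    def test_isolated_single_with_high_lookahead_mean_is_one_cough(self):
        probs = [0.1, 0.96, 0.88, 0.1]
        dets = postprocess(_series(probs), 0.95)
        assert len(dets) == 1
        assert dets[0].rule == "single-lookahead"

    def test_isolated_single_with_low_lookahead_mean_is_no_cough(self):
        probs = [0.1, 0.96, 0.80, 0.1]
        assert postprocess(_series(probs), 0.95) == []

    def test_isolated_single_at_series_end_is_no_cough(self):
        probs = [0.1, 0.1, 0.96]
        assert postprocess(_series(probs), 0.95) == []

    def test_short_run_is_one_cough_at_run_centre(self):
        probs = [0.0, 0.97, 0.98, 0.99, 0.0]
        dets = postprocess(_series(probs), 0.95)
        assert len(dets) == 1
        # run covers [1*stride, 3*stride + window]
        assert dets[0].time == pytest.approx((STRIDE + 3 * STRIDE + WINDOW) / 2)

    def test_matches_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 60))
            probs = np.round(rng.uniform(0, 1, n), 3)
            t = float(rng.uniform(0.5, 0.99))
            dets = postprocess(_series(probs), t)
            oracle = brute_force_rules(list(probs), t)
            assert [pytest.approx(x) for x in oracle] == [d.time for d in dets]

    def test_trailing_silent_windows_do_not_change_output(self):
        rng = np.random.default_rng(3)
        probs = list(np.round(rng.uniform(0, 1, 30), 3))
        base = postprocess(_series(probs), 0.8)
        extended = postprocess(_series(probs + [0.0] * 10), 0.8)
        assert [d.time for d in base] == [d.time for d in extended]

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            postprocess(_series([0.5]), 0.4)

    def test_nonuniform_stride_rejected(self):
        with pytest.raises(ValueError):
            ProbabilitySeries(np.array([0.0, 0.065, 0.2]),
                              np.zeros(3), np.zeros(3, bool), stride=0.065)


class TestSlideAndScore:
    @pytest.fixture(scope="class")
    def tiny_ensemble(self):
        """Untrained 5-member ensemble (deterministic random weights)."""
        from nightcough.features import FeatureConfig
        from nightcough.nn import ArchitectureSpec, CnnClassifier
        from nightcough.recognition import EnsembleModel

        arch = ArchitectureSpec(channels=(3, 4, 4, 5, 5),
                                kernels=((1, 3), (3, 1), (3, 3), (3, 3), (3, 3)))
        members = [CnnClassifier(arch, input_shape=(80, 122), seed=i)
                   for i in range(5)]
        return EnsembleModel(members, 0.6, FeatureConfig())

    def test_ten_second_recording_has_144_windows(self, tiny_ensemble):
        from nightcough.audio_io import AudioSegment
        from nightcough.segmentation import slide_and_score

        audio = AudioSegment(np.zeros(10 * 22_050), 22_050)
        series = slide_and_score(audio, tiny_ensemble)
        assert len(series) == 144  # 1 + floor((10.0 - 0.65) / 0.065)

    def test_digitally_silent_recording_all_flagged(self, tiny_ensemble):
        from nightcough.audio_io import AudioSegment
        from nightcough.segmentation import slide_and_score

        audio = AudioSegment(np.zeros(5 * 22_050), 22_050)
        series = slide_and_score(audio, tiny_ensemble)
        assert np.all(series.silent)
        assert np.all(series.probabilities == 0.0)

    def test_chunked_processing_equals_whole(self, tiny_ensemble):
        # chunked-vs-whole equivalence: windows on the shared stride grid
        # must score identically whether the recording is processed whole or
        # in two window-aligned overlapping chunks
        from nightcough.audio_io import AudioSegment
        from nightcough.segmentation import slide_and_score

        sr = 22_050
        rng = np.random.default_rng(0)
        x = np.zeros(8 * sr)
        for onset in (1.0, 3.5, 6.2):  # loud bursts well above the dB filter
            i = int(onset * sr)
            x[i:i + 2000] = rng.uniform(-0.5, 0.5, 2000)
        audio = AudioSegment(x, sr)
        whole = slide_and_score(audio, tiny_ensemble)

        hop = int(round(0.065 * sr))
        wlen = tiny_ensemble.feature_config.window_samples
        cut = 60 * hop  # chunk boundary on the stride grid
        first = AudioSegment(x[:cut + wlen - 1 + hop], sr, 0.0)
        second = AudioSegment(x[cut:], sr, cut / sr)
        s1 = slide_and_score(first, tiny_ensemble)
        s2 = slide_and_score(second, tiny_ensemble)
        stitched = np.concatenate([s1.probabilities[:60], s2.probabilities])
        times = np.concatenate([s1.times[:60], s2.times])
        assert np.allclose(times, whole.times[:times.size], atol=1e-9)
        assert np.allclose(stitched, whole.probabilities[:stitched.size],
                           atol=1e-6)


def brute_force_epochs(times, pause=2.0):
    """Gap-grouping oracle: all maximal groups with every gap < pause."""
    groups, current = [], []
    for t in times:
        if current and t - current[-1] >= pause:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return [g for g in groups if len(g) >= 2]


class TestDeriveEpochs:
    def test_three_close_coughs_one_epoch(self):
        epochs, n, coughs_in = derive_epochs([10.0, 11.0, 12.5])
        assert n == 1 and coughs_in == 3
        assert epochs[0].start == 10.0 and epochs[0].end == 12.5

    def test_single_cough_is_no_epoch(self):
        _, n, coughs_in = derive_epochs([5.0])
        assert n == 0 and coughs_in == 0

    def test_gap_exactly_two_seconds_splits(self):
        epochs, n, coughs_in = derive_epochs([0.0, 1.9, 4.0])
        assert n == 1 and coughs_in == 2
        assert epochs[0].times == (0.0, 1.9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            times = np.sort(rng.uniform(0, 60, rng.integers(0, 25)))
            epochs, n, coughs_in = derive_epochs(list(times))
            oracle = brute_force_epochs(list(times))
            assert n == len(oracle)
            assert [list(e.times) for e in epochs] == oracle
            assert coughs_in == sum(len(g) for g in oracle)

    def test_counting_invariants(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            times = np.sort(rng.uniform(0, 100, rng.integers(0, 30)))
            _, n, coughs_in = derive_epochs(list(times))
            assert coughs_in <= times.size
            assert n <= times.size // 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            derive_epochs([3.0, 1.0])


def _det(t):
    return CoughDetection(time=t, run_length=2, rule="run")


class TestMatchDetections:
    def _track(self, spans):
        return LabelTrack([LabelEvent(a, b, "cough") for a, b in spans])

    def test_perfect_predictions(self):
        spans = [(1.0, 1.4), (5.0, 5.3), (9.0, 9.5)]
        preds = [_det(1.2), _det(5.15), _det(9.25)]
        res = match_detections(preds, self._track(spans), tolerance=0.5)
        c = res["counts"]
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_spurious_prediction_is_false_positive(self):
        res = match_detections([_det(30.0)], self._track([(1.0, 1.4)]), 0.5)
        assert res["counts"].fp == 1 and res["counts"].fn == 1

    def test_greedy_matching_one_to_one(self):
        # two predictions near one annotation: only one matches
        res = match_detections([_det(1.1), _det(1.3)], self._track([(1.0, 1.4)]), 0.5)
        c = res["counts"]
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_greedy_equals_optimal_for_separated_events(self):
        # bipartite-matching oracle: with events separated by > 2*tolerance
        # and jitter < tolerance/2, greedy matching is optimal
        rng = np.random.default_rng(11)
        from scipy.optimize import linear_sum_assignment
        tol = 0.5
        for _ in range(50):
            n = int(rng.integers(1, 12))
            onsets = np.cumsum(rng.uniform(2 * tol + 0.6, 5.0, n)) + 1.0
            spans = [(o, o + 0.3) for o in onsets]
            preds = [_det(o + 0.15 + rng.uniform(-tol / 2, tol / 2))
                     for o in onsets]
            res = match_detections(preds, self._track(spans), tol)
            # optimal assignment via Hungarian on the feasibility matrix
            cost = np.ones((n, n))
            for i, d in enumerate(preds):
                for j, (a, b) in enumerate(spans):
                    if a - tol <= d.time <= b + tol:
                        cost[i, j] = 0
            ri, ci = linear_sum_assignment(cost)
            optimal_tp = int(np.sum(cost[ri, ci] == 0))
            assert res["counts"].tp == optimal_tp

    def test_epoch_detected_via_one_matched_member(self):
        # annotated epoch of 3; predictions hit only one member but form a
        # predicted epoch with a nearby false positive
        spans = [(10.0, 10.3), (11.0, 11.3), (12.0, 12.3)]
        preds = [_det(10.15), _det(11.7)]
        res = match_detections(preds, self._track(spans), 0.2)
        assert res["annotated_epochs"] == 1
        assert res["detected_epochs"] == 1

    def test_matched_prediction_outside_any_epoch_does_not_detect_epoch(self):
        spans = [(10.0, 10.3), (11.0, 11.3)]
        preds = [_det(10.15)]  # singleton prediction: not in a predicted epoch
        res = match_detections(preds, self._track(spans), 0.2)
        assert res["annotated_epochs"] == 1
        assert res["detected_epochs"] == 0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], self._track([(0.0, 1.0)]), -0.1)
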