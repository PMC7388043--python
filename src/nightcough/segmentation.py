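"""Cough segmentation from continuous audio, epoch derivation and matching.

Continuous recordings are scanned with 650 ms windows starting every 65 ms.
Windows whose level stays below -26 dBFS are discarded by the dB filter
(carried as probability 0 with a silent flag); the remaining windows are
scored by the trained ensemble.  The probability sequence becomes cough
detections through three postprocessing rules:

1. only *consecutive* above-threshold probabilities count as a cough
   (a run of 2..8 above-threshold windows is one cough, at the run centre);
2. an isolated single above-threshold probability p_i still counts as a
   cough when mean(p_i, p_{i+1}) > 0.9;
3. a run longer than 8 consecutive detections is recognised as two coughs
   (one at the centre of each half of the run).

Cough epochs are maximal groups of two or more coughs in which every
consecutive gap is shorter than 2 seconds; singleton coughs are not epochs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .audio_io import AudioSegment, LabelTrack
from .evaluation import ConfusionCounts
from .features import mel_spectrogram
from .nn import CnnClassifier
from .recognition import EnsembleModel

__all__ = [
    "ProbabilitySeries",
    "CoughDetection",
    "CoughEpoch",
    "slide_and_score",
    "postprocess",
    "tune_segmentation_threshold",
    "derive_epochs",
    "match_detections",
    "segment_recording",
    "DEFAULT_STRIDE",
    "SILENCE_THRESHOLD_DB",
]

DEFAULT_STRIDE = 0.065
SILENCE_THRESHOLD_DB = -26.0


@dataclasses.dataclass(frozen=True)
class ProbabilitySeries:
    """Ensemble cough probabilities on a uniform window grid.

    ``times`` are window start times (strictly increasing, constant stride);
    silent (dB-filtered) windows carry probability 0 and ``silent=True``.
    """

    times: np.ndarray
    probabilities: np.ndarray
    silent: np.ndarray
    stride: float
    window: float = 0.650

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        s = np.asarray(self.silent, dtype=bool)
        if not (t.shape == p.shape == s.shape):
            raise ValueError("times/probabilities/silent must share a shape")
        if t.size > 1:
            d = np.diff(t)
            if np.any(d <= 0) or np.max(np.abs(d - self.stride)) > 1e-6:
                raise ValueError("times must increase with a constant stride")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "silent", s)

    def __len__(self) -> int:
        return self.times.size


@dataclasses.dataclass(frozen=True)
class CoughDetection:
    """One detected cough: centre time of its detection run."""

    time: float
    run_length: int
    rule: str  # "run" | "single-lookahead" | "long-run-split"

    def __post_init__(self):
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


@dataclasses.dataclass(frozen=True)
class CoughEpoch:
    """Two or more coughs with every consecutive gap under the 2 s pause."""

    times: tuple
    start: float
    end: float

    @property
    def size(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# scoring

def slide_and_score(
    audio: AudioSegment,
    model: EnsembleModel,
    stride: float = DEFAULT_STRIDE,
    silence_threshold_db: float = SILENCE_THRESHOLD_DB,
    batch: int = 128,
) -> ProbabilitySeries:
    """Score overlapping windows of a recording with the ensemble.

    Windows of ``model.feature_config.window_duration`` start every
    ``stride`` seconds (window count 1 + floor((T - window) / stride)).
    Windows whose whole-window RMS stays below the dB threshold are not
    scored: they carry probability 0 and are flagged silent.
    """
    cfg = model.feature_config
    sr = audio.sample_rate
    if sr != cfg.sample_rate:
        raise ValueError(
            f"audio rate {sr} does not match feature config rate {cfg.sample_rate}"
        )
    wlen = cfg.window_samples
    hop = int(round(stride * sr))
    n = audio.samples.size
    if n < wlen:
        raise ValueError("audio shorter than one analysis window")
    starts = np.arange(0, n - wlen + 1, hop)

    # dB filter measured as in the annotation-side silence filter: 10 ms RMS
    # frames; a window is silent iff every frame inside it stays below the
    # threshold
    from numpy.lib.stride_tricks import sliding_window_view

    from .audio_io import _frame_rms_db

    frame = max(1, int(round(0.010 * sr)))
    fhop = max(1, frame // 2)
    fdb = _frame_rms_db(audio.samples, frame, fhop)
    fpw = max(1, (wlen - frame) // fhop + 1)
    if fdb.size >= fpw:
        wmax = sliding_window_view(fdb, fpw).max(axis=1)
    else:
        wmax = np.array([fdb.max()])
    k = np.minimum(starts // fhop, wmax.size - 1)
    silent = wmax[k] < silence_threshold_db

    probs = np.zeros(starts.size)
    active = np.flatnonzero(~silent)
    for i in range(0, active.size, batch):
        idx = active[i:i + batch]
        specs = [
            mel_spectrogram(
                AudioSegment(audio.samples[s:s + wlen], sr,
                             audio.start_time + s / sr), cfg)
            for s in starts[idx]
        ]
        probs[idx] = model.predict_proba(CnnClassifier.prepare(specs))
    times = audio.start_time + starts / sr
    return ProbabilitySeries(times, probs, silent, stride=hop / sr,
                             window=wlen / sr)


# ---------------------------------------------------------------------------
# postprocessing rules

def postprocess(series: ProbabilitySeries, threshold: float) -> list[CoughDetection]:
    """Turn a probability series into cough detections via rules 1-3.

    A maximal run of consecutive above-threshold probabilities of length
    2..8 is one cough at the run centre; a run longer than 8 is two coughs
    (centres of its two halves); an isolated single above-threshold
    probability p_i is a cough iff mean(p_i, p_{i+1}) > 0.9 (no following
    window means no cough).  Silent windows carry probability 0 and
    therefore break runs.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0.5, 1), got {threshold}")
    p = series.probabilities
    t = series.times
    above = p >= threshold
    window = series.window
    detections: list[CoughDetection] = []

    def run_center(i0: int, i1: int) -> float:
        # centre of the span covered by windows i0..i1 inclusive
        return (t[i0] + t[i1] + window) / 2.0

    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        length = j - i + 1
        if length == 1:
            if i + 1 < n and (p[i] + p[i + 1]) / 2.0 > 0.9:
                detections.append(CoughDetection(run_center(i, i), 1,
                                                 "single-lookahead"))
        elif length <= 8:
            detections.append(CoughDetection(run_center(i, j), length, "run"))
        else:
            mid = i + length // 2
            detections.append(CoughDetection(run_center(i, mid - 1), length,
                                             "long-run-split"))
            detections.append(CoughDetection(run_center(mid, j), length,
                                             "long-run-split"))
        i = j + 1
    return detections


def tune_segmentation_threshold(
    series_list: Sequence[ProbabilitySeries],
    truth_counts: Sequence[int],
    grid_step: float = 0.01,
) -> float:
    """Calibrate the decision threshold for segmentation on validation nights.

    The window-level MCC grid search can tie over a wide band when validation
    windows are cleanly separated, and the postprocessing rules (notably the
    >8-run split) assume a threshold high enough that one cough does not stay
    above it across more than eight strides.  This refinement re-runs the
    grid over [0.5, 1) on scored validation nights and picks the value whose
    postprocessed cough counts best agree with the annotated counts (total
    absolute count difference; ties resolve to the smallest threshold).
    Scoring is threshold-independent, so each night is scored once.
    """
    if len(series_list) != len(truth_counts) or not series_list:
        raise ValueError("need one truth count per scored night")
    best_t, best_err = 0.5, None
    inv = int(round(1.0 / grid_step))
    grid = np.arange(int(round(0.5 * inv)), inv) / inv
    for t in grid:
        err = sum(abs(len(postprocess(s, float(t))) - c)
                  for s, c in zip(series_list, truth_counts))
        if best_err is None or err < best_err:
            best_t, best_err = float(t), err
    return best_t


# ---------------------------------------------------------------------------
# epochs

def derive_epochs(
    cough_times: Sequence[float], pause: float = 2.0,
) -> tuple[list[CoughEpoch], int, int]:
    """Group cough times into epochs under the 2-second pause rule.

    Maximal groups in which every consecutive gap is strictly less than
    ``pause`` and which hold at least two coughs become epochs.  Returns
    (epochs, epoch count, number of coughs inside epochs).
    """
    times = list(cough_times)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("cough times must be sorted")
    epochs: list[CoughEpoch] = []
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] < pause:
            j += 1
        if j > i:
            members = tuple(times[i:j + 1])
            epochs.append(CoughEpoch(members, members[0], members[-1]))
        i = j + 1
    coughs_in = sum(e.size for e in epochs)
    return epochs, len(epochs), coughs_in


# ---------------------------------------------------------------------------
# matching detections against annotations

def match_detections(
    predicted: Sequence[CoughDetection],
    annotated: LabelTrack,
    tolerance: float = 0.5,
    pause: float = 2.0,
) -> dict:
    """Greedy one-to-one matching of predicted coughs to annotated coughs.

    In time order, each predicted cough matches the earliest unmatched
    annotated cough whose interval, dilated by ``tolerance`` seconds,
    contains the prediction time.  Unmatched predictions are false
    positives; unmatched annotations are false negatives.  An annotated
    epoch counts as detected iff at least one of its coughs is matched by a
    prediction that itself belongs to a predicted epoch.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    events = [e for e in annotated if e.label.split(":", 1)[0] == "cough"]
    preds = sorted(predicted, key=lambda d: d.time)
    matched_ann: dict[int, float] = {}   # annotation index -> prediction time
    matched_pairs: list[tuple[float, int]] = []
    fp = 0
    for d in preds:
        hit = None
        for k, e in enumerate(events):
            if k in matched_ann:
                continue
            if e.start - tolerance <= d.time <= e.end + tolerance:
                hit = k
                break
        if hit is None:
            fp += 1
        else:
            matched_ann[hit] = d.time
            matched_pairs.append((d.time, hit))
    tp = len(matched_ann)
    fn = len(events) - tp

    # epoch-level matching
    ann_times = [e.start + (e.end - e.start) / 2.0 for e in events]
    ann_epochs, _, _ = derive_epochs(sorted(ann_times), pause=pause)
    pred_epochs, _, _ = derive_epochs(sorted(d.time for d in preds), pause=pause)
    in_pred_epoch = {t for ep in pred_epochs for t in ep.times}
    ann_center_to_idx = {c: k for k, c in zip(range(len(events)), ann_times)}
    detected_epochs = 0
    for ep in ann_epochs:
        hit = False
        for c in ep.times:
            k = ann_center_to_idx[c]
            if k in matched_ann and matched_ann[k] in in_pred_epoch:
                hit = True
                break
        if hit:
            detected_epochs += 1
    return {
        "counts": ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0),
        "matched_pairs": matched_pairs,
        "annotated_epochs": len(ann_epochs),
        "predicted_epochs": len(pred_epochs),
        "detected_epochs": detected_epochs,
    }


def segment_recording(
    audio: AudioSegment,
    model: EnsembleModel,
    stride: float = DEFAULT_STRIDE,
    pause: float = 2.0,
) -> dict:
    """Full segmentation of one recording: detections, epochs and counts."""
    series = slide_and_score(audio, model, stride=stride)
    detections = postprocess(series, model.threshold)
    epochs, n_epochs, coughs_in = derive_epochs([d.time for d in detections],
                                                pause=pause)
    return {
        "series": series,
        "detections": detections,
        "epochs": epochs,
        "cough_count": len(detections),
        "epoch_count": n_epochs,
        "coughs_in_epochs": coughs_in,
    }
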