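"""Imbalance-aware ensemble cough/noncough window classification.

The recognizer addresses the extreme rarity of coughs among nocturnal sounds
with three techniques used together:

* **ensemble learning** — the (majority) noncough training windows are split
  into 5 participant-disjunct folds; one CNN is trained per fold, each paired
  with the full cough set, and the ensemble probability is the arithmetic
  mean of the 5 member probabilities;
* **balanced minibatch training** — every minibatch holds equally many cough
  and noncough windows, the minority class being resampled with replacement;
* **decision thresholding** — the 0.5 cutoff is replaced by a threshold t
  found by grid search on [0.5, 1) that maximises the Matthews correlation
  coefficient on a validation set.

A window is declared a cough iff the mean member probability is >= t.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterator, Sequence

import numpy as np

from .audio_io import AudioSegment, LabelTrack
from .evaluation import ConfusionCounts, confusion_metrics
from .features import FeatureConfig, MelSpectrogram, fit_window, mel_spectrogram
from .nn import Adam, ArchitectureSpec, CnnClassifier, DivergenceError

__all__ = [
    "LabeledWindow",
    "TrainingConfig",
    "EnsembleModel",
    "extract_training_windows",
    "windows_from_corpus",
    "make_disjunct_folds",
    "balanced_batches",
    "train_member",
    "train_ensemble",
    "tune_threshold",
    "ensemble_predict",
    "partition_participants",
]


@dataclasses.dataclass(frozen=True)
class LabeledWindow:
    """One 650 ms training window: spectrogram, class label, provenance."""

    spectrogram: MelSpectrogram
    label: str  # "cough" | "noncough"
    participant_id: str
    night_id: str = ""

    def __post_init__(self):
        if self.label not in ("cough", "noncough"):
            raise ValueError(f"label must be cough/noncough, got {self.label!r}")


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one CNN member.

    Minibatch gradient descent with Adam; Xavier-initialised weights;
    dropout rate 0.5.  ``batch_size`` must be even so batches can hold equal
    class halves.
    """

    learning_rate: float = 1e-3
    batch_size: int = 16
    iterations: int = 300
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (balanced class halves)")


class EnsembleModel:
    """Five trained window classifiers plus one decision threshold."""

    def __init__(self, members: Sequence[CnnClassifier], threshold: float,
                 feature_config: FeatureConfig | None = None):
        if len(members) != 5:
            raise ValueError(f"ensemble requires exactly 5 members, got {len(members)}")
        if not 0.5 <= threshold < 1.0:
            raise ValueError(f"threshold must lie in [0.5, 1), got {threshold}")
        self.members = list(members)
        self.threshold = float(threshold)
        self.feature_config = feature_config or FeatureConfig()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Mean member probability for a prepared (N, 1, H, W) batch."""
        return np.mean([m.predict_proba(x) for m in self.members], axis=0)

    def save(self, path) -> None:
        arrays = {}
        for i, m in enumerate(self.members):
            for j, w in enumerate(m.get_weights()):
                arrays[f"member{i}_w{j}"] = w
        meta = json.dumps({
            "threshold": self.threshold,
            "arch": [dataclasses.asdict(m.arch) for m in self.members],
            "input_shape": list(self.members[0].input_shape),
            "seeds": [m.seed for m in self.members],
            "feature_config": self.feature_config.to_dict(),
        })
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            members = []
            for i, arch_d in enumerate(meta["arch"]):
                arch = ArchitectureSpec(
                    channels=tuple(arch_d["channels"]),
                    kernels=tuple(tuple(k) for k in arch_d["kernels"]),
                    dropout_rate=arch_d["dropout_rate"],
                )
                m = CnnClassifier(arch, input_shape=tuple(meta["input_shape"]),
                                  seed=meta["seeds"][i])
                weights = []
                j = 0
                while f"member{i}_w{j}" in data:
                    weights.append(data[f"member{i}_w{j}"])
                    j += 1
                m.set_weights(weights)
                members.append(m)
        return cls(members, meta["threshold"],
                   FeatureConfig.from_dict(meta["feature_config"]))


# ---------------------------------------------------------------------------
# window extraction

def extract_training_windows(
    events: LabelTrack,
    audio: AudioSegment,
    config: FeatureConfig | None = None,
    participant_id: str = "",
    night_id: str = "",
) -> list[LabeledWindow]:
    """Cut labelled events into 650 ms training windows.

    Each noncough event is tiled into floor(duration / 0.65) nonoverlapping
    windows (at least one, zero-padded if the event is shorter).  Each cough
    event yields exactly one window centred on its absolute-amplitude
    maximum.  Uncertain events must have been discarded upstream.
    """
    config = config or FeatureConfig()
    sr = audio.sample_rate
    wlen = config.window_samples
    out: list[LabeledWindow] = []
    for ev in events:
        if ev.label == "uncertain":
            raise ValueError("uncertain events must be discarded before windowing")
        base = ev.label.split(":", 1)[0]
        if base not in ("cough", "noncough"):
            continue
        i0 = int(round((ev.start - audio.start_time) * sr))
        i1 = int(round((ev.end - audio.start_time) * sr))
        if i0 < 0 or i1 > audio.samples.size:
            raise ValueError(f"event [{ev.start}, {ev.end}) outside audio bounds")
        span = audio.samples[i0:i1]
        if base == "cough":
            m = i0 + int(np.argmax(np.abs(span)))
            c0 = m - wlen // 2
            window = np.zeros(wlen)
            lo, hi = max(c0, 0), min(c0 + wlen, audio.samples.size)
            window[lo - c0:hi - c0] = audio.samples[lo:hi]
            seg = AudioSegment(window, sr, audio.start_time + c0 / sr)
            out.append(LabeledWindow(mel_spectrogram(seg, config), "cough",
                                     participant_id, night_id))
        else:
            n_windows = max(1, span.size // wlen)
            for k in range(n_windows):
                chunk = span[k * wlen:(k + 1) * wlen]
                seg = fit_window(
                    AudioSegment(chunk, sr, ev.start + k * wlen / sr), config
                )
                out.append(LabeledWindow(mel_spectrogram(seg, config), "noncough",
                                         participant_id, night_id))
    return out


def windows_from_corpus(corpus, config: FeatureConfig | None = None) -> list[LabeledWindow]:
    """Turn a list of isolated CorpusEvents into labelled windows."""
    config = config or FeatureConfig()
    out = []
    for ev in corpus:
        track = LabelTrack([_corpus_label_event(ev)])
        out.extend(extract_training_windows(track, ev.audio, config,
                                            participant_id=ev.participant_id))
    return out


def _corpus_label_event(ev):
    from .audio_io import LabelEvent
    return LabelEvent(0.0, ev.audio.duration, ev.label)


# ---------------------------------------------------------------------------
# folds and batches

def make_disjunct_folds(
    windows: Sequence[LabeledWindow], n_folds: int = 5, seed: int = 0,
) -> list[list[LabeledWindow]]:
    """Split windows into participant-disjunct folds of the noncough class.

    Noncough windows are partitioned by participant into ``n_folds`` groups
    of near-equal window counts (greedy balancing: participants in shuffled
    order, largest-first, each assigned to the currently smallest fold);
    every fold is paired with the full cough set.
    """
    coughs = [w for w in windows if w.label == "cough"]
    noncoughs = [w for w in windows if w.label == "noncough"]
    by_participant: dict[str, list[LabeledWindow]] = {}
    for w in noncoughs:
        by_participant.setdefault(w.participant_id, []).append(w)
    if len(by_participant) < n_folds:
        raise ValueError(
            f"need at least {n_folds} noncough participants, got {len(by_participant)}"
        )
    rng = np.random.default_rng(seed)
    pids = list(by_participant)
    rng.shuffle(pids)
    pids.sort(key=lambda p: len(by_participant[p]), reverse=True)
    fold_pids: list[list[str]] = [[] for _ in range(n_folds)]
    fold_sizes = [0] * n_folds
    for pid in pids:
        i = int(np.argmin(fold_sizes))
        fold_pids[i].append(pid)
        fold_sizes[i] += len(by_participant[pid])
    return [
        coughs + [w for pid in fp for w in by_participant[pid]]
        for fp in fold_pids
    ]


def balanced_batches(
    fold: Sequence[LabeledWindow], batch_size: int, seed: int = 0,
) -> Iterator[list[LabeledWindow]]:
    """One balanced epoch over a fold: every batch is half cough, half noncough.

    The majority class is traversed once in shuffled order, ``batch_size/2``
    windows at a time; the minority class is sampled with replacement to fill
    the other half.  Yields floor(n_majority / (batch_size/2)) batches.
    """
    if batch_size % 2:
        raise ValueError("batch_size must be even")
    half = batch_size // 2
    coughs = [w for w in fold if w.label == "cough"]
    noncoughs = [w for w in fold if w.label == "noncough"]
    if not coughs or not noncoughs:
        raise ValueError("both classes must be present in the fold")
    major, minor = (noncoughs, coughs) if len(noncoughs) >= len(coughs) else (coughs, noncoughs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(major))
    for b in range(len(major) // half):
        batch = [major[i] for i in order[b * half:(b + 1) * half]]
        batch += [minor[i] for i in rng.integers(len(minor), size=half)]
        yield batch


def _endless_batches(fold, batch_size, seed):
    epoch = 0
    while True:
        yield from balanced_batches(fold, batch_size, seed=seed + epoch)
        epoch += 1


# ---------------------------------------------------------------------------
# training

def train_member(
    fold: Sequence[LabeledWindow],
    config: TrainingConfig | None = None,
    arch: ArchitectureSpec | None = None,
    input_shape: tuple | None = None,
) -> CnnClassifier:
    """Train one CNN member on a fold with balanced minibatches and Adam."""
    config = config or TrainingConfig()
    if not fold:
        raise ValueError("fold is empty")
    if input_shape is None:
        input_shape = fold[0].spectrogram.shape
    if arch is not None and arch.dropout_rate != config.dropout_rate:
        arch = dataclasses.replace(arch, dropout_rate=config.dropout_rate)
    model = CnnClassifier(arch, input_shape=input_shape, seed=config.seed)
    optimizer = Adam(lr=config.learning_rate)
    batches = _endless_batches(fold, config.batch_size, config.seed)
    for it in range(config.iterations):
        batch = next(batches)
        x = CnnClassifier.prepare([w.spectrogram for w in batch])
        y = np.array([1.0 if w.label == "cough" else 0.0 for w in batch])
        loss = model.train_step(x, y, optimizer)
        if not np.isfinite(loss):
            raise DivergenceError(it)
    return model


def train_ensemble(
    windows: Sequence[LabeledWindow],
    config: TrainingConfig | None = None,
    arch: ArchitectureSpec | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[CnnClassifier]:
    """Train the 5 members on participant-disjunct noncough folds."""
    config = config or TrainingConfig(seed=seed)
    folds = make_disjunct_folds(windows, n_folds=n_folds, seed=seed)
    members = []
    for i, fold in enumerate(folds):
        member_cfg = dataclasses.replace(config, seed=config.seed + 101 * i)
        members.append(train_member(fold, member_cfg, arch=arch))
    return members


# ---------------------------------------------------------------------------
# thresholding and prediction

def _mean_member_proba(models, windows, batch: int = 256) -> np.ndarray:
    specs = [w.spectrogram for w in windows]
    probs = np.zeros(len(specs))
    for i in range(0, len(specs), batch):
        x = CnnClassifier.prepare(specs[i:i + batch])
        probs[i:i + batch] = np.mean([m.predict_proba(x) for m in models], axis=0)
    return probs


def tune_threshold(
    models: Sequence[CnnClassifier],
    validation: Sequence[LabeledWindow],
    grid_step: float = 0.01,
) -> float:
    """Grid-search the ensemble decision threshold on [0.5, 1).

    Returns the grid value maximising the Matthews correlation coefficient
    of the mean-probability decision on the validation set; ties resolve to
    the smallest threshold.  Grid values whose MCC is undefined rank below
    every defined value.
    """
    labels = np.array([w.label == "cough" for w in validation])
    if labels.all() or not labels.any():
        raise ValueError("validation set must contain both classes")
    probs = _mean_member_proba(models, validation)
    best_t, best_mcc = None, -np.inf
    inv = int(round(1.0 / grid_step))
    grid = np.arange(int(round(0.5 * inv)), inv) / inv
    for t in grid:
        pred = probs >= t
        c = ConfusionCounts(
            tp=int(np.sum(pred & labels)), fp=int(np.sum(pred & ~labels)),
            fn=int(np.sum(~pred & labels)), tn=int(np.sum(~pred & ~labels)),
        )
        mcc = confusion_metrics(c)["mcc"]
        if mcc is not None and mcc > best_mcc:
            best_t, best_mcc = float(t), mcc
    if best_t is None:
        raise ValueError("MCC undefined at every grid value")
    return best_t


def ensemble_predict(model: EnsembleModel, x: MelSpectrogram) -> tuple[float, bool]:
    """Score one window: (mean member probability, cough decision)."""
    p = float(model.predict_proba(CnnClassifier.prepare([x]))[0])
    return p, p >= model.threshold


# ---------------------------------------------------------------------------
# participant-level dataset partitioning

def partition_participants(
    participant_ids: Sequence[str],
    seed: int = 0,
    fractions: tuple = (0.65, 0.15, 0.20),
) -> tuple[list[str], list[str], list[str]]:
    """Random participant-disjunct train/validation/test split (65:15:20).

    The test share is drawn first, then the validation share from the
    remainder, mirroring how the recording corpus was partitioned; counts
    are rounded to the nearest participant.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    pids = sorted(set(participant_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(pids)
    n = len(pids)
    n_test = max(1, int(round(fractions[2] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    test = pids[:n_test]
    val = pids[n_test:n_test + n_val]
    train = pids[n_test + n_val:]
    if not train:
        raise ValueError("too few participants to split")
    return sorted(train), sorted(val), sorted(test)
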