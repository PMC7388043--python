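"""Audio and annotation I/O, plus the amplitude-threshold silence filter.

The package works with mono PCM recordings and Audacity-style label tracks
(tab-separated ``start end label`` rows, times in seconds).  Silence marking
mirrors the Sound Finder workflow used to pre-segment overnight recordings
before human annotation: stretches whose level stays below a dB threshold for
at least a minimum duration are labelled silence, everything else is sound.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioSegment",
    "LabelEvent",
    "LabelTrack",
    "AudioFormatError",
    "LabelParseError",
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "mark_silence",
    "rms_dbfs",
]

_DB_FLOOR = -200.0


class AudioFormatError(ValueError):
    """Raised for unreadable or unsupported audio input."""


class LabelParseError(ValueError):
    """Raised when a label-track row cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclasses.dataclass(frozen=True)
class AudioSegment:
    """Mono waveform with its sample rate and absolute start time.

    Samples are float64 in [-1, 1]; ``start_time`` is seconds from the start
    of the recording the segment was cut from (0.0 for whole recordings).
    """

    samples: np.ndarray
    sample_rate: int
    start_time: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioFormatError("AudioSegment requires a 1-D (mono) signal")
        if self.sample_rate <= 0:
            raise AudioFormatError("sample_rate must be positive")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise AudioFormatError("samples must lie in [-1, 1]")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def slice(self, start: float, end: float) -> "AudioSegment":
        """Cut [start, end) seconds (relative to the recording) from the segment."""
        i0 = int(round((start - self.start_time) * self.sample_rate))
        i1 = int(round((end - self.start_time) * self.sample_rate))
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise ValueError(f"slice [{start}, {end}) outside segment bounds")
        return AudioSegment(self.samples[i0:i1], self.sample_rate, start)


@dataclasses.dataclass(frozen=True)
class LabelEvent:
    start: float
    end: float
    label: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"event start {self.start} must precede end {self.end}")


class LabelTrack:
    """Ordered list of annotated acoustic events.

    Labels are free strings; the pipeline uses ``cough``, ``noncough`` (or
    ``noncough:<kind>``), ``uncertain`` and ``silence``/``sound``.  Events are
    kept sorted by start time.
    """

    def __init__(self, events: Iterable[LabelEvent] = ()):
        self.events: list[LabelEvent] = sorted(events, key=lambda e: (e.start, e.end))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelTrack) and self.events == other.events

    def __repr__(self) -> str:
        return f"LabelTrack({len(self.events)} events)"

    def with_label(self, *labels: str) -> "LabelTrack":
        """Sub-track of events whose label (or its ``:``-prefix) is in *labels*."""
        keep = [
            e for e in self.events
            if e.label in labels or e.label.split(":", 1)[0] in labels
        ]
        return LabelTrack(keep)

    def drop_uncertain(self) -> "LabelTrack":
        return LabelTrack(e for e in self.events if e.label != "uncertain")


def read_wav(path, *, downmix: bool = False) -> AudioSegment:
    """Read a WAV file (PCM 8/16/32-bit or float32/64) into an AudioSegment.

    Stereo input is rejected unless ``downmix=True``, in which case channels
    are averaged.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise AudioFormatError(f"missing or empty audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise AudioFormatError(f"unsupported WAV encoding in {path}: {exc}") from exc
    if data.ndim == 2:
        if not downmix:
            raise AudioFormatError(
                f"{path} has {data.shape[1]} channels; pass downmix=True to average"
            )
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32 / float64
        samples = data.astype(np.float64)
    samples = np.clip(samples, -1.0, 1.0)
    return AudioSegment(samples, int(rate))


def write_wav(path, audio: AudioSegment, *, dtype: str = "int16") -> None:
    """Write an AudioSegment as PCM 16-bit (default) or float32 WAV."""
    path = Path(path)
    if dtype == "int16":
        data = np.clip(np.round(audio.samples * 32767.0), -32768, 32767).astype(np.int16)
    elif dtype == "float32":
        data = audio.samples.astype(np.float32)
    else:
        raise AudioFormatError(f"unsupported output dtype {dtype!r}")
    wavfile.write(path, audio.sample_rate, data)


def read_labels(path) -> LabelTrack:
    """Parse an Audacity label-track TSV into a LabelTrack (sorted by start)."""
    events = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise LabelParseError(
                    f"expected 3 tab-separated fields, got {len(parts)}", lineno
                )
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError:
                raise LabelParseError(f"unparseable time in {line!r}", lineno) from None
            if end <= start:
                raise LabelParseError(f"end {end} <= start {start}", lineno)
            events.append(LabelEvent(start, end, parts[2]))
    return LabelTrack(events)


def write_labels(path, track: LabelTrack) -> None:
    """Write a LabelTrack as TSV with 6-decimal times."""
    with open(path, "w") as fh:
        for e in track:
            fh.write(f"{e.start:.6f}\t{e.end:.6f}\t{e.label}\n")


def rms_dbfs(x: np.ndarray) -> float:
    """RMS level of a signal in dB relative to digital full scale."""
    rms = float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0
    if rms <= 0.0:
        return _DB_FLOOR
    return max(20.0 * np.log10(rms), _DB_FLOOR)


def _frame_rms_db(samples: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """dBFS of RMS frames on a hop grid; the tail is padded with zeros."""
    n = samples.size
    n_frames = max(1, int(np.ceil(n / hop)))
    padded = np.zeros(n_frames * hop + frame, dtype=np.float64)
    padded[:n] = samples
    sq = np.concatenate(([0.0], np.cumsum(np.square(padded))))
    starts = np.arange(n_frames) * hop
    energy = sq[starts + frame] - sq[starts]
    rms = np.sqrt(energy / frame)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    return np.maximum(db, _DB_FLOOR)


def mark_silence(
    audio: AudioSegment,
    threshold_db: float = -26.0,
    min_silence: float = 1.0,
    *,
    frame_duration: float = 0.010,
) -> LabelTrack:
    """Label silence/sound intervals the way the Sound Finder filter does.

    Level is RMS dBFS over ``frame_duration`` frames with 50% overlap.  A
    below-threshold stretch becomes ``silence`` only if it lasts at least
    ``min_silence`` seconds; shorter quiet gaps are absorbed into the
    surrounding ``sound`` intervals.  The returned intervals partition
    [0, duration] exactly, with edges snapped to the frame grid.
    """
    if threshold_db >= 0.0:
        raise ValueError("threshold_db must be negative (dBFS)")
    if audio.samples.size == 0:
        raise ValueError("cannot mark silence on empty audio")
    frame = max(1, int(round(frame_duration * audio.sample_rate)))
    hop = max(1, frame // 2)
    db = _frame_rms_db(audio.samples, frame, hop)
    quiet = db < threshold_db

    duration = audio.duration
    events: list[LabelEvent] = []
    # Walk maximal quiet runs; keep those spanning >= min_silence seconds.
    silences: list[tuple[float, float]] = []
    i = 0
    n = quiet.size
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            t0 = i * hop / audio.sample_rate
            t1 = min(j * hop / audio.sample_rate, duration) if j < n else duration
            if t1 - t0 >= min_silence:
                silences.append((t0, t1))
            i = j
        else:
            i += 1

    cursor = 0.0
    for t0, t1 in silences:
        if t0 > cursor:
            events.append(LabelEvent(cursor, t0, "sound"))
        events.append(LabelEvent(t0, t1, "silence"))
        cursor = t1
    if cursor < duration:
        events.append(LabelEvent(cursor, duration, "sound"))
    return LabelTrack(events)
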