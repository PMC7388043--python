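"""Synthetic overnight soundscapes with ground-truth annotations.

The study data this package targets — long, mostly silent bedroom recordings
punctuated by short acoustic events, a small minority of which are coughs —
was never deposited, so every stage of the pipeline is exercised on synthetic
audio with known ground truth instead.

A synthetic cough is the simplest signal with the two phases that matter: an
explosive broadband burst (white noise with a 5 ms attack and fast
exponential decay) followed by a voiced tail (a sawtooth-like harmonic stack
at the fundamental frequency f0).  f0 carries the sex cue: male coughs draw
f0 from 85-180 Hz, female from 165-255 Hz, with the 165-180 Hz overlap region
excluded by default so ground truth is unambiguous.  Noncough events are
spectrally distinct archetypes (pure tones, chirps, snore-like low-frequency
AM noise, low-passed thumps, babble) over a pink-noise background.

Coughs cluster into epochs: a night plan draws Poisson counts of cough
epochs, isolated coughs and noncough events, with intra-epoch gaps short
enough that the 2-second epoch rule recovers exactly the planted clusters,
and inter-event margins wide enough that distinct events never merge.

One integer seed drives all draws through a single documented PRNG stream,
so nights are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .audio_io import AudioSegment, LabelEvent, LabelTrack

__all__ = [
    "SyntheticCoughSpec",
    "SyntheticNightConfig",
    "PlannedEvent",
    "CorpusEvent",
    "DensityError",
    "MALE_F0_RANGE",
    "FEMALE_F0_RANGE",
    "sample_cough_spec",
    "synth_cough",
    "synth_noncough",
    "plan_night_events",
    "synth_night",
    "synth_event_corpus",
    "NONCOUGH_KINDS",
]

MALE_F0_RANGE = (85.0, 180.0)
FEMALE_F0_RANGE = (165.0, 255.0)
NONCOUGH_KINDS = ("snore", "tone", "chirp", "thump", "babble")

#: margin (s) kept between distinct planted events so that epoch clusters
#: never merge across groups and detections never collide
_GROUP_MARGIN = 3.0


class DensityError(ValueError):
    """Raised when requested events cannot be placed without overlap."""


@dataclasses.dataclass(frozen=True)
class SyntheticCoughSpec:
    """Parameters of one synthetic cough."""

    sex: str
    f0: float
    burst_duration: float = 0.35
    peak_level_db: float = -6.0

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        lo, hi = FEMALE_F0_RANGE if self.sex == "female" else MALE_F0_RANGE
        if not lo <= self.f0 <= hi:
            raise ValueError(
                f"{self.sex} f0 must lie in [{lo}, {hi}] Hz, got {self.f0}"
            )
        if not 0.2 <= self.burst_duration <= 0.65:
            raise ValueError("burst_duration must lie in [0.2, 0.65] s")
        if self.peak_level_db <= -26.0:
            raise ValueError("peak_level_db must exceed -26 dBFS")


@dataclasses.dataclass(frozen=True)
class SyntheticNightConfig:
    """Conditions of one synthetic night.

    Rates are per hour; a night is rendered at ``sample_rate`` with a pink
    noise background at ``background_level_db`` RMS (kept below -26 dBFS so
    background alone reads as silence).
    """

    duration: float = 600.0
    cough_epoch_rate: float = 6.0
    coughs_per_epoch_range: tuple = (2, 4)
    intra_epoch_gap_range: tuple = (0.1, 1.0)
    isolated_cough_rate: float = 6.0
    noncough_event_rate: float = 30.0
    noncough_kinds: tuple = NONCOUGH_KINDS
    sex: str = "female"
    background_level_db: float = -50.0
    cough_duration_range: tuple = (0.2, 0.5)
    cough_peak_db_range: tuple = (-12.0, -6.0)
    noncough_peak_db_range: tuple = (-20.0, -10.0)
    allow_f0_overlap: bool = False
    sample_rate: int = 22_050
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for r in (self.cough_epoch_rate, self.isolated_cough_rate,
                  self.noncough_event_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if self.intra_epoch_gap_range[1] >= 2.0:
            raise ValueError("intra-epoch gaps must stay below the 2 s epoch pause")
        if self.background_level_db >= -26.0:
            raise ValueError("background must stay below the -26 dBFS silence level")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        for k in self.noncough_kinds:
            if k not in NONCOUGH_KINDS:
                raise ValueError(f"unknown noncough kind {k!r}")


@dataclasses.dataclass(frozen=True)
class PlannedEvent:
    """One event of a night plan (times in seconds from night start)."""

    start: float
    duration: float
    label: str  # "cough" or "noncough:<kind>"
    seed: int
    epoch_id: int | None = None  # index of the planted epoch, None if not in one
    cough_spec: SyntheticCoughSpec | None = None
    peak_level_db: float | None = None

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def center(self) -> float:
        return self.start + self.duration / 2.0


@dataclasses.dataclass(frozen=True)
class CorpusEvent:
    """One isolated labelled event of an event corpus."""

    participant_id: str
    sex: str
    label: str
    audio: AudioSegment


# ---------------------------------------------------------------------------
# event synthesis

def sample_cough_spec(
    sex: str,
    rng: np.random.Generator,
    *,
    allow_overlap: bool = False,
    duration_range: tuple = (0.2, 0.5),
    peak_db_range: tuple = (-12.0, -6.0),
) -> SyntheticCoughSpec:
    """Draw a cough spec with f0 uniform in the sex's range.

    By default the 165-180 Hz male/female overlap is excluded so synthetic
    ground truth is unambiguous; ``allow_overlap=True`` re-enables it.
    """
    if sex == "male":
        lo, hi = MALE_F0_RANGE
        if not allow_overlap:
            hi = FEMALE_F0_RANGE[0]
    else:
        lo, hi = FEMALE_F0_RANGE
        if not allow_overlap:
            lo = MALE_F0_RANGE[1]
    return SyntheticCoughSpec(
        sex=sex,
        f0=float(rng.uniform(lo, hi)),
        burst_duration=float(rng.uniform(*duration_range)),
        peak_level_db=float(rng.uniform(*peak_db_range)),
    )


def _normalize_peak(x: np.ndarray, peak_db: float) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak == 0:
        return x
    return x * (10.0 ** (peak_db / 20.0) / peak)


def synth_cough(spec: SyntheticCoughSpec, sample_rate: int, seed: int) -> AudioSegment:
    """Render one synthetic cough: noise burst attack plus voiced tail.

    The burst is white noise with a 5 ms linear attack and a 50 ms
    exponential decay; the tail is a 5-harmonic stack at ``spec.f0`` with
    sawtooth-like 1/k amplitudes, entering at 60 ms.  Peak amplitude matches
    ``spec.peak_level_db`` exactly; total length is ``spec.burst_duration``.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8000 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(spec.burst_duration * sample_rate))
    t = np.arange(n) / sample_rate

    attack = np.minimum(t / 0.005, 1.0)
    burst_env = attack * np.exp(-t / 0.050)
    burst = rng.standard_normal(n) * burst_env

    tail_t = t - 0.060
    tail_env = np.where(
        tail_t > 0,
        np.minimum(tail_t / 0.020, 1.0) * np.exp(-tail_t / (spec.burst_duration / 2.5)),
        0.0,
    )
    phases = rng.uniform(0, 2 * np.pi, 5)
    tail = np.zeros(n)
    for k in range(1, 6):
        tail += np.sin(2 * np.pi * k * spec.f0 * t + phases[k - 1]) / k
    tail *= 0.35 * tail_env

    return AudioSegment(_normalize_peak(burst + tail, spec.peak_level_db), sample_rate)


def _lowpass(x: np.ndarray, cutoff: float, sample_rate: int) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfilt(sos, x)


_NONCOUGH_DUR_RANGES = {
    "snore": (1.0, 3.0),
    "tone": (0.3, 1.5),
    "chirp": (0.3, 1.5),
    "thump": (0.15, 0.30),
    "babble": (0.5, 2.0),
}


def noncough_duration(kind: str, seed: int) -> float:
    """Duration that ``synth_noncough(kind, ..., seed)`` will draw."""
    if kind not in _NONCOUGH_DUR_RANGES:
        raise ValueError(f"unknown noncough kind {kind!r}")
    return float(np.random.default_rng(seed).uniform(*_NONCOUGH_DUR_RANGES[kind]))


def synth_noncough(
    kind: str,
    sample_rate: int,
    seed: int,
    peak_level_db: float = -12.0,
) -> AudioSegment:
    """Render one noncough archetype (snore, tone, chirp, thump, babble)."""
    if kind not in _NONCOUGH_DUR_RANGES:
        raise ValueError(f"unknown noncough kind {kind!r}")
    rng = np.random.default_rng(seed)
    dur = float(rng.uniform(*_NONCOUGH_DUR_RANGES[kind]))
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "snore":
        am = 0.2 + np.abs(np.sin(2 * np.pi * rng.uniform(2.0, 5.0) * t))
        x = _lowpass(rng.standard_normal(n), 300.0, sample_rate) * am
    elif kind == "tone":
        x = np.sin(2 * np.pi * rng.uniform(500.0, 3000.0) * t)
    elif kind == "chirp":
        f0, f1 = sorted(rng.uniform(300.0, 4000.0, 2))
        x = sps.chirp(t, f0=f0, t1=dur, f1=f1)
    elif kind == "thump":
        env = np.minimum(t / 0.005, 1.0) * np.exp(-t / 0.080)
        x = _lowpass(rng.standard_normal(n), 200.0, sample_rate) * env
    else:  # babble
        x = np.zeros(n)
        for _ in range(3):
            f = rng.uniform(200.0, 1000.0)
            am = 0.5 + 0.5 * np.sin(2 * np.pi * rng.uniform(2.0, 8.0) * t
                                    + rng.uniform(0, 2 * np.pi))
            x += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) * am
    # soft fade at the edges so events start and end without clicks
    fade = min(int(0.01 * sample_rate), x.size // 4)
    if fade > 0:
        ramp = np.linspace(0.0, 1.0, fade)
        x[:fade] *= ramp
        x[-fade:] *= ramp[::-1]
    return AudioSegment(_normalize_peak(x, peak_level_db), sample_rate)


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pink (1/f) noise with unit RMS, synthesised in the frequency domain."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spectrum / np.sqrt(f), n=n)
    return x / np.sqrt(np.mean(x ** 2))


# ---------------------------------------------------------------------------
# night planning and rendering

def plan_night_events(config: SyntheticNightConfig) -> list[PlannedEvent]:
    """Draw the event plan of one night (no audio rendering).

    Counts of epochs, isolated coughs and noncough events are Poisson with
    the configured per-hour rates.  Events are grouped (an epoch is one
    group) and groups are placed uniformly at random subject to a 3 s margin
    between any two events of different groups; if the draw cannot fit, a
    DensityError is raised.

    PRNG stream order (single generator seeded with ``config.seed``): the
    three Poisson counts, then per-epoch structure, then isolated coughs,
    then noncough events, then the group order permutation and placement.
    """
    rng = np.random.default_rng(config.seed)
    hours = config.duration / 3600.0
    n_epochs = int(rng.poisson(config.cough_epoch_rate * hours))
    n_isolated = int(rng.poisson(config.isolated_cough_rate * hours))
    n_noncough = int(rng.poisson(config.noncough_event_rate * hours))

    def cough_event(offset: float, epoch_id: int | None) -> PlannedEvent:
        spec = sample_cough_spec(
            config.sex, rng,
            allow_overlap=config.allow_f0_overlap,
            duration_range=config.cough_duration_range,
            peak_db_range=config.cough_peak_db_range,
        )
        return PlannedEvent(
            start=offset, duration=spec.burst_duration, label="cough",
            seed=int(rng.integers(2 ** 31)), epoch_id=epoch_id, cough_spec=spec,
        )

    # groups hold events with starts relative to the group origin
    groups: list[list[PlannedEvent]] = []
    for e in range(n_epochs):
        k = int(rng.integers(config.coughs_per_epoch_range[0],
                             config.coughs_per_epoch_range[1] + 1))
        offset = 0.0
        members = []
        for i in range(k):
            ev = cough_event(offset, epoch_id=e)
            members.append(ev)
            offset = ev.end + float(rng.uniform(*config.intra_epoch_gap_range))
        groups.append(members)
    for _ in range(n_isolated):
        groups.append([cough_event(0.0, epoch_id=None)])
    for _ in range(n_noncough):
        kind = str(rng.choice(list(config.noncough_kinds)))
        ev_seed = int(rng.integers(2 ** 31))
        groups.append([PlannedEvent(
            start=0.0, duration=noncough_duration(kind, ev_seed),
            label=f"noncough:{kind}", seed=ev_seed,
            peak_level_db=float(rng.uniform(*config.noncough_peak_db_range)),
        )])

    if not groups:
        return []
    order = rng.permutation(len(groups))
    spans = [g[-1].end for g in groups]
    total = sum(spans) + _GROUP_MARGIN * (len(groups) + 1)
    free = config.duration - total
    if free < 0:
        raise DensityError(
            f"cannot place {len(groups)} event groups spanning {total:.1f} s "
            f"with {_GROUP_MARGIN} s margins in a {config.duration:.1f} s night"
        )
    gaps = np.sort(rng.uniform(0.0, free, len(groups)))
    gaps = np.concatenate([[gaps[0]], np.diff(gaps)])

    events: list[PlannedEvent] = []
    cursor = _GROUP_MARGIN
    for slot, gi in enumerate(order):
        cursor += gaps[slot]
        for ev in groups[gi]:
            events.append(dataclasses.replace(ev, start=cursor + ev.start))
        cursor += spans[gi] + _GROUP_MARGIN
    return sorted(events, key=lambda e: e.start)


def synth_night(config: SyntheticNightConfig) -> tuple[AudioSegment, LabelTrack]:
    """Render one synthetic night: audio plus ground-truth label track."""
    events = plan_night_events(config)
    n = int(round(config.duration * config.sample_rate))
    rng = np.random.default_rng((config.seed, 1))  # background stream
    audio = pink_noise(n, rng) * 10.0 ** (config.background_level_db / 20.0)

    labels = []
    for ev in events:
        if ev.label == "cough":
            seg = synth_cough(ev.cough_spec, config.sample_rate, ev.seed)
        else:
            kind = ev.label.split(":", 1)[1]
            seg = synth_noncough(kind, config.sample_rate, ev.seed,
                                 peak_level_db=ev.peak_level_db)
        i0 = int(round(ev.start * config.sample_rate))
        i1 = min(i0 + seg.samples.size, n)
        audio[i0:i1] += seg.samples[:i1 - i0]
        labels.append(LabelEvent(ev.start, ev.start + seg.duration, ev.label))
    audio = np.clip(audio, -1.0, 1.0)
    return AudioSegment(audio, config.sample_rate), LabelTrack(labels)


# ---------------------------------------------------------------------------
# isolated-event corpora

def synth_event_corpus(
    n_participants: int = 40,
    coughs_per_participant: int = 5,
    noncoughs_per_participant: int = 50,
    sample_rate: int = 22_050,
    seed: int = 0,
    noncough_kinds: Sequence[str] = NONCOUGH_KINDS,
) -> list[CorpusEvent]:
    """Generate isolated labelled events across synthetic participants.

    Each participant is assigned a sex (alternating) and contributes
    ``coughs_per_participant`` coughs and ``noncoughs_per_participant``
    noncough events, for training/evaluating the window classifier at desk
    scale.
    """
    rng = np.random.default_rng(seed)
    corpus: list[CorpusEvent] = []
    for p in range(n_participants):
        sex = "female" if p % 2 == 0 else "male"
        pid = f"P{p:03d}"
        for _ in range(coughs_per_participant):
            spec = sample_cough_spec(sex, rng)
            corpus.append(CorpusEvent(
                pid, sex, "cough",
                synth_cough(spec, sample_rate, int(rng.integers(2 ** 31))),
            ))
        for _ in range(noncoughs_per_participant):
            kind = str(rng.choice(list(noncough_kinds)))
            corpus.append(CorpusEvent(
                pid, sex, f"noncough:{kind}",
                synth_noncough(kind, sample_rate, int(rng.integers(2 ** 31)),
                               peak_level_db=float(rng.uniform(-20.0, -10.0))),
            ))
    return corpus
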