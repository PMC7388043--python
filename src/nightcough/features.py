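"""Spectral feature extraction.

Two representations feed the pipeline:

* a log-Mel spectrogram of a 650 ms window, the input of the cough/noncough
  CNN.  Defaults are pinned so the spectrogram is exactly 80 Mel bands by
  122 frames;
* a 41-row matrix for sex assignment: 20 Mel-frequency cepstral coefficients
  (coefficient 0 included), their first time-derivative estimates, and the
  first time-derivative estimate of the zero-crossing rate, all on a common
  4096-sample / 256-hop frame grid.

Everything here is deterministic and pure: the same samples always yield
bit-identical features.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct, rfft

from .audio_io import AudioSegment

__all__ = [
    "FeatureConfig",
    "MelSpectrogram",
    "SexFeatureMatrix",
    "mel_filterbank",
    "mel_spectrogram",
    "extract_sex_features",
    "fit_window",
]


def hz_to_mel(f):
    """HTK Mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the CNN front-end.

    The defaults give a (80, 122) log-Mel spectrogram for one 650 ms window:
    14,334 samples at 22,050 Hz analysed in 1024-sample frames with a
    110-sample hop and no centre padding (frame count
    1 + (14334 - 1024) // 110 = 122).  ``window_samples`` is the 650 ms
    nominal length rounded up onto the frame grid.
    """

    sample_rate: int = 22_050
    window_duration: float = 0.650
    window_samples: int = 14_334
    frame_length: int = 1024
    hop: int = 110
    n_mels: int = 80
    log_floor_db: float = -100.0

    @property
    def n_frames(self) -> int:
        return 1 + (self.window_samples - self.frame_length) // self.hop

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class MelSpectrogram:
    """Log-magnitude Mel spectrogram, shape (n_mels, n_frames)."""

    values: np.ndarray
    config: FeatureConfig

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("MelSpectrogram values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("MelSpectrogram values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class SexFeatureMatrix:
    """41 x F feature matrix for sex assignment (rows 0-19 MFCC, 20-39
    delta-MFCC, 40 delta-ZCR); ``source`` says whether the signal was a
    single cough or a concatenated cough epoch."""

    values: np.ndarray
    source: str = "cough"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != 41:
            raise ValueError(f"expected a (41, F) matrix, got {v.shape}")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        object.__setattr__(self, "values", v)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def mel_filterbank(
    sample_rate: int, n_fft: int, n_mels: int,
    fmin: float = 0.0, fmax: float | None = None,
) -> np.ndarray:
    """Triangular Mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    if fmax is None:
        fmax = sample_rate / 2.0
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    bin_hz = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((n_mels, bin_hz.size))
    for m in range(n_mels):
        lo, mid, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (bin_hz - lo) / (mid - lo)
        down = (hi - bin_hz) / (hi - mid)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _frame(x: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    """Frame a signal into (n_frames, frame_length) without padding."""
    if x.size < frame_length:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {frame_length}-sample frame"
        )
    return sliding_window_view(x, frame_length)[::hop]


def _power_frames(x: np.ndarray, frame_length: int, hop: int, n_fft: int) -> np.ndarray:
    frames = _frame(x, frame_length, hop) * np.hanning(frame_length)
    return np.abs(rfft(frames, n=n_fft, axis=1)) ** 2


def fit_window(audio: AudioSegment, config: FeatureConfig) -> AudioSegment:
    """Symmetrically zero-pad a short segment to the analysis window length.

    Longer segments are rejected: the caller is responsible for windowing.
    """
    n = audio.samples.size
    target = config.window_samples
    if n > target:
        raise ValueError(f"segment of {n} samples exceeds the {target}-sample window")
    if n == target:
        return audio
    left = (target - n) // 2
    padded = np.zeros(target)
    padded[left:left + n] = audio.samples
    return AudioSegment(padded, audio.sample_rate,
                        audio.start_time - left / audio.sample_rate)


def mel_spectrogram(window: AudioSegment, config: FeatureConfig | None = None) -> MelSpectrogram:
    """Log-Mel spectrogram of one analysis window.

    Frames are Hann-windowed, power spectra pass through a triangular Mel
    filterbank, and magnitudes are log-compressed (10*log10) with a floor at
    ``config.log_floor_db``.
    """
    config = config or FeatureConfig()
    window = fit_window(window, config)
    power = _power_frames(window.samples, config.frame_length, config.hop,
                          config.frame_length)
    fb = mel_filterbank(config.sample_rate, config.frame_length, config.n_mels)
    mel_power = power @ fb.T  # (frames, mels)
    floor = 10.0 ** (config.log_floor_db / 10.0)
    values = 10.0 * np.log10(np.maximum(mel_power, floor)).T
    return MelSpectrogram(values.astype(np.float32), config)


# ---------------------------------------------------------------------------
# sex-assignment features: 20 MFCC + 20 delta-MFCC + 1 delta-ZCR

_MFCC_N = 20
_MFCC_FFT = 4096
_MFCC_FRAME = 4096
_MFCC_HOP = 256
_MFCC_MELS = 40


def _delta(x: np.ndarray) -> np.ndarray:
    """Centred first difference along the last axis, edges replicated."""
    padded = np.concatenate([x[..., :1], x, x[..., -1:]], axis=-1)
    return (padded[..., 2:] - padded[..., :-2]) / 2.0


def _zcr(frames: np.ndarray) -> np.ndarray:
    """Per-frame fraction of sign changes (sign taken as x >= 0)."""
    sign = frames >= 0.0
    return np.mean(sign[:, 1:] != sign[:, :-1], axis=1)


def sex_frame_count(n_samples: int) -> int:
    """Frames available to the sex-feature grid for an n-sample signal."""
    return 1 + (n_samples - _MFCC_FRAME) // _MFCC_HOP


def extract_sex_features(signal: AudioSegment, source: str = "cough") -> SexFeatureMatrix:
    """Compute the 41 x F sex-assignment feature matrix of a signal.

    MFCCs (n=20, coefficient 0 included) use 4096-sample Hann frames, a
    4096-point FFT and a 256-sample hop; the zero-crossing rate shares the
    frame grid, so all three feature blocks have the same frame count
    F = 1 + floor((N - 4096) / 256).
    """
    x = signal.samples
    if x.size < _MFCC_FRAME:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {_MFCC_FRAME}-sample frame"
        )
    power = _power_frames(x, _MFCC_FRAME, _MFCC_HOP, _MFCC_FFT)
    fb = mel_filterbank(signal.sample_rate, _MFCC_FFT, _MFCC_MELS)
    logmel = np.log(np.maximum(power @ fb.T, 1e-20))
    mfcc = dct(logmel, type=2, norm="ortho", axis=1)[:, :_MFCC_N].T  # (20, F)
    zcr = _zcr(_frame(x, _MFCC_FRAME, _MFCC_HOP))  # (F,)
    values = np.vstack([mfcc, _delta(mfcc), _delta(zcr)[None, :]])
    return SexFeatureMatrix(values, source=source)
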