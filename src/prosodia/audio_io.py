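"""WAV reading/writing and signal framing.

All downstream stages operate on :class:`AudioSignal`, a mono float signal
normalized to [-1, 1] at its native sampling rate.  No resampling is done on
load; clinical recordings at 44.1 and 48 kHz are analysed as-is.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


class AudioFormatError(ValueError):
    """Raised when a file cannot be read as PCM WAV."""


@dataclass
class AudioSignal:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in [-1, 1], float64.
    rate : int
        Sampling rate in Hz, > 0.
    id : str
        Recording identifier (defaults to the file stem on load).
    """

    samples: np.ndarray
    rate: int
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def slice(self, start_s: float, end_s: float, id_suffix: str = "") -> "AudioSignal":
        """Extract [start_s, end_s) as a new signal (clipped to bounds)."""
        i0 = max(0, int(round(start_s * self.rate)))
        i1 = min(self.samples.size, int(round(end_s * self.rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s})")
        return AudioSignal(self.samples[i0:i1].copy(), self.rate,
                           self.id + id_suffix)


_PCM_SCALE = {np.dtype(np.int16): 2 ** 15,
              np.dtype(np.int32): 2 ** 31,
              np.dtype(np.uint8): 2 ** 7}


def read_wav(path: str | os.PathLike) -> AudioSignal:
    """Read a PCM WAV file into a normalized mono :class:`AudioSignal`.

    Multichannel input is mixed to mono by the arithmetic channel mean.
    Integer PCM is scaled to [-1, 1]; float data is taken verbatim.
    """
    path = os.fspath(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.atleast_1d(data)
    if data.dtype == np.uint8:  # 8-bit PCM is unsigned, offset binary
        data = data.astype(np.float64) - 128.0
        data /= 128.0
    elif data.dtype in _PCM_SCALE:
        data = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    name = os.path.splitext(os.path.basename(path))[0]
    return AudioSignal(data, int(rate), id=name)


def write_wav(path: str | os.PathLike, sig: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV."""
    x = np.clip(sig.samples, -1.0, 1.0)
    wavfile.write(os.fspath(path), int(sig.rate),
                  (x * (2 ** 15 - 1)).astype(np.int16))


@dataclass
class FrameSet:
    """Zero-padded analysis frames with their center times."""

    frames: np.ndarray          # (n_frames, frame_len)
    center_times: np.ndarray    # seconds
    rate: int
    win_s: float
    hop_s: float


def frame_signal(sig: AudioSignal, win_s: float, hop_s: float) -> FrameSet:
    """Slice a signal into overlapping frames.

    Frame ``k`` is centered at ``k * hop_s``; frames extending past either
    edge are zero-padded.  The number of frames is
    ``floor(duration / hop_s) + 1`` so every sample is covered.
    """
    if win_s <= 0 or hop_s <= 0:
        raise ValueError("window and hop must be positive")
    if hop_s > win_s:
        raise ValueError("hop must not exceed window")
    flen = int(round(win_s * sig.rate))
    if flen < 2:
        raise ValueError("window shorter than 2 samples")
    n = sig.samples.size
    n_frames = int(np.floor(n / sig.rate / hop_s)) + 1
    half = flen // 2
    padded = np.pad(sig.samples, (half, flen))
    frames = np.empty((n_frames, flen))
    centers = np.empty(n_frames)
    for k in range(n_frames):
        c = int(round(k * hop_s * sig.rate))
        frames[k] = padded[c:c + flen]
        centers[k] = k * hop_s
    return FrameSet(frames, centers, sig.rate, win_s, hop_s)
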