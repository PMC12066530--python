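"""Two-pass fundamental-frequency estimation.

A first pass searches a very wide space (60-750 Hz by default) with a
normalized-autocorrelation estimator.  The first quartile q1 of the voiced
first-pass values then narrows the search to [0.75*q1, q1 * 2**1.5]
(i.e. 1.5 octaves above q1) for the final pass, which removes most octave
errors without per-speaker (age/sex) tuning of the search range.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .audio_io import AudioSignal, frame_signal

log = logging.getLogger(__name__)

STEP_S = 0.010        # analysis hop fixed at 10 ms
WINDOW_S = 0.040      # autocorrelation window
WIDE_BOUNDS = (60.0, 750.0)
DEFAULT_VOICING_THRESHOLD = 0.45


class UnvoicedUtteranceError(RuntimeError):
    """No voiced frames were found in the first pass."""


@dataclass
class PitchTrack:
    """f0 estimates on a uniform 10 ms grid.

    ``f0`` is NaN at unvoiced frames.  ``q1`` and ``bounds`` record the
    first-pass quartile and the final search space (both None after a
    single-pass call).
    """

    times: np.ndarray
    f0: np.ndarray
    q1: float | None = None
    bounds: tuple[float, float] | None = None

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "f0_hz"])
            for t, f in zip(self.times, self.f0):
                w.writerow([f"{t:.3f}", "" if np.isnan(f) else f"{f:.3f}"])


def _nacf_frames(frames: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of each (mean-removed) frame via FFT."""
    x = frames - frames.mean(axis=1, keepdims=True)
    n = x.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :n]
    r0 = ac[:, :1].copy()
    r0[r0 <= 0] = np.inf
    return ac / r0


def estimate_f0_once(sig: AudioSignal, lo: float, hi: float,
                     voicing_threshold: float = DEFAULT_VOICING_THRESHOLD) -> PitchTrack:
    """Single-pass f0 track with candidate lags restricted to [1/hi, 1/lo].

    Voicing requires the best normalized-autocorrelation peak to reach
    ``voicing_threshold``; parabolic interpolation refines the peak lag.
    """
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= sig.rate / 2:
        raise ValueError(f"upper bound {hi} Hz >= Nyquist {sig.rate / 2} Hz")
    fs = frame_signal(sig, WINDOW_S, STEP_S)
    nacf = _nacf_frames(fs.frames)
    lag_lo = max(2, int(np.floor(sig.rate / hi)))
    lag_hi = min(nacf.shape[1] - 2, int(np.ceil(sig.rate / lo)))
    f0 = np.full(len(fs.center_times), np.nan)
    if lag_hi <= lag_lo:
        return PitchTrack(fs.center_times, f0)
    seg = nacf[:, lag_lo:lag_hi + 1]
    best = np.argmax(seg, axis=1) + lag_lo
    peak = nacf[np.arange(len(best)), best]
    energy = np.mean(fs.frames ** 2, axis=1)
    voiced = (peak >= voicing_threshold) & (energy > 1e-10)
    # parabolic interpolation over the three lags around the peak
    for i in np.flatnonzero(voiced):
        k = best[i]
        ym, y0, yp = nacf[i, k - 1], nacf[i, k], nacf[i, k + 1]
        denom = ym - 2 * y0 + yp
        delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        cand = sig.rate / (k + delta)
        if lo <= cand <= hi:
            f0[i] = cand
    return PitchTrack(fs.center_times, f0)


def second_pass_bounds(q1: float) -> tuple[float, float]:
    """Final-pass search space: 0.75*q1 up to 1.5 octaves above q1."""
    if q1 <= 0:
        raise ValueError(f"q1 must be positive, got {q1}")
    return 0.75 * q1, q1 * 2.0 ** 1.5


def estimate_f0(sig: AudioSignal,
                voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
                wide_bounds: tuple[float, float] = WIDE_BOUNDS) -> PitchTrack:
    """Two-pass f0 track.

    q1 is the linear-interpolation first quartile of the (median-smoothed)
    voiced first-pass values.  Raises :class:`UnvoicedUtteranceError` when
    the first pass finds no voiced frame.
    """
    if sig.duration_s < 0.2:
        raise ValueError("utterance shorter than 0.2 s")
    hi = min(wide_bounds[1], sig.rate / 2 * 0.95)
    first = estimate_f0_once(sig, wide_bounds[0], hi, voicing_threshold)
    if first.n_voiced == 0:
        raise UnvoicedUtteranceError(f"no voiced frames in {sig.id!r}")
    v = first.f0[first.voiced]
    if v.size >= 5:  # octave-jump smoothing before the quartile only
        v = medfilt(v, 5)
    q1 = float(np.quantile(v, 0.25))  # linear-interpolation quantile
    lo2, hi2 = second_pass_bounds(q1)
    hi2 = min(hi2, sig.rate / 2 * 0.95)
    second = estimate_f0_once(sig, lo2, hi2, voicing_threshold)
    second.q1 = q1
    second.bounds = (lo2, hi2)
    return second
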