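"""Short-term spectral and intensity measurements at intonation targets.

Every spectral-tilt quantity used by the feature battery lives here:

* SER — spectral energy ratio (dB) between the 0-1 kHz and 1-5 kHz bands;
* L2-L1, L3-L1 — harmonic level differences read off the spectrum, raw and
  with the Iseli et al. correction for nearby formants (formant bandwidths
  from the Hawks-Miller regression);
* C1 — first Mel-frequency cepstral coefficient;
* SLF / SLF6D — slope of a 1st-order and coefficients of a 6th-order
  polynomial fit to the short-term log-magnitude spectrum (0-5 kHz).

dB values are referenced to digital full scale (a full-scale square wave is
0 dB); no SPL calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from scipy.signal import get_window

EPS = 1e-12
SILENCE_FLOOR_DB = -120.0
SER_CAP_DB = 60.0


@dataclass
class SpectralSlice:
    freqs: np.ndarray          # Hz, strictly increasing
    log_mag: np.ndarray        # dB
    center_time_s: float = 0.0
    f0_hz: float | None = None
    flagged: bool = False      # set for degenerate (all-zero) frames
    _win_energy: float = 0.0   # windowed-frame energy, for Parseval checks


def short_term_spectrum(frame: np.ndarray, rate: int,
                        center_time_s: float = 0.0) -> SpectralSlice:
    """Hann-windowed log-magnitude spectrum of one frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.size < 128:
        raise ValueError("frame shorter than 128 samples")
    win = get_window("hann", frame.size, fftbins=True)
    xw = frame * win
    spec = np.abs(rfft(xw))
    freqs = rfftfreq(frame.size, 1.0 / rate)
    flagged = not np.any(frame)
    log_mag = 20.0 * np.log10(spec + EPS)
    return SpectralSlice(freqs, log_mag, center_time_s,
                         flagged=flagged, _win_energy=float(np.sum(xw ** 2)))


def intensity_db(frame: np.ndarray) -> tuple[float, bool]:
    """Frame intensity: 10*log10(mean square), 0 dB = full-scale square.

    Returns ``(level_db, flagged)``; silence floors at -120 dB, flagged.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    ms = float(np.mean(frame ** 2))
    if ms <= 10.0 ** (SILENCE_FLOOR_DB / 10.0):
        return SILENCE_FLOOR_DB, True
    return 10.0 * np.log10(ms), False


def _band_power(slice_: SpectralSlice, lo: float, hi: float,
                include_lo: bool = True) -> float:
    power = (10.0 ** (slice_.log_mag / 20.0)) ** 2
    if include_lo:
        m = (slice_.freqs >= lo) & (slice_.freqs <= hi)
    else:
        m = (slice_.freqs > lo) & (slice_.freqs <= hi)
    return float(power[m].sum())


def ser_db(slice_: SpectralSlice) -> tuple[float, bool]:
    """Spectral energy ratio (dB): band [0, 1 kHz] over (1 kHz, 5 kHz].

    A vanishing high band caps the ratio at +60 dB (flagged).
    """
    if slice_.freqs[-1] <= 5000.0:
        raise ValueError("Nyquist must exceed 5 kHz for SER")
    low = _band_power(slice_, 0.0, 1000.0)
    high = _band_power(slice_, 1000.0, 5000.0, include_lo=False)
    if high <= low * 10.0 ** (-SER_CAP_DB / 10.0) or high == 0.0:
        return SER_CAP_DB, True
    return 10.0 * np.log10(max(low, EPS ** 2) / high), False


def _peak_interp(log_mag: np.ndarray, k: int) -> tuple[float, float]:
    """Parabolic interpolation over bins (k-1, k, k+1) -> (offset, level)."""
    if k <= 0 or k >= log_mag.size - 1:
        return 0.0, float(log_mag[k])
    ym, y0, yp = log_mag[k - 1], log_mag[k], log_mag[k + 1]
    denom = ym - 2 * y0 + yp
    if denom == 0:
        return 0.0, float(y0)
    d = 0.5 * (ym - yp) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, float(y0 - 0.25 * (ym - yp) * d)


def harmonic_levels(slice_: SpectralSlice, f0: float
                    ) -> tuple[float, float, float | None]:
    """Levels (dB) of the spectral peaks nearest 1*f0, 2*f0, 3*f0.

    Each peak is searched within +-f0/4 of the nominal harmonic and refined
    by parabolic interpolation.  L3 is None when 3*f0 reaches Nyquist.
    """
    if f0 is None or f0 <= 0:
        raise ValueError("f0 required for harmonic levels")
    nyq = slice_.freqs[-1]
    out = []
    for k in (1, 2, 3):
        target = k * f0
        if target >= nyq:
            out.append(None)
            continue
        m = np.abs(slice_.freqs - target) <= f0 / 4
        if not m.any():
            out.append(None)
            continue
        idx = np.flatnonzero(m)
        j = idx[np.argmax(slice_.log_mag[idx])]
        _, level = _peak_interp(slice_.log_mag, j)
        out.append(level)
    l1, l2, l3 = out
    if l1 is None or l2 is None:
        raise ValueError("first two harmonics must lie below Nyquist")
    return l1, l2, l3


# -- Hawks & Miller formant-bandwidth regression ----------------------------

# Fifth-order polynomial branches (low: F < 500 Hz, high: F >= 500 Hz) with
# an f0-dependent scale factor, as published for vowel synthesis.
_HM_LOW = (165.327516, -6.73636734e-1, 1.80874446e-3, -4.52201682e-6,
           7.49514000e-9, -4.70219241e-12)
_HM_HIGH = (15.8146139, 8.10159009e-2, -9.79728215e-5, 5.28725064e-8,
            -1.07099364e-11, 7.91528509e-16)
_HM_SPLIT_HZ = 500.0


def hawks_miller_bandwidth(formant_hz: float, f0_hz: float) -> float:
    """Formant bandwidth (Hz) from the Hawks-Miller polynomial regression."""
    if not (100.0 < formant_hz < 5000.0):
        raise ValueError(f"formant {formant_hz} Hz outside (100, 5000)")
    s = 1.0 + 0.25 * (f0_hz - 132.0) / 88.0
    coefs = _HM_LOW if formant_hz < _HM_SPLIT_HZ else _HM_HIGH
    powers = formant_hz ** np.arange(6)
    return float(s * np.dot(coefs, powers))


# -- Iseli et al. formant correction ----------------------------------------

def iseli_correction_db(freq_hz: float, formant_hz: float,
                        bandwidth_hz: float, rate: int) -> float:
    """dB boost that one formant resonance adds at ``freq_hz``.

    Discrete-time two-pole resonance magnitude, normalized to unit gain at
    zero frequency; subtracting this from a measured harmonic level removes
    the formant's influence.
    """
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth must be positive")
    r = np.exp(-np.pi * bandwidth_hz / rate)
    wx = 2 * np.pi * formant_hz / rate
    w = 2 * np.pi * freq_hz / rate
    a = r ** 2 + 1 - 2 * r * np.cos(wx + w)
    b = r ** 2 + 1 - 2 * r * np.cos(wx - w)
    num = r ** 2 + 1 - 2 * r * np.cos(wx)
    return float(10.0 * np.log10(num ** 2 / (a * b)))


def iseli_corrected_level(level_db: float, freq_hz: float,
                          formants: list[tuple[float, float]],
                          rate: int) -> float:
    """Harmonic level with the influence of the given formants removed.

    ``formants`` is a list of (frequency Hz, bandwidth Hz); an empty list
    returns the level unchanged.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    corr = sum(iseli_correction_db(freq_hz, F, B, rate) for F, B in formants)
    return level_db - corr


# -- formant estimation ------------------------------------------------------

def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin solution of the LPC normal equations."""
    n = x.size
    r = np.correlate(x, x, mode="full")[n - 1:n + order]
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    if err <= 0:
        raise np.linalg.LinAlgError("zero-energy frame")
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[1:i][::-1])
        k = -acc / err
        a[1:i] = a[1:i] + k * a[1:i][::-1]
        a[i] = k
        err *= (1 - k * k)
        if err <= 0:
            raise np.linalg.LinAlgError("unstable recursion")
    return a


def estimate_formants(frame: np.ndarray, rate: int,
                      f0_hz: float = 100.0,
                      n_formants: int = 3) -> list[tuple[float, float]]:
    """First formants as (frequency, bandwidth) via LPC root-solving.

    Pre-emphasis 0.97; LPC order 2 + rate/1000 (rounded); roots kept when
    the frequency falls in (90, 5000) Hz with raw LPC bandwidth < 700 Hz.
    Reported bandwidths come from the Hawks-Miller regression at ``f0_hz``.
    Returns an empty list (correction degrades to identity) when no stable
    structure is found.
    """
    frame = np.asarray(frame, dtype=float)
    x = np.append(frame[0], frame[1:] - 0.97 * frame[:-1])
    x = x * get_window("hann", x.size, fftbins=True)
    order = 2 + int(round(rate / 1000.0))
    if x.size <= order + 1 or not np.any(x):
        return []
    try:
        a = _lpc(x, order)
        roots = np.roots(a)
    except np.linalg.LinAlgError:
        return []
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * rate / (2 * np.pi)
    bws = -rate / np.pi * np.log(np.abs(roots))
    cands = [(float(F), float(B)) for F, B in zip(freqs, bws)
             if 90.0 < F < 5000.0 and 0 < B < 700.0]
    cands.sort()
    # merge near-duplicate roots (one resonance can split into two poles),
    # keeping the sharper of the pair
    merged: list[tuple[float, float]] = []
    for F, B in cands:
        if merged and F - merged[-1][0] < max(150.0, 0.1 * F):
            if B < merged[-1][1]:
                merged[-1] = (F, B)
        else:
            merged.append((F, B))
    out = []
    for F, _ in merged[:n_formants]:
        if 100.0 < F < 5000.0:
            out.append((F, hawks_miller_bandwidth(F, f0_hz)))
    return out


# -- Mel cepstrum ------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft_bins: int, rate: int) -> np.ndarray:
    """Triangular Mel filters 0-Nyquist, each normalized to unit area so a
    flat power spectrum maps to equal filter outputs."""
    nyq = rate / 2.0
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(nyq), n_filters + 2))
    freqs = np.linspace(0.0, nyq, n_fft_bins)
    fb = np.zeros((n_filters, n_fft_bins))
    for i in range(n_filters):
        lo, ce, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(ce - lo, EPS)
        down = (hi - freqs) / max(hi - ce, EPS)
        tri = np.maximum(0.0, np.minimum(up, down))
        s = tri.sum()
        if s > 0:
            fb[i] = tri / s
    return fb


def mfcc_c1(frame: np.ndarray, rate: int, n_filters: int = 26
            ) -> tuple[float, bool]:
    """First Mel-frequency cepstral coefficient of one frame.

    26 triangular filters on the power spectrum, log energies, orthonormal
    DCT-II; index 0 (the gain term) is discarded, so C1 is invariant to
    amplitude scaling.  Silent frames return (0, flagged).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size < 256:
        raise ValueError("frame shorter than 256 samples")
    if not np.any(frame):
        return 0.0, True
    win = get_window("hann", frame.size, fftbins=True)
    power = np.abs(rfft(frame * win)) ** 2
    fb = _mel_filterbank(n_filters, power.size, rate)
    e = fb @ power
    # floor 60 dB below the strongest filter: keeps C1 finite and stable
    # when a narrow low filter happens to fall between harmonics
    log_e = np.log(np.maximum(e, e.max() * 1e-6))
    cep = dct(log_e, type=2, norm="ortho")
    return float(cep[1]), False


def spectral_poly_fit(slice_: SpectralSlice, order: int,
                      f_max_hz: float = 5000.0) -> np.ndarray:
    """Least-squares polynomial fit to the log-magnitude spectrum, 0-5 kHz.

    The frequency axis is in kHz so coefficients stay well-scaled.  Order 1
    returns the slope only (dB/kHz); order 6 returns the six non-constant
    coefficients, lowest degree first.
    """
    if order not in (1, 6):
        raise ValueError("order must be 1 or 6")
    m = slice_.freqs <= f_max_hz
    fk = slice_.freqs[m] / 1000.0
    y = slice_.log_mag[m]
    if fk.size < order + 1:
        raise ValueError("not enough bins below 5 kHz for the fit")
    coefs = np.polynomial.polynomial.polyfit(fk, y, order)
    return np.array([coefs[1]]) if order == 1 else coefs[1:]
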