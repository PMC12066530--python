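"""Assembly of the per-utterance prosodic predictor battery (205 features).

Quantities measured at the Momel target points (MTPs) — times, Momel f0,
intensity, and the spectral-tilt family — and their successive differences
are each collapsed into six summary statistics (min, max, mean, SD,
coefficient of variation, IQR).  Together with utterance-level quantities
(duration, MTP concentration, f0 key/range, long-term-average-spectrum SER,
...) this yields exactly 205 named predictors per utterance, organised in
four domains with subtotals 15 (time), 16 (f0), 16 (intensity) and 158
(spectral tilt).

Two rows of the published battery layout are degenerate duplicates; they
are reconstructed here as the MTP time span (a second duration-like slot)
and the utterance mean intensity (the intensity-domain "key" slot).  Both
reconstructions are documented in the methods note.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .stylize import IntsintAnnotation, MomelCurve

STAT_NAMES = ("min", "max", "mean", "sd", "cv", "iqr")


@dataclass
class SummaryStats6:
    min: float
    max: float
    mean: float
    sd: float
    cv: float
    iqr: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.min, self.max, self.mean, self.sd, self.cv, self.iqr)


def summarize6(values) -> SummaryStats6:
    """Six summary statistics of a sequence (NaNs are ignored).

    SD uses the n-1 denominator (0 for a single value); CV = SD/mean and is
    NaN when the mean vanishes; IQR uses linear-interpolation quantiles.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to summarize")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    cv = sd / mean if abs(mean) >= 1e-12 else np.nan
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return SummaryStats6(float(v.min()), float(v.max()), mean, sd,
                         float(cv), float(q3 - q1))


@dataclass
class TiltMeasures:
    """Spectral-tilt quantities at one MTP."""

    ser_db: float
    l2_l1_db: float
    l3_l1_db: float
    l2_l1_corr_db: float
    l3_l1_corr_db: float
    c1: float
    slf_slope: float           # dB/kHz
    slf6d: np.ndarray          # 6 non-constant polynomial coefficients


@dataclass
class UtteranceAnalysis:
    """Everything measured from one utterance, ready for feature assembly."""

    utterance_id: str
    speaker_id: str
    recording_id: str
    duration_s: float
    curve: MomelCurve
    annotation: IntsintAnnotation
    intensities_db: np.ndarray          # per MTP
    tilt: list[TiltMeasures]            # per MTP
    ltas_ser_db: float
    intensity_track_db: np.ndarray      # per 10 ms frame over the utterance


# ---------------------------------------------------------------------------
# feature name registry (order is frozen; tests assert its checksum)

def _stats(prefix: str) -> list[str]:
    return [f"{prefix}_{s}" for s in STAT_NAMES]


def _build_names() -> tuple[list[str], dict[str, list[str]]]:
    domains: dict[str, list[str]] = {}
    domains["time"] = (_stats("mtp_time")
                       + _stats("mtp_dtime")
                       + ["duration_s", "mtp_rate", "mtp_span_s"])
    domains["f0"] = (_stats("mtp_f0")
                     + _stats("mtp_df0")
                     + ["f0_key_hz", "f0_range_hz", "f0_min_hz", "f0_max_hz"])
    domains["intensity"] = (_stats("mtp_intensity")
                            + _stats("mtp_dintensity")
                            + ["intensity_mean_db", "intensity_range_db",
                               "intensity_min_db", "intensity_max_db"])
    tilt = (_stats("mtp_ser") + ["ser_ltas_db"]
            + _stats("mtp_dser") + ["ser_sd_vs_ltas_db"]
            + _stats("mtp_l2l1") + _stats("mtp_l2l1_corr")
            + _stats("mtp_l3l1") + _stats("mtp_l3l1_corr")
            + _stats("mtp_dl2l1") + _stats("mtp_dl2l1_corr")
            + _stats("mtp_dl3l1") + _stats("mtp_dl3l1_corr")
            + _stats("mtp_c1") + _stats("mtp_dc1")
            + _stats("mtp_slf") + _stats("mtp_dslf"))
    for c in range(1, 7):
        tilt += _stats(f"mtp_slf6d_c{c}")
    for c in range(1, 7):
        tilt += _stats(f"mtp_dslf6d_c{c}")
    domains["tilt"] = tilt
    names = sum(domains.values(), [])
    return names, domains


FEATURE_NAMES, FEATURE_DOMAINS = _build_names()
N_FEATURES = len(FEATURE_NAMES)
ID_COLUMNS = ["utterance_id", "speaker_id", "recording_id"]


def feature_checksum(names=None) -> str:
    """SHA-256 over the frozen, ordered feature-name list."""
    names = FEATURE_NAMES if names is None else list(names)
    return hashlib.sha256(",".join(names).encode()).hexdigest()


@dataclass
class FeatureVector:
    values: dict[str, float]
    utterance_id: str
    speaker_id: str
    recording_id: str = ""
    n_mtps: int = 0

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            raise ValueError("feature names or order do not match the "
                             "frozen 205-name registry")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def mtp_series(curve: MomelCurve, annotation: IntsintAnnotation,
               intensities_db: np.ndarray, tilt: list[TiltMeasures]
               ) -> dict[str, np.ndarray]:
    """Per-MTP level series and their first differences.

    Differences are (value at k) - (value at k-1) for k = 2..n; the first
    MTP contributes to the level series only.
    """
    n = len(curve)
    if n < 2:
        raise ValueError("need at least 2 MTPs for difference series")
    t = curve.times
    f0 = curve.f0
    series = {
        "time": t, "dtime": np.diff(t),
        "f0": f0, "df0": np.diff(f0),
        "intensity": np.asarray(intensities_db),
        "dintensity": np.diff(intensities_db),
    }
    for attr, key in (("ser_db", "ser"), ("l2_l1_db", "l2l1"),
                      ("l2_l1_corr_db", "l2l1_corr"), ("l3_l1_db", "l3l1"),
                      ("l3_l1_corr_db", "l3l1_corr"), ("c1", "c1"),
                      ("slf_slope", "slf")):
        vals = np.array([getattr(tm, attr) if getattr(tm, attr) is not None
                         else np.nan for tm in tilt], dtype=float)
        series[key] = vals
        series["d" + key] = np.diff(vals)
    slf6d = np.array([tm.slf6d for tm in tilt])     # (n_mtps, 6)
    series["slf6d"] = slf6d
    series["dslf6d"] = np.diff(slf6d, axis=0)
    return series


def build_feature_vector(analysis: UtteranceAnalysis) -> FeatureVector:
    """Compute the 205 predictors for one analysed utterance."""
    curve, ann = analysis.curve, analysis.annotation
    n = len(curve)
    if n < 2:
        raise ValueError("utterance with < 2 MTPs is excluded")
    s = mtp_series(curve, ann, analysis.intensities_db, analysis.tilt)
    vals: dict[str, float] = {}

    def put6(prefix: str, data) -> None:
        st = summarize6(data)
        for name, v in zip(STAT_NAMES, st.as_tuple()):
            vals[f"{prefix}_{name}"] = v

    # -- time
    put6("mtp_time", s["time"])
    put6("mtp_dtime", s["dtime"])
    vals["duration_s"] = analysis.duration_s
    vals["mtp_rate"] = n / analysis.duration_s
    vals["mtp_span_s"] = float(s["time"][-1] - s["time"][0])
    # -- f0: curve extrema sampled on the 10 ms grid
    lo, hi = curve.domain
    grid = np.arange(lo, hi + 1e-9, 0.010)
    cf = curve(grid)
    put6("mtp_f0", s["f0"])
    put6("mtp_df0", s["df0"])
    vals["f0_key_hz"] = ann.key_hz
    vals["f0_min_hz"] = float(cf.min())
    vals["f0_max_hz"] = float(cf.max())
    vals["f0_range_hz"] = vals["f0_max_hz"] - vals["f0_min_hz"]
    # -- intensity
    put6("mtp_intensity", s["intensity"])
    put6("mtp_dintensity", s["dintensity"])
    track = np.asarray(analysis.intensity_track_db, dtype=float)
    track = track[np.isfinite(track)]
    vals["intensity_mean_db"] = float(track.mean())
    vals["intensity_min_db"] = float(track.min())
    vals["intensity_max_db"] = float(track.max())
    vals["intensity_range_db"] = vals["intensity_max_db"] - vals["intensity_min_db"]
    # -- spectral tilt
    put6("mtp_ser", s["ser"])
    vals["ser_ltas_db"] = analysis.ltas_ser_db
    put6("mtp_dser", s["dser"])
    dev = s["ser"][np.isfinite(s["ser"])] - analysis.ltas_ser_db
    vals["ser_sd_vs_ltas_db"] = float(np.sqrt(np.mean(dev ** 2)))
    for key in ("l2l1", "l2l1_corr", "l3l1", "l3l1_corr"):
        put6(f"mtp_{key}", s[key])
    for key in ("dl2l1", "dl2l1_corr", "dl3l1", "dl3l1_corr"):
        put6(f"mtp_{key}", s[key])
    put6("mtp_c1", s["c1"])
    put6("mtp_dc1", s["dc1"])
    put6("mtp_slf", s["slf"])
    put6("mtp_dslf", s["dslf"])
    for c in range(6):
        put6(f"mtp_slf6d_c{c + 1}", s["slf6d"][:, c])
    for c in range(6):
        put6(f"mtp_dslf6d_c{c + 1}", s["dslf6d"][:, c])

    ordered = {name: vals[name] for name in FEATURE_NAMES}
    return FeatureVector(ordered, analysis.utterance_id,
                         analysis.speaker_id, analysis.recording_id, n)
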