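"""Intonation stylization: Momel target points and INTSINT coding.

The voiced f0 track is reduced to a small set of (time, frequency) target
points (MTPs) through which a C1-continuous quadratic spline — the
macro-prosodic contour — is drawn.  Each MTP is then assigned one of eight
symbolic INTSINT levels (T, H, U, S, M, D, L, B) relative to an utterance
*key* (Hz) and *span* (octaves) found by grid search; absolute levels sit on
the key and the span edges, relative levels are defined on a log-frequency
scale from the preceding target.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from .pitch import PitchTrack

log = logging.getLogger(__name__)

INTSINT_LABELS = ("T", "H", "U", "S", "M", "D", "L", "B")
ABSOLUTE_LABELS = ("T", "M", "B")
RELATIVE_LABELS = ("H", "U", "S", "D", "L")


class StylizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MomelTargetPoint:
    time_s: float
    f0_hz: float

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("MTP frequency must be positive")


class MomelCurve:
    """Quadratic-spline macro-prosodic contour anchored at the MTPs.

    The spline has knots at the midpoints between consecutive MTP times,
    is C1-continuous, and interpolates every MTP.  With two MTPs it
    degenerates to the straight line through both.
    """

    def __init__(self, mtps: Sequence[MomelTargetPoint]):
        if len(mtps) < 2:
            raise StylizationError("need at least 2 MTPs")
        times = np.array([m.time_s for m in mtps])
        if not np.all(np.diff(times) > 0):
            raise ValueError("MTP times must be strictly increasing")
        self.mtps = list(mtps)
        self._times = times
        self._f0 = np.array([m.f0_hz for m in mtps])
        k = 2 if len(mtps) >= 3 else 1
        # for even-degree interpolation scipy places interior knots at the
        # data midpoints, which is exactly the construction wanted here
        self._spline = make_interp_spline(times, self._f0, k=k)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self._times[0]), float(self._times[-1])

    @property
    def times(self) -> np.ndarray:
        return self._times

    @property
    def f0(self) -> np.ndarray:
        return self._f0

    def __len__(self) -> int:
        return len(self.mtps)

    def __call__(self, t):
        lo, hi = self.domain
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < lo - 1e-9) or np.any(t_arr > hi + 1e-9):
            raise ValueError(f"time outside curve domain [{lo}, {hi}]")
        return self._spline(np.clip(t_arr, lo, hi))


def spline_eval(curve: MomelCurve, t) -> float | np.ndarray:
    """Evaluate the macro-prosodic contour at time(s) ``t`` (in-domain)."""
    out = curve(t)
    return float(out) if np.isscalar(t) else out


def _quadfit(t: np.ndarray, f: np.ndarray) -> np.ndarray | None:
    """Least-squares quadratic coefficients, linear fallback on rank loss."""
    try:
        coef, res, rank, _ = np.linalg.lstsq(
            np.vander(t, 3), f, rcond=None)
        if rank < 3:
            raise np.linalg.LinAlgError
        return coef
    except np.linalg.LinAlgError:
        lin = np.polyfit(t, f, 1)
        return np.array([0.0, lin[0], lin[1]])


def momel_targets(track: PitchTrack,
                  window_s: float = 0.300,
                  outlier_frac: float = 0.05,
                  reduction_s: float = 0.200,
                  min_separation_s: float = 0.05) -> MomelCurve:
    """Extract Momel target points from a pitch track.

    Each voiced frame contributes a candidate target from a local quadratic
    regression over a sliding 300 ms window (one refit after removing
    frames > 5 % off the first fit): the parabola apex when it falls inside
    the window — this concentrates candidates at intonational turning
    points — otherwise the fitted value at the frame.  Candidates are
    partitioned over 200 ms reduction windows and averaged into final MTPs;
    the first and last voiced frames (at their locally fitted values)
    always anchor the contour so the curve spans the utterance.
    """
    voiced = track.voiced
    if voiced.sum() < 3:
        raise StylizationError("too short to stylize (< 3 voiced frames)")
    tv = track.times[voiced]
    fv = track.f0[voiced]
    half = window_s / 2
    cands_t, cands_f = [], []
    edge_vals = {}
    for i, tc in enumerate(tv):
        m = np.abs(tv - tc) <= half
        if m.sum() < 5:
            if i in (0, len(tv) - 1):
                edge_vals[i] = fv[i]
            continue
        coef = _quadfit(tv[m], fv[m])
        fit = np.polyval(coef, tv[m])
        keep = np.abs(fv[m] - fit) <= outlier_frac * np.abs(fit)
        if keep.sum() >= 5 and not keep.all():
            coef = _quadfit(tv[m][keep], fv[m][keep])
        if i in (0, len(tv) - 1):
            edge_vals[i] = float(np.polyval(coef, tv[i]))
        a, b, _ = coef
        t_cand, f_cand = tc, float(np.polyval(coef, tc))
        if abs(a) > 1e-9:
            t_apex = -b / (2 * a)
            f_apex = float(np.polyval(coef, t_apex))
            if (tv[m][0] <= t_apex <= tv[m][-1]
                    and 0.5 * fv[m].min() <= f_apex <= 2.0 * fv[m].max()):
                t_cand, f_cand = t_apex, f_apex
        if f_cand > 0:
            cands_t.append(t_cand)
            cands_f.append(f_cand)
    # reduction: average candidates within 200 ms partition windows
    reduced: list[tuple[float, float]] = []
    if cands_t:
        order = np.argsort(cands_t)
        ct = np.array(cands_t)[order]
        cf = np.array(cands_f)[order]
        bins = np.floor((ct - ct[0]) / reduction_s).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            reduced.append((float(ct[sel].mean()), float(cf[sel].mean())))
    # endpoint anchors at the first/last voiced frames
    t0, t1 = float(tv[0]), float(tv[-1])
    f_start = float(edge_vals.get(0, fv[0]))
    f_end = float(edge_vals.get(len(tv) - 1, fv[-1]))
    points = [(t0, f_start)]
    for t, f in reduced:
        if t - points[-1][0] >= min_separation_s and t1 - t >= min_separation_s:
            points.append((t, f))
    points.append((t1, f_end))
    mtps = [MomelTargetPoint(t, max(f, 1.0)) for t, f in points]
    return MomelCurve(mtps)


# ---------------------------------------------------------------------------
# INTSINT

@dataclass
class IntsintAnnotation:
    key_hz: float
    span_oct: float
    labels: list[str]
    predicted_f0: np.ndarray
    objective: float  # summed squared log2-frequency error

    def __post_init__(self) -> None:
        if not (0.5 <= self.span_oct <= 2.5):
            raise ValueError("span must lie in [0.5, 2.5] octaves")
        if len(self.labels) != len(self.predicted_f0):
            raise ValueError("labels and predictions disagree in length")


def intsint_predict(label: str, prev_f0: float | None,
                    key: float, span: float) -> float:
    """Model f0 (Hz) of one INTSINT level.

    Absolute levels: T = key*2**(span/2), M = key, B = key*2**(-span/2).
    Relative levels sit on a log scale from the preceding target: H/L at the
    midpoint to the T/B level, U/D a quarter of the way, S unchanged.
    """
    if label not in INTSINT_LABELS:
        raise ValueError(f"unknown INTSINT label {label!r}")
    top = key * 2.0 ** (span / 2)
    bottom = key * 2.0 ** (-span / 2)
    if label == "T":
        return top
    if label == "M":
        return key
    if label == "B":
        return bottom
    if prev_f0 is None or prev_f0 <= 0:
        raise ValueError(f"relative label {label!r} requires a previous f0")
    lp = np.log(prev_f0)
    if label == "S":
        return prev_f0
    if label == "H":
        return float(np.exp((lp + np.log(top)) / 2))
    if label == "L":
        return float(np.exp((lp + np.log(bottom)) / 2))
    if label == "U":
        return float(np.exp(lp + (np.log(top) - lp) / 4))
    # "D"
    return float(np.exp(lp + (np.log(bottom) - lp) / 4))


def _code_sequence(f0: np.ndarray, key: float, span: float
                   ) -> tuple[list[str], np.ndarray, float]:
    """Greedy left-to-right INTSINT coding for one (key, span)."""
    labels: list[str] = []
    preds = np.empty_like(f0)
    obj = 0.0
    prev: float | None = None
    logf = np.log(f0)
    for i, lf in enumerate(logf):
        choices = ABSOLUTE_LABELS if i == 0 else INTSINT_LABELS
        best_lab, best_pred, best_err = None, None, np.inf
        for lab in choices:
            p = intsint_predict(lab, prev, key, span)
            err = abs(np.log(p) - lf)
            if err < best_err:
                best_lab, best_pred, best_err = lab, p, err
        labels.append(best_lab)
        preds[i] = best_pred
        obj += best_err ** 2
        prev = best_pred
    return labels, preds, obj


def intsint_annotate(curve: MomelCurve,
                     key_steps: int = 50,
                     span_step: float = 0.05) -> IntsintAnnotation:
    """Fit key, span and per-MTP labels by grid search.

    Key candidates cover +-0.5 octave around the (geometric) mean MTP f0 in
    ``key_steps`` increments — the grid contains the mean itself, where the
    search originates; span candidates cover [0.5, 2.5] octaves in
    ``span_step`` increments.  Within each (key, span) the labels are assigned greedily
    left to right (first MTP restricted to the absolute levels), minimizing
    the absolute log-frequency error; the returned annotation minimizes the
    summed squared log error over the whole grid.
    """
    if len(curve) < 2:
        raise StylizationError("need at least 2 MTPs to annotate")
    f0 = curve.f0
    mean_f0 = float(np.exp(np.mean(np.log(f0))))
    exps = np.linspace(-0.5, 0.5, key_steps + 1)
    # stepwise search originating from the mean: try keys nearest the mean
    # first so exact ties resolve to the canonical mean-key coding
    exps = exps[np.argsort(np.abs(exps), kind="stable")]
    keys = mean_f0 * 2.0 ** exps
    spans = np.arange(0.5, 2.5 + 1e-9, span_step)
    kk, ss = np.meshgrid(keys, spans, indexing="ij")
    kk, ss = kk.ravel(), ss.ravel()
    # greedy coding vectorized over the whole (key, span) grid
    log_top = np.log(kk) + ss / 2 * np.log(2)
    log_bot = np.log(kk) - ss / 2 * np.log(2)
    log_key = np.log(kk)
    obj = np.zeros_like(kk)
    prev = None  # log predicted f0 of the previous MTP, per grid point
    for i, lf in enumerate(np.log(f0)):
        if prev is None:
            preds = np.stack([log_top, log_key, log_bot])
        else:
            preds = np.stack([
                log_top, (prev + log_top) / 2, prev + (log_top - prev) / 4,
                prev, log_key, prev + (log_bot - prev) / 4,
                (prev + log_bot) / 2, log_bot])
        errs = np.abs(preds - lf)
        pick = np.argmin(errs, axis=0)
        cols = np.arange(preds.shape[1])
        obj += errs[pick, cols] ** 2
        prev = preds[pick, cols]
    g = int(np.argmin(obj))
    labels, pred_f0, best_obj = _code_sequence(f0, float(kk[g]), float(ss[g]))
    return IntsintAnnotation(float(kk[g]), float(ss[g]), labels,
                             pred_f0, best_obj)


def mtps_to_csv(curve: MomelCurve, annotation: IntsintAnnotation | None,
                path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "f0_hz", "label"])
        labels = annotation.labels if annotation else [""] * len(curve)
        for m, lab in zip(curve.mtps, labels):
            w.writerow([f"{m.time_s:.4f}", f"{m.f0_hz:.3f}", lab])
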