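"""Voice-activity detection: split a recording into utterance-like spans.

The built-in detector is a frame-energy gate: frame RMS in dB (25 ms window,
10 ms hop), thresholded at ``max(noise floor + margin_db, floor_db)`` where
the noise floor is the 10th percentile of frame levels.  Supra-threshold
frames are merged across short gaps, short spans are dropped, and a small
pad is added at both ends.  A pretrained neural detector (e.g. an
overlap-aware segmentation model) can be plugged in via
:func:`register_external_vad`; its spans are validated and used verbatim.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .audio_io import AudioSignal, frame_signal

log = logging.getLogger(__name__)


@dataclass
class UtteranceSpan:
    start_s: float
    end_s: float
    recording_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid span [{self.start_s}, {self.end_s}]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class VadConfig:
    win_s: float = 0.025
    hop_s: float = 0.010
    margin_db: float = 12.0       # above the noise floor
    floor_db: float = -55.0       # absolute minimum threshold
    noise_percentile: float = 10.0
    max_gap_s: float = 0.3
    min_dur_s: float = 0.25
    pad_s: float = 0.05


def _frame_levels_db(sig: AudioSignal, cfg: VadConfig) -> tuple[np.ndarray, np.ndarray]:
    fs = frame_signal(sig, cfg.win_s, cfg.hop_s)
    ms = np.mean(fs.frames ** 2, axis=1)
    db = 10.0 * np.log10(np.maximum(ms, 1e-12))
    return fs.center_times, db


def detect_utterances(sig: AudioSignal,
                      cfg: VadConfig | None = None) -> list[UtteranceSpan]:
    """Detect utterance-like vocal-activity spans with the energy gate.

    Silence (nothing above threshold) yields an empty list, not an error.
    """
    cfg = cfg or VadConfig()
    if sig.duration_s < 0.1:
        raise ValueError("signal shorter than 0.1 s")
    times, db = _frame_levels_db(sig, cfg)
    noise_floor = float(np.percentile(db, cfg.noise_percentile))
    threshold = max(noise_floor + cfg.margin_db, cfg.floor_db)
    active = db > threshold
    if not active.any():
        return []
    # group active frames, merging gaps shorter than max_gap_s
    idx = np.flatnonzero(active)
    spans: list[list[float]] = []
    start = times[idx[0]]
    prev = times[idx[0]]
    for t in times[idx[1:]]:
        if t - prev > cfg.max_gap_s:
            spans.append([start, prev])
            start = t
        prev = t
    spans.append([start, prev])
    out = []
    for s, e in spans:
        s = max(0.0, s - cfg.pad_s)
        e = min(sig.duration_s, e + cfg.pad_s)
        if e - s >= cfg.min_dur_s:
            out.append(UtteranceSpan(s, e, sig.id))
    return out


VadCallable = Callable[[AudioSignal], Sequence[tuple[float, float]]]


def register_external_vad(fn: VadCallable) -> Callable[[AudioSignal], list[UtteranceSpan]]:
    """Wrap an external detector so the pipeline can consume its spans.

    The callable must return time-ordered, non-overlapping ``(start_s,
    end_s)`` pairs; they are validated and used verbatim.
    """

    def detector(sig: AudioSignal) -> list[UtteranceSpan]:
        raw = list(fn(sig))
        spans = []
        prev_end = -np.inf
        for s, e in raw:
            if e <= s:
                raise ValueError(f"reversed or empty span ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"overlapping span ({s}, {e})")
            prev_end = e
            spans.append(UtteranceSpan(max(0.0, s),
                                       min(sig.duration_s, e), sig.id))
        if not spans:
            log.warning("external VAD returned no spans for %s", sig.id)
        return spans

    return detector


def spans_to_csv(spans: Iterable[UtteranceSpan], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["recording_id", "start_s", "end_s"])
        for sp in spans:
            w.writerow([sp.recording_id, f"{sp.start_s:.6f}", f"{sp.end_s:.6f}"])
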