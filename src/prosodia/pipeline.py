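"""End-to-end feature extraction: recording -> per-utterance feature rows.

Stages: utterance detection (built-in energy VAD or a registered external
detector), two-pass f0 tracking, Momel stylization, INTSINT annotation,
per-MTP acoustic measurement (30 ms Hann window centered on each target),
and assembly of the 205-predictor battery.  Utterances that cannot be
analysed (unvoiced, too short, fewer than 2 MTPs, or an empty measurement
block) are dropped with a reason code rather than emitted partially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import acoustics, pitch, stylize, vad
from .audio_io import AudioSignal, frame_signal
from .features import (FEATURE_NAMES, ID_COLUMNS, FeatureVector,
                       TiltMeasures, UtteranceAnalysis, build_feature_vector)

log = logging.getLogger(__name__)

MTP_WINDOW_S = 0.030   # analysis window centered on each MTP


@dataclass
class ExtractionConfig:
    vad: vad.VadConfig = field(default_factory=vad.VadConfig)
    voicing_threshold: float = pitch.DEFAULT_VOICING_THRESHOLD
    mtp_window_s: float = MTP_WINDOW_S
    momel_window_s: float = 0.300
    momel_reduction_s: float = 0.200
    intsint_key_steps: int = 50
    intsint_span_step: float = 0.05


@dataclass
class SkippedUtterance:
    recording_id: str
    start_s: float
    end_s: float
    reason: str


def _mtp_frame(sig: AudioSignal, t: float, win_s: float) -> np.ndarray:
    half = int(round(win_s * sig.rate / 2))
    c = int(round(t * sig.rate))
    lo, hi = max(0, c - half), min(sig.samples.size, c + half)
    frame = np.zeros(2 * half)
    frame[lo - (c - half):lo - (c - half) + (hi - lo)] = sig.samples[lo:hi]
    return frame


def analyze_utterance(utt: AudioSignal, cfg: ExtractionConfig | None = None,
                      utterance_id: str = "", speaker_id: str = ""
                      ) -> UtteranceAnalysis:
    """Run pitch, stylization and acoustics on one utterance signal."""
    cfg = cfg or ExtractionConfig()
    track = pitch.estimate_f0(utt, voicing_threshold=cfg.voicing_threshold)
    curve = stylize.momel_targets(track, window_s=cfg.momel_window_s,
                                  reduction_s=cfg.momel_reduction_s)
    ann = stylize.intsint_annotate(curve, key_steps=cfg.intsint_key_steps,
                                   span_step=cfg.intsint_span_step)

    intensities = np.empty(len(curve))
    tilt: list[TiltMeasures] = []
    for i, mtp in enumerate(curve.mtps):
        frame = _mtp_frame(utt, mtp.time_s, cfg.mtp_window_s)
        intensities[i], _ = acoustics.intensity_db(frame)
        sl = acoustics.short_term_spectrum(frame, utt.rate, mtp.time_s)
        sl.f0_hz = mtp.f0_hz
        ser, _ = acoustics.ser_db(sl)
        l1, l2, l3 = acoustics.harmonic_levels(sl, mtp.f0_hz)
        formants = acoustics.estimate_formants(frame, utt.rate, mtp.f0_hz)
        l1c = acoustics.iseli_corrected_level(l1, mtp.f0_hz, formants, utt.rate)
        l2c = acoustics.iseli_corrected_level(l2, 2 * mtp.f0_hz, formants, utt.rate)
        l3c = (acoustics.iseli_corrected_level(l3, 3 * mtp.f0_hz, formants, utt.rate)
               if l3 is not None else None)
        c1, _ = acoustics.mfcc_c1(frame, utt.rate)
        slf = acoustics.spectral_poly_fit(sl, 1)[0]
        slf6d = acoustics.spectral_poly_fit(sl, 6)
        tilt.append(TiltMeasures(
            ser_db=ser,
            l2_l1_db=l2 - l1,
            l3_l1_db=(l3 - l1) if l3 is not None else np.nan,
            l2_l1_corr_db=l2c - l1c,
            l3_l1_corr_db=(l3c - l1c) if l3c is not None else np.nan,
            c1=c1, slf_slope=float(slf), slf6d=slf6d))

    # long-term average spectrum over 30 ms frames, 10 ms hop
    fs = frame_signal(utt, cfg.mtp_window_s, 0.010)
    from scipy.fft import rfft, rfftfreq
    from scipy.signal import get_window
    win = get_window("hann", fs.frames.shape[1], fftbins=True)
    mean_power = np.mean(np.abs(rfft(fs.frames * win, axis=1)) ** 2, axis=0)
    ltas = acoustics.SpectralSlice(
        rfftfreq(fs.frames.shape[1], 1.0 / utt.rate),
        10.0 * np.log10(mean_power + acoustics.EPS))
    ltas_ser, _ = acoustics.ser_db(ltas)
    # utterance intensity statistics cover the stylized region only, so
    # onset/offset ramps at the detected span edges do not set the minimum
    track_db = np.array([acoustics.intensity_db(f)[0] for f in fs.frames])
    lo, hi = curve.domain
    in_dom = (fs.center_times >= lo) & (fs.center_times <= hi)
    track_db = track_db[in_dom] if in_dom.any() else track_db
    track_db[track_db <= acoustics.SILENCE_FLOOR_DB] = np.nan

    return UtteranceAnalysis(
        utterance_id=utterance_id or utt.id,
        speaker_id=speaker_id,
        recording_id=utt.id,
        duration_s=utt.duration_s,
        curve=curve, annotation=ann,
        intensities_db=intensities, tilt=tilt,
        ltas_ser_db=ltas_ser, intensity_track_db=track_db)


def extract_recording(sig: AudioSignal, cfg: ExtractionConfig | None = None,
                      speaker_id: str = "",
                      detector: Callable[[AudioSignal], list[vad.UtteranceSpan]] | None = None,
                      ) -> tuple[list[FeatureVector], list[SkippedUtterance]]:
    """Detect utterances in a recording and extract one feature row each."""
    cfg = cfg or ExtractionConfig()
    spans = detector(sig) if detector else vad.detect_utterances(sig, cfg.vad)
    rows: list[FeatureVector] = []
    skipped: list[SkippedUtterance] = []
    for k, sp in enumerate(spans):
        utt_id = f"{sig.id}_u{k:03d}"
        try:
            utt = sig.slice(sp.start_s, sp.end_s)
            analysis = analyze_utterance(utt, cfg, utterance_id=utt_id,
                                         speaker_id=speaker_id)
            rows.append(build_feature_vector(analysis))
        except (pitch.UnvoicedUtteranceError, stylize.StylizationError,
                ValueError) as exc:
            skipped.append(SkippedUtterance(sig.id, sp.start_s, sp.end_s,
                                            str(exc)))
            log.info("skipped %s: %s", utt_id, exc)
    return rows, skipped


def feature_table(rows: list[FeatureVector],
                  labels: dict[str, int] | None = None) -> pd.DataFrame:
    """Feature rows as a DataFrame: id columns, 205 features, optional label.

    ``labels`` maps recording_id (or speaker_id) to an ordinal severity.
    """
    recs = []
    for fv in rows:
        rec = {"utterance_id": fv.utterance_id, "speaker_id": fv.speaker_id,
               "recording_id": fv.recording_id}
        rec.update(fv.values)
        if labels is not None:
            rec["label"] = labels.get(fv.recording_id,
                                      labels.get(fv.speaker_id))
        recs.append(rec)
    cols = ID_COLUMNS + FEATURE_NAMES + (["label"] if labels is not None else [])
    return pd.DataFrame(recs, columns=cols)
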