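"""Seeded synthetic speech so every pipeline stage is testable end to end.

Clinical speech recordings cannot be shared, so the corpus used for tests
and demonstrations is synthesized: a harmonic source follows the quadratic
interpolation of planted (time, f0) targets, a log-frequency tilt shapes
the harmonic amplitudes (time-varying between targets, which drives C1 and
the harmonic level differences), an optional resonator cascade adds
formants, a piecewise-linear dB envelope modulates intensity, and pauses
are inserted as silence.

The labelled corpus emulates the effect structure that severity ratings
track in dysprosodic speech: higher severity multiplies down (i) the SD of
f0 change between successive targets, (ii) the dynamic range of spectral
tilt (hence C1 dynamics) and (iii) the intensity range.  Labels are
assigned at the speaker level, mirroring per-recording clinical ratings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal
from .stylize import MomelCurve, MomelTargetPoint


@dataclass
class SynthSpec:
    planted_targets: list[tuple[float, float]]
    tilt_db_per_oct: float = -12.0
    tilt_targets: list[float] | None = None    # per-target tilt (optional)
    formants: list[tuple[float, float]] = field(
        default_factory=lambda: [(500.0, 80.0), (1500.0, 120.0), (2500.0, 160.0)])
    intensity_env: list[tuple[float, float]] | None = None  # (time_s, dB)
    pauses: list[tuple[float, float]] = field(default_factory=list)
    rate: int = 48000
    seed: int = 0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.planted_targets]
        if sorted(times) != times:
            raise ValueError("planted targets must be time-ordered")
        for _, f in self.planted_targets:
            if not (60.0 <= f <= 500.0):
                raise ValueError(f"target f0 {f} Hz outside [60, 500]")


@dataclass
class GroundTruth:
    planted_targets: list[tuple[float, float]]
    tilt_db_per_oct: float
    tilt_targets: list[float] | None
    intensity_env: list[tuple[float, float]] | None
    pauses: list[tuple[float, float]]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list)


def synth_utterance(spec: SynthSpec, utt_id: str = "synthetic"
                    ) -> tuple[AudioSignal, GroundTruth]:
    """Render one synthetic voiced utterance from its spec."""
    max_f0 = max(f for _, f in spec.planted_targets)
    if max_f0 > spec.rate / 4:
        raise ValueError("f0 above rate/4")
    t0 = spec.planted_targets[0][0]
    t1 = spec.planted_targets[-1][0]
    n = int(round((t1 + t0) * spec.rate))  # symmetric tail after last target
    t = np.arange(n) / spec.rate
    # f0 contour: quadratic interpolation through targets, held at the ends
    if len(spec.planted_targets) >= 2:
        curve = MomelCurve([MomelTargetPoint(tt, ff)
                            for tt, ff in spec.planted_targets])
        f0_t = np.empty(n)
        inside = (t >= t0) & (t <= t1)
        f0_t[inside] = curve(t[inside])
        f0_t[t < t0] = spec.planted_targets[0][1]
        f0_t[t > t1] = spec.planted_targets[-1][1]
    else:
        f0_t = np.full(n, spec.planted_targets[0][1])
    f0_t = np.clip(f0_t, 40.0, spec.rate / 4)
    phase = 2 * np.pi * np.cumsum(f0_t) / spec.rate
    # per-sample tilt (dB/octave), linearly interpolated between targets
    if spec.tilt_targets is not None:
        tt = np.array([p[0] for p in spec.planted_targets])
        tilt_t = np.interp(t, tt, np.asarray(spec.tilt_targets, dtype=float))
    else:
        tilt_t = np.full(n, spec.tilt_db_per_oct)
    # additive harmonic synthesis with tilt-shaped amplitudes
    n_harm = max(2, int(np.floor(0.45 * spec.rate / max_f0)))
    x = np.zeros(n)
    for k in range(1, n_harm + 1):
        amp = 10.0 ** (tilt_t * np.log2(k) / 20.0)
        x += amp * np.sin(k * phase)
    # resonator cascade (two-pole sections, unit DC gain)
    from scipy.signal import lfilter
    for F, B in spec.formants:
        if F >= spec.rate / 2:
            continue
        r = np.exp(-np.pi * B / spec.rate)
        theta = 2 * np.pi * F / spec.rate
        a = [1.0, -2 * r * np.cos(theta), r ** 2]
        g = sum(a)
        x = lfilter([g], a, x)
    # aspiration-noise floor (-45 dB re the voiced source) so the spectrum
    # has energy between harmonics, as in real phonation
    rng = np.random.default_rng(spec.seed)
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x = x + rng.normal(0.0, rms * 10.0 ** (-45.0 / 20.0), size=n)
    # normalize the source first so the envelope controls realized dB
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.35 / peak
    if spec.intensity_env is not None:
        et = np.array([p[0] for p in spec.intensity_env])
        ed = np.array([p[1] for p in spec.intensity_env])
        x *= 10.0 ** (np.interp(t, et, ed) / 20.0)
        x = np.clip(x, -1.0, 1.0)
    for start, dur in spec.pauses:
        i0, i1 = int(start * spec.rate), int((start + dur) * spec.rate)
        x[max(0, i0):min(n, i1)] = 0.0
    truth = GroundTruth(list(spec.planted_targets), spec.tilt_db_per_oct,
                        spec.tilt_targets,
                        list(spec.intensity_env) if spec.intensity_env else None,
                        list(spec.pauses))
    if not np.any(x):
        x[0] = 0.0  # keep a valid signal even for an all-silent envelope
    return AudioSignal(x, spec.rate, id=utt_id), truth


@dataclass
class CorpusSpec:
    n_speakers: int = 20
    utterances_per_speaker: int = 5
    proportions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    f0_step_effect: float = 0.5        # per severity step, on planted-step SD
    tilt_dyn_effect: float = 0.5       # per severity step, on tilt dynamics
    intensity_effect: float = 0.5      # per severity step, on intensity range
    base_f0_step_sd_oct: float = 0.22  # log2 scale, ~3.3 semitones
    base_tilt_db: float = -8.0         # mean source tilt, dB/octave
    base_tilt_dyn_db: float = 4.0      # SD of per-target tilt around the mean
    base_intensity_range_db: float = 18.0
    rate: int = 16000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("severity proportions must sum to 1")
        for eff in (self.f0_step_effect, self.tilt_dyn_effect,
                    self.intensity_effect):
            if not (0 < eff <= 1):
                raise ValueError("effect multipliers must lie in (0, 1]")


def strong_effects(**overrides) -> CorpusSpec:
    """Corpus spec for the strong-effect validation condition.

    Severity-2 speakers retain 0.3**2 = 9 % of the healthy f0-step SD
    (~0.3 semitones per step), tilt dynamics and intensity range — i.e.
    clinically overt monopitch/monoloudness — so end-to-end recovery of the
    planted class structure is expected of a sound pipeline.
    """
    return CorpusSpec(f0_step_effect=0.3, tilt_dyn_effect=0.3,
                      intensity_effect=0.3, **overrides)


@dataclass
class CorpusItem:
    signal: AudioSignal
    severity: int
    speaker_id: str
    truth: GroundTruth


def _speaker_severities(spec: CorpusSpec) -> list[int]:
    counts = [int(round(p * spec.n_speakers)) for p in spec.proportions]
    while sum(counts) > spec.n_speakers:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < spec.n_speakers:
        counts[int(np.argmin(counts))] += 1
    sev = [lab for lab, c in enumerate(counts) for _ in range(c)]
    return sev


def synth_corpus(spec: CorpusSpec) -> list[CorpusItem]:
    """Generate the labelled synthetic corpus (deterministic per seed)."""
    severities = _speaker_severities(spec)
    items: list[CorpusItem] = []
    for s_idx in range(spec.n_speakers):
        rng = np.random.default_rng([spec.seed, s_idx])
        severity = severities[s_idx]
        key = rng.uniform(100.0, 220.0)
        f0_sd = spec.base_f0_step_sd_oct * spec.f0_step_effect ** severity
        tilt_dyn = spec.base_tilt_dyn_db * spec.tilt_dyn_effect ** severity
        int_range = spec.base_intensity_range_db * spec.intensity_effect ** severity
        for u_idx in range(spec.utterances_per_speaker):
            n_targets = int(rng.integers(4, 10))
            gaps = rng.uniform(0.25, 0.45, size=n_targets - 1)
            times = 0.20 + np.concatenate([[0.0], np.cumsum(gaps)])
            # f0 walk on a log2 scale with reflecting bounds at +-0.7 oct;
            # reflection flips step signs only, so the planted step-SD
            # contrast between severity classes is preserved exactly
            x = 0.0
            xs = [0.0]
            for step in rng.normal(0.0, f0_sd, size=n_targets - 1):
                x += step
                while x > 0.7 or x < -0.7:
                    x = 1.4 - x if x > 0.7 else -1.4 - x
                xs.append(x)
            f0s = key * 2.0 ** np.array(xs)
            tilts = spec.base_tilt_db + rng.normal(0.0, tilt_dyn,
                                                   size=n_targets)
            tilts = np.clip(tilts, -16.0, -2.0)
            env_db = rng.uniform(-int_range / 2, int_range / 2,
                                 size=n_targets)
            # silent margins so utterance detection sees a noise floor
            margins = [(0.0, times[0] - 0.03),
                       (times[-1] + 0.03, times[0])]
            uspec = SynthSpec(
                planted_targets=list(zip(times.tolist(), f0s.tolist())),
                tilt_targets=tilts.tolist(),
                intensity_env=list(zip(times.tolist(), env_db.tolist())),
                formants=[(500.0, 80.0), (1500.0, 120.0), (2500.0, 160.0)],
                pauses=margins, rate=spec.rate, seed=spec.seed)
            sig, truth = synth_utterance(
                uspec, utt_id=f"spk{s_idx:03d}_utt{u_idx:02d}")
            items.append(CorpusItem(sig, severity, f"spk{s_idx:03d}", truth))
    return items


def write_manifest(items: list[CorpusItem], path: str,
                   wav_paths: list[str] | None = None) -> None:
    """Manifest CSV: path, speaker, severity, planted parameters as JSON."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "recording_id", "speaker_id", "severity",
                    "planted_json"])
        for i, it in enumerate(items):
            p = wav_paths[i] if wav_paths else f"{it.signal.id}.wav"
            w.writerow([p, it.signal.id, it.speaker_id, it.severity,
                        it.truth.to_json()])
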