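"""Shared fixtures: tone generators and the strong-effect synthetic corpus.

The corpus extraction and the end-to-end random-forest training are
expensive, so they run once per session and are shared by the synthesis,
model and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from prosodia import models as mdl
from prosodia import pipeline
from prosodia.audio_io import AudioSignal
from prosodia.features import FEATURE_NAMES
from prosodia.synth import strong_effects, synth_corpus


def make_sine(freq: float, dur_s: float, rate: int = 16000,
              amp: float = 0.5, phase: float = 0.0) -> AudioSignal:
    t = np.arange(int(dur_s * rate)) / rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t + phase), rate)


def make_sawtooth(freq: float, dur_s: float, rate: int = 16000,
                  amp: float = 0.5) -> AudioSignal:
    t = np.arange(int(dur_s * rate)) / rate
    phase = (freq * t) % 1.0
    return AudioSignal(amp * (2 * phase - 1), rate)


@pytest.fixture(scope="session")
def tone():
    return make_sine


@pytest.fixture(scope="session")
def sawtooth():
    return make_sawtooth


@pytest.fixture(scope="session")
def strong_corpus():
    """Strong-effect corpus (20 speakers x 5 utterances, seed 1)."""
    return synth_corpus(strong_effects(seed=1))


@pytest.fixture(scope="session")
def strong_corpus_features(strong_corpus):
    """Feature table of the strong-effect corpus plus planted ground truth.

    Returns (table, planted) where planted maps recording_id to the SD of
    the planted log2 f0 steps.
    """
    rows, labels, planted = [], {}, {}
    for it in strong_corpus:
        r, _ = pipeline.extract_recording(it.signal, speaker_id=it.speaker_id)
        rows.extend(r)
        labels[it.signal.id] = it.severity
        f0s = [f for _, f in it.truth.planted_targets]
        planted[it.signal.id] = float(np.diff(np.log2(f0s)).std(ddof=1))
    table = pipeline.feature_table(rows, labels)
    # severity is a speaker-level rating: split/group at the speaker level
    table["recording_id"] = table["speaker_id"]
    return table, planted


@pytest.fixture(scope="session")
def e2e_models(strong_corpus_features):
    """Tuned random forest + f0-SD baseline evaluated on held-out speakers."""
    table, _ = strong_corpus_features
    train, test = mdl.stratified_split(table, 0.25, seed=1)
    y = train["label"].to_numpy(int)
    yt = test["label"].to_numpy(int)
    Xf, _ = mdl.filter_correlated(train[FEATURE_NAMES], y)
    cols = list(Xf.columns)
    grid = mdl.TuningGrid("random_forest", {
        "n_trees": mdl.ParamRange(100, 500, "int"),
        "mtry": mdl.ParamRange(1, 74, "int"),
        "min_node": mdl.ParamRange(2, 40, "int")}, n_candidates=20, seed=1)
    tuned = mdl.tune_cv("random_forest", Xf.to_numpy(), y, grid=grid, k=10,
                        seed=1, groups=train["recording_id"].to_numpy())
    rf = mdl.average_fold_models(tuned)
    rf_pred = rf.predict(test[cols].to_numpy())
    baseline = mdl.baseline_f0sd_model(train[["mtp_f0_sd"]].to_numpy(), y)
    bl_pred = baseline.predict(test[["mtp_f0_sd"]].to_numpy())
    return {"truth": yt, "rf_pred": rf_pred, "baseline_pred": bl_pred,
            "tuned": tuned, "train": train, "test": test, "kept": cols}
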