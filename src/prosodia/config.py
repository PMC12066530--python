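"""Pipeline configuration: YAML file with one section per module.

Unknown sections or keys are rejected (fail-fast) and a config round-trips
through the file losslessly.  Every default is the module's own documented
design choice; the config only overrides them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .pipeline import ExtractionConfig
from .vad import VadConfig


@dataclass
class ModelConfig:
    n_candidates: int = 1000
    cv_folds: int = 10
    test_fraction: float = 0.25
    rho_threshold: float = 0.9
    firm_bins: int = 10
    seed: int = 0


@dataclass
class PipelineConfig:
    vad: VadConfig = field(default_factory=VadConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        self.extraction.vad = self.vad

    def to_dict(self) -> dict:
        d = {"vad": asdict(self.vad), "model": asdict(self.model),
             "extraction": asdict(self.extraction)}
        d["extraction"].pop("vad")
        return d

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _apply(obj, section: str, data: dict) -> None:
    valid = {f.name for f in fields(obj)}
    for key, val in data.items():
        if key not in valid or key == "vad":
            raise ValueError(f"unknown config key {section}.{key}")
        setattr(obj, key, val)


def load_config(path: str | None) -> PipelineConfig:
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sections = {"vad": cfg.vad, "extraction": cfg.extraction,
                "model": cfg.model}
    for section, payload in data.items():
        if section not in sections:
            raise ValueError(f"unknown config section {section!r}")
        _apply(sections[section], section, payload or {})
    cfg.extraction.vad = cfg.vad
    return cfg
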