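"""Run configuration: one YAML file covering every pipeline stage.

Sections map one-to-one onto the stage config dataclasses; unknown
sections or keys are rejected rather than ignored, and the effective
(merged) configuration is echoed into every JSON report so a run can be
reproduced from its output alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectorConfig
from .postprocess import PostprocessConfig
from .spectrogram import SpectrogramParams
from .synthetic import AnnotatorNoise, BreathingProfile

__all__ = ["RunConfig", "load_config"]

_SECTIONS = {
    "spectrogram": SpectrogramParams,
    "detector": DetectorConfig,
    "postprocess": PostprocessConfig,
    "profile": BreathingProfile,
    "annotator_noise": AnnotatorNoise,
}


@dataclass(frozen=True)
class RunConfig:
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    profile: BreathingProfile = field(default_factory=BreathingProfile)
    annotator_noise: AnnotatorNoise = field(default_factory=AnnotatorNoise)
    seed: int = 0

    def as_dict(self) -> dict:
        out = {name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS}
        out["seed"] = self.seed
        return out


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file and apply keyword overrides.

    ``overrides`` are dotted flat keys, e.g. ``postprocess__confidence_threshold``
    (double underscore as the section separator) or plain ``seed``.
    Unknown sections/keys raise ValueError.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        raw = loaded

    sections: dict[str, dict] = {name: {} for name in _SECTIONS}
    seed = 0
    for key, value in raw.items():
        if key == "seed":
            seed = int(value)
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            sections[key].update(value)
        else:
            raise ValueError(f"unknown config section {key!r}")

    for key, value in overrides.items():
        if value is None:
            continue
        if key == "seed":
            seed = int(value)
            continue
        if "__" not in key:
            raise ValueError(f"unknown config override {key!r}")
        section, _, leaf = key.partition("__")
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        sections[section][leaf] = value

    built = {}
    for name, cls in _SECTIONS.items():
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(sections[name]) - valid
        if bad:
            raise ValueError(
                f"unknown keys in config section {name!r}: {sorted(bad)}"
            )
        built[name] = cls(**sections[name])
    return RunConfig(seed=seed, **built)
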