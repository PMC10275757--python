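"""Run configuration and built-in presets.

Presets mirror the three transducers the stimulation experiments used; a
:class:`RunConfig` selects pipeline stages, a preset, a seed and an output
directory, and round-trips losslessly through YAML.  Unknown keys are
rejected with every violation reported at once.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .acoustics import AcousticMedium, TransducerSpec

__all__ = [
    "RunConfig",
    "load_config",
    "get_preset",
    "preset_names",
    "get_medium",
]


@lru_cache(maxsize=1)
def _presets() -> dict:
    text = resources.files("sonosim").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_names() -> list[str]:
    return sorted(_presets()["transducers"])


def get_preset(name: str, source_amplitude: float = 1.0) -> TransducerSpec:
    """Built-in transducer preset by name ('0.5MHz', '2.25MHz', '15MHz')."""
    try:
        entry = _presets()["transducers"][name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return TransducerSpec(
        center_frequency=float(entry["center_frequency"]),
        aperture_diameter=float(entry["aperture_diameter"]),
        radius_of_curvature=float(entry["radius_of_curvature"]),
        source_amplitude=source_amplitude,
    )


def preset_pressure_range(name: str) -> tuple[float, float]:
    lo, hi = _presets()["transducers"][name]["pressure_range"]
    return float(lo), float(hi)


def get_medium(name: str = "water") -> AcousticMedium:
    entry = _presets()["media"][name]
    return AcousticMedium(**{k: float(v) for k, v in entry.items()})


class RunConfig(BaseModel):
    """Validated pipeline configuration (extra keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    stages: list[str] = Field(default_factory=lambda: ["generate", "analyze"])
    preset: str = "15MHz"
    seed: int = 0
    outdir: str = "sonosim-run"
    log_level: str = "INFO"
    overrides: dict[str, float] = Field(default_factory=dict)

    def model_post_init(self, _ctx) -> None:
        known = {"generate", "analyze", "field", "heat"}
        bad = [s for s in self.stages if s not in known]
        if bad:
            raise ValueError(
                f"unknown stages {bad}; valid stages: {sorted(known)}"
            )
        if self.preset not in preset_names():
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {preset_names()}"
            )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the defaults; schema violations are reported all at
    once (one line per offending key).
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in err.errors()
        ]
        raise ValueError(
            "invalid configuration:\n" + "\n".join(lines)
        ) from err
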