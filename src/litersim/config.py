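"""Configuration schema, YAML/JSON round-trip and run manifests.

A :class:`RunConfig` is validated before any computation; unknown keys are
rejected so typos fail loudly.  CSV is the lingua franca between pipeline
stages, and every output directory gets a manifest JSON sufficient to re-run
the command bit-identically (config, seeds, package version, circuit hash).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .circuits import build_circuit
from .light import LightProgram
from .network import CircuitSpec
from .params import RateParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CircuitConfig(_Strict):
    architecture: str
    variant: str = "tip"
    params: dict[str, float | int] = Field(default_factory=dict)

    def build(self) -> CircuitSpec:
        return build_circuit(self.architecture, self.variant, RateParams.from_dict(self.params) if self.params else None)


class LightConfig(_Strict):
    kind: str = "constant"
    intensity: float = 0.0
    pulse_duration_min: float | None = None
    period_h: float = 1.0
    duty_fraction: float | None = None
    total_duration_h: float = 72.0

    def build(self) -> LightProgram:
        if self.kind == "constant":
            return LightProgram.constant(self.intensity, self.total_duration_h)
        if self.kind == "single_pulse":
            if self.pulse_duration_min is None:
                raise ValueError("single_pulse requires pulse_duration_min")
            return LightProgram.single_pulse(self.intensity, self.pulse_duration_min, self.total_duration_h)
        if self.kind == "duty_cycle":
            if self.duty_fraction is None:
                raise ValueError("duty_cycle requires duty_fraction")
            return LightProgram.duty_cycle(self.intensity, self.duty_fraction, self.period_h, self.total_duration_h)
        raise ValueError(f"unknown light kind {self.kind!r}")


class EngineConfig(_Strict):
    engine: str = "deterministic"
    n_runs: int = 10_000
    seed: int | None = None
    t_end_h: float | None = None

    @field_validator("engine")
    @classmethod
    def _engine_known(cls, v):
        if v not in ("deterministic", "stochastic"):
            raise ValueError(f"engine must be deterministic or stochastic, got {v!r}")
        return v


class AnalysisConfig(_Strict):
    fit_hill: bool = True
    fit_linear: bool = True
    linear_dose_max: float = 225.0
    n_boot: int = 1000
    fold_change: bool = True


class RunConfig(_Strict):
    circuit: CircuitConfig
    light: LightConfig = Field(default_factory=LightConfig)
    engine: EngineConfig = Field(default_factory=EngineConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output_dir: str = "litersim_out"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # JSON is a YAML subset
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


# -- circuit spec round-trip ------------------------------------------------

def circuit_to_dict(spec: CircuitSpec) -> dict:
    return {
        "architecture": spec.architecture,
        "variant": spec.variant,
        "params": spec.params.to_dict(),
    }


def circuit_from_dict(d: dict) -> CircuitSpec:
    return build_circuit(d["architecture"], d["variant"], RateParams.from_dict(d["params"]))


def write_circuit(spec: CircuitSpec, path: str | Path) -> None:
    """Lossless circuit round-trip file (YAML); networks rebuild identically."""
    Path(path).write_text(yaml.safe_dump(circuit_to_dict(spec), sort_keys=False))


def read_circuit(path: str | Path) -> CircuitSpec:
    return circuit_from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(out_dir: str | Path, payload: dict) -> Path:
    """Write the reproducibility manifest for one command invocation."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("litersim")
    except PackageNotFoundError:
        ver = "unknown"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    path.write_text(json.dumps({"litersim_version": ver, **payload}, indent=2, sort_keys=True))
    return path
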