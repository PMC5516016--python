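"""Run configuration: schema-validated YAML/JSON with full defaulting."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1


@dataclass
class SynthConfig:
    preset: str = "visual_imagery"
    n_subjects: int = 12
    n_trials: int = 40
    tr: float = 2.0
    dt: float = 0.1
    imagery_drive_occ: bool = False


@dataclass
class InversionConfig:
    tol: float = 1e-3
    max_iter: int = 96
    estimate_noise: bool = True
    estimate_hemo: bool = True


@dataclass
class PriorConfig:
    a_variance: float = 1.0 / 16.0
    b_variance: float = 1.0 / 16.0
    c_variance: float = 1.0
    self_variance: float = 1.0 / 16.0
    hemo_variance: float = 1.0 / 256.0


@dataclass
class PEBConfig:
    between_variance: float = 1.0 / 16.0
    gamma_prior_var: float = 1.0 / 16.0
    pp_threshold: float = 0.95


@dataclass
class ContrastConfig:
    equal_weights: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "visdcm-out"
    dataset_path: str | None = None     # analyse an existing study directory
    synth: SynthConfig = field(default_factory=SynthConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    peb: PEBConfig = field(default_factory=PEBConfig)
    contrast: ContrastConfig = field(default_factory=ContrastConfig)
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "synth": SynthConfig,
    "inversion": InversionConfig,
    "priors": PriorConfig,
    "peb": PEBConfig,
    "contrast": ContrastConfig,
}


def _build(raw: dict, strict: bool) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    errors: list[str] = []
    top_known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - top_known
    if unknown and strict:
        errors.extend(f"unknown key: {k}" for k in sorted(unknown))
    kwargs: dict = {}
    for key in ("seed", "out_dir", "dataset_path", "schema_version"):
        if key in raw:
            kwargs[key] = raw[key]
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            errors.append(f"section {name!r} must be a mapping")
            continue
        known = set(cls.__dataclass_fields__)
        bad = set(section) - known
        if bad and strict:
            errors.extend(f"unknown key: {name}.{k}" for k in sorted(bad))
        kwargs[name] = cls(**{k: v for k, v in section.items() if k in known})
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = RunConfig(**kwargs)
    if cfg.schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {cfg.schema_version}")
    if cfg.synth.n_subjects < 1 or cfg.synth.n_trials < 0:
        raise ValueError("invalid config: synth sizes must be positive")
    return cfg


def load_config(path, strict: bool = False) -> RunConfig:
    """Load and validate a YAML or JSON run configuration, applying defaults."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build(raw or {}, strict)


def save_config(cfg: RunConfig, path) -> None:
    """Echo the fully defaulted configuration (round-trips to an equal config)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
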