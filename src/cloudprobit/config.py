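"""Pipeline configuration: one YAML file, one master seed, strict keys."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .probit import ModelSpec
from .sampler import SamplerConfig
from .synthetic import GeneratorConfig, WeatherProcess


@dataclass
class ReportConfig:
    cri_level: float = 0.95
    mem_threshold: int = 3
    mem_delta: float = 1.0
    n_ppc: int = 200
    make_figures: bool = True


@dataclass
class PipelineConfig:
    """Nested configuration for the simulate -> fit -> report pipeline.

    The master ``seed`` drives every stage: the generator uses ``seed`` and
    the sampler ``seed + 1`` (kept below 2**31), so one flag reproduces the
    whole run.
    """

    seed: int
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    def __post_init__(self):
        self.generator = dataclasses.replace(self.generator, seed=int(self.seed))
        self.sampler = dataclasses.replace(self.sampler,
                                           seed=int(self.seed + 1) % (2 ** 31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["weather"] = {k: asdict(v) if not isinstance(v, dict) else v
                                     for k, v in self.generator.weather.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict, seed_override: int | None = None) -> "PipelineConfig":
        d = dict(d or {})
        known = {"seed", "generator", "model", "sampler", "report"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        seed = seed_override if seed_override is not None else d.get("seed")
        if seed is None:
            raise ConfigurationError("missing required field: seed")
        gen = _build(GeneratorConfig, d.get("generator", {}), "generator")
        model = _build(ModelSpec, d.get("model", {}), "model")
        sampler = _build(SamplerConfig, d.get("sampler", {}), "sampler")
        report = _build(ReportConfig, d.get("report", {}), "report")
        return cls(seed=int(seed), generator=gen, model=model,
                   sampler=sampler, report=report)

    @classmethod
    def from_yaml(cls, path, seed_override: int | None = None) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            d = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
        return cls.from_dict(d, seed_override=seed_override)


def _build(cls, block: dict, name: str):
    if not isinstance(block, dict):
        raise ConfigurationError(f"config block {name!r} must be a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigurationError(f"unknown keys in {name!r}: {sorted(unknown)}")
    kwargs = dict(block)
    for key in ("gamma", "cutpoints", "random_effect_sd", "followup_iqr",
                "belief_probs"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cls is GeneratorConfig and "weather" in kwargs:
        procs = {}
        for var, sub in kwargs["weather"].items():
            if isinstance(sub, WeatherProcess):
                procs[var] = sub
                continue
            wfields = {f.name for f in dataclasses.fields(WeatherProcess)}
            bad = set(sub) - wfields
            if bad:
                raise ConfigurationError(
                    f"unknown keys in generator.weather.{var}: {sorted(bad)}")
            procs[var] = WeatherProcess(**sub)
        kwargs["weather"] = procs
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"invalid {name!r} block: {exc}") from exc


def load_preset(name: str) -> dict:
    """Load a bundled preset config as a dict ('smoke', 'default', 'paper-scale')."""
    from importlib import resources
    fname = f"{name}.yaml"
    ref = resources.files("cloudprobit") / "presets" / fname
    if not ref.is_file():
        raise ConfigurationError(f"unknown preset {name!r}")
    return yaml.safe_load(ref.read_text())
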