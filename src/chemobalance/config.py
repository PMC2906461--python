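"""Schema-validated YAML configuration.

Unknown keys are rejected (listing every offender), physical bounds are
enforced by the underlying dataclasses, and defaults documented on those
dataclasses are applied for anything omitted.  A missing genome size loads
successfully but emits a provenance warning, since the packaged defaults come
from public genome records rather than the experiment at hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .chemostat import BiomassCalibration, ReactorConfig
from .qpcr import DEFAULT_ASSAYS, SpeciesAssay
from .simulate import NoiseModel
from .trophic import DEFAULT_DIGESTIBLE, AllocationSplits

__all__ = ["ConfigError", "PipelineConfig", "load_config", "default_config", "reference_config_path"]


class ConfigError(ValueError):
    """Configuration schema violation; carries the offending keys."""

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = keys or []


@dataclass(frozen=True)
class PipelineConfig:
    reactor: ReactorConfig = field(default_factory=ReactorConfig)
    calibration: BiomassCalibration = field(default_factory=BiomassCalibration)
    assays: Mapping[str, SpeciesAssay] = field(default_factory=lambda: dict(DEFAULT_ASSAYS))
    splits: AllocationSplits = field(default_factory=AllocationSplits)
    noise: NoiseModel = field(default_factory=NoiseModel)
    digestible: frozenset[str] = DEFAULT_DIGESTIBLE
    energy_weights: Mapping[str, float] = field(default_factory=dict)
    od600: float = 0.4


def default_config() -> PipelineConfig:
    return PipelineConfig()


def reference_config_path() -> Path:
    """Path of the packaged reference configuration."""
    return Path(resources.files("chemobalance") / "data" / "reference_config.yaml")


def _build(cls, section: Mapping[str, Any], name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {unknown}", unknown)
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values in section {name!r}: {exc}") from exc


def _build_assays(section: Mapping[str, Any]) -> dict[str, SpeciesAssay]:
    assays: dict[str, SpeciesAssay] = {}
    for species, spec in section.items():
        if not isinstance(spec, Mapping):
            raise ConfigError(f"assay entry for {species!r} must be a mapping")
        allowed = {"rrn_copies_per_genome", "genome_size_bp", "primer_forward", "primer_reverse"}
        unknown = sorted(set(spec) - allowed)
        if unknown:
            raise ConfigError(f"unknown keys in assay {species!r}: {unknown}", unknown)
        spec = dict(spec)
        default = DEFAULT_ASSAYS.get(species)
        genome_default = False
        if "genome_size_bp" not in spec:
            if default is None:
                raise ConfigError(f"assay {species!r} needs genome_size_bp (no default known)")
            spec["genome_size_bp"] = default.genome_size_bp
            genome_default = True
            warnings.warn(
                f"assay {species!r}: genome_size_bp not configured; using the "
                "packaged default from public genome records",
                stacklevel=3,
            )
        if "rrn_copies_per_genome" not in spec:
            if default is None:
                raise ConfigError(f"assay {species!r} needs rrn_copies_per_genome")
            spec["rrn_copies_per_genome"] = default.rrn_copies_per_genome
        try:
            assays[species] = SpeciesAssay(
                species=species, genome_size_is_default=genome_default, **spec
            )
        except ValueError as exc:
            raise ConfigError(f"invalid assay {species!r}: {exc}") from exc
    return assays


_SECTIONS = {"reactor", "calibration", "assays", "splits", "noise", "digestible",
             "energy_weights", "od600"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    unknown = sorted(set(raw) - _SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {unknown}", unknown)

    kwargs: dict[str, Any] = {}
    if "reactor" in raw:
        kwargs["reactor"] = _build(ReactorConfig, raw["reactor"], "reactor")
    if "calibration" in raw:
        kwargs["calibration"] = _build(BiomassCalibration, raw["calibration"], "calibration")
    if "splits" in raw:
        kwargs["splits"] = _build(AllocationSplits, raw["splits"], "splits")
    if "noise" in raw:
        kwargs["noise"] = _build(NoiseModel, raw["noise"], "noise")
    if "assays" in raw:
        kwargs["assays"] = _build_assays(raw["assays"])
    if "digestible" in raw:
        kwargs["digestible"] = frozenset(raw["digestible"])
    if "energy_weights" in raw:
        kwargs["energy_weights"] = dict(raw["energy_weights"])
    if "od600" in raw:
        od = float(raw["od600"])
        if od < 0:
            raise ConfigError("od600 must be non-negative")
        kwargs["od600"] = od
    return PipelineConfig(**kwargs)
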