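"""Run configuration: every tunable of the pipeline in one versioned record.

Defaults are the screen's canonical constants: the CH blood-VAF window
(2%, 25%), tumor-cohort frequency floor 5%, population-frequency ceiling
0.01%, dichotomization cutoff grid 0.00-0.30 in steps of 0.01, class weights
{0: 1, 1: 4}, probability cut-point 0.5, and 1000 bootstrap resamples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    # synthetic cohorts
    n_variants: int = 500
    panel_size: int = 98
    n_discovery_patients: int = 600
    min_alt_reads: int = 3
    # panel thresholds
    vaf_low: float = 0.02
    vaf_high: float = 0.25
    tumor_freq_min: float = 0.05
    popfreq_max: float = 1e-4
    expression_min_fraction: float = 0.01
    sift_max: float = 0.05
    polyphen_min: float = 0.446
    # split
    test_frac: float = 0.25
    val_frac: float = 0.25
    # grid
    cutoff_start: float = 0.0
    cutoff_stop: float = 0.30
    cutoff_step: float = 0.01
    class_weight_options: list = field(
        default_factory=lambda: [{0: 1, 1: 1}, {0: 1, 1: 4}]
    )
    l2_options: list = field(default_factory=lambda: [1.0])
    # model
    tol: float = 1e-8
    max_iter: int = 2000
    cutpoint: float = 0.5
    # inference
    bootstrap_B: int = 1000
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        for name in (
            "vaf_low", "vaf_high", "tumor_freq_min", "popfreq_max",
            "expression_min_fraction", "sift_max", "polyphen_min",
            "test_frac", "val_frac", "cutpoint",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.vaf_low >= self.vaf_high:
            raise ConfigError("vaf_low must be below vaf_high")
        if self.bootstrap_B < 2:
            raise ConfigError("bootstrap_B must be >= 2")
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported config schema version {self.schema_version}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are an error."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ConfigError(f"{path}: cannot parse YAML: {exc}") from exc
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "class_weight_options" in raw:
        raw["class_weight_options"] = [
            {int(k): v for k, v in cw.items()} for cw in raw["class_weight_options"]
        ]
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
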