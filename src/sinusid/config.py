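"""Run configuration: every tunable of the pipeline in one serializable
object, so a cohort run is reproducible from (config, seed) alone."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .akaze import AkazeParams
from .orb import OrbParams
from .synth import CovariateSpec, SynthParams

METHODS = ("akaze", "orb", "both")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    method: str = "both"
    seed: int = 0
    n_cases: int = 60
    symmetric_scores: bool = False
    log_level: str = "INFO"
    synth: SynthParams = field(default_factory=SynthParams)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    orb: OrbParams = field(default_factory=OrbParams)
    akaze: AkazeParams = field(default_factory=AkazeParams)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        # the root seed flows into the generator
        if self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    def methods(self) -> tuple[str, ...]:
        return ("akaze", "orb") if self.method == "both" else (self.method,)

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"]["age_range"] = list(d["covariates"]["age_range"])
        d["covariates"]["interval_range"] = list(d["covariates"]["interval_range"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("synth", SynthParams), ("covariates", CovariateSpec),
                         ("orb", OrbParams), ("akaze", AkazeParams)):
            if key in data and isinstance(data[key], dict):
                sub_known = {f.name for f in fields(sub)}
                sub_unknown = set(data[key]) - sub_known
                if sub_unknown:
                    raise ConfigError(f"unknown keys in config section {key!r}: {sorted(sub_unknown)}")
                payload = dict(data[key])
                for rng_key in ("age_range", "interval_range"):
                    if rng_key in payload:
                        payload[rng_key] = tuple(payload[rng_key])
                data[key] = sub(**payload)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the full configuration (for provenance records)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
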