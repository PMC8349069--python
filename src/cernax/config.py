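"""Pipeline configuration: a nested YAML document with CLI overrides.

Exactly one of ``simulate`` (a cohort-generator block) or ``inputs``
(paths to the six cohort files) must be present.  A single top-level
seed drives every source of randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .screen import ScreenThresholds
from .simulate import CohortConfig

_INPUT_KEYS = ("counts", "samples", "transcripts", "utr3", "mirna", "genesets")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cernax_out"
    simulate: CohortConfig | None = None
    inputs: dict[str, str] | None = None
    fc_threshold: float = 1.0
    deg_alpha: float = 0.05
    paired: bool = False
    r_threshold: float = 0.45
    corr_alpha: float = 0.05
    ora_alpha: float = 0.05
    terms: tuple[str, str] = ("adhesion-like", "epidermis-like")
    mre_weights: dict[str, float] | None = None
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    clinical_gene: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "simulate/inputs", "exactly one of the two blocks must be set"
            )
        if self.inputs is not None:
            missing = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ConfigurationError("inputs", f"missing paths: {missing}")
        for name in ("deg_alpha", "corr_alpha", "ora_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(name, "must be in (0, 1)")
        if self.fc_threshold < 0:
            raise ConfigurationError("fc_threshold", "must be >= 0")
        if not (0.0 <= self.r_threshold < 1.0):
            raise ConfigurationError("r_threshold", "must be in [0, 1)")
        if len(self.terms) != 2:
            raise ConfigurationError("terms", "exactly two term ids required")
        self.screen.validate()
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulate", None)
        scr = data.pop("screen", None)
        terms = data.pop("terms", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration key")
        cfg = cls(**data)
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", cfg.seed)
            bad = set(sim) - set(CohortConfig.__dataclass_fields__)
            if bad:
                raise ConfigurationError(
                    f"simulate.{sorted(bad)[0]}", "unknown configuration key"
                )
            cfg.simulate = CohortConfig(**sim)
            cfg.simulate.seed = cfg.seed
        if scr is not None:
            bad = set(scr) - set(ScreenThresholds.__dataclass_fields__)
            if bad:
                raise ConfigurationError(
                    f"screen.{sorted(bad)[0]}", "unknown configuration key"
                )
            cfg.screen = ScreenThresholds(**scr)
        if terms is not None:
            cfg.terms = tuple(terms)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["terms"] = list(self.terms)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()
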