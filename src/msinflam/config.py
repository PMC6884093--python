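"""Pipeline configuration: YAML round-trip, validation, hashing."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .panel import BiomarkerSpec, default_panel, panel_map

DEFAULT_GROUPING = {"HD": "HD", "RRMS": "RRMS", "PPMS": "PMS", "SPMS": "PMS"}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All analysis choices, with the published defaults baked in."""

    panel: list[BiomarkerSpec] = field(default_factory=default_panel)
    grouping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPING))
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "race"])
    covariate_interactions: bool = True
    selection_alpha: float = 0.05
    lambda_range: tuple[float, float] = (-3.0, 3.0)
    lambda_step: float = 0.01
    fixed_lambdas: dict[str, float] | None = None
    cluster_mode: str = "frozen"          # "frozen" | "derived"
    derive_csf: bool = False              # data-driven CSF split is opt-in
    r_threshold: float = 0.3
    icc_flag_threshold: float = 0.8
    alpha: float = 0.05
    severity_cols: list[str] = field(default_factory=lambda: ["msss", "armss", "msdss"])
    subcohorts: list[str] = field(default_factory=lambda: ["MS", "RRMS", "PMS"])
    seed: int = 0

    def validate(self) -> None:
        panel_map(self.panel)  # raises on duplicates
        if self.cluster_mode not in ("frozen", "derived"):
            raise ConfigError(f"cluster_mode must be frozen|derived, got {self.cluster_mode!r}")
        if not (0 < self.alpha < 1) or not (0 < self.selection_alpha < 1):
            raise ConfigError("alpha values must lie in (0, 1)")
        if not (0 <= self.r_threshold <= 1):
            raise ConfigError("r_threshold must lie in [0, 1]")
        for c in self.covariates:
            if not isinstance(c, str):
                raise ConfigError("covariates must be column names")
        for s in self.subcohorts:
            if s not in ("MS", "RRMS", "PMS", "HD"):
                raise ConfigError(f"unknown subcohort {s!r}")
        known = set(self.grouping)
        for d in ("HD", "RRMS", "PPMS", "SPMS"):
            if d not in known:
                raise ConfigError(f"grouping map must cover diagnosis {d!r}")
        if self.fixed_lambdas:
            pm = panel_map(self.panel)
            for a in self.fixed_lambdas:
                if a not in pm:
                    raise ConfigError(f"fixed_lambdas references unknown analyte {a!r}")

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = [asdict(s) for s in self.panel]
        d["lambda_range"] = list(self.lambda_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "panel" in d:
            d["panel"] = [BiomarkerSpec(**s) for s in d["panel"]]
        if "lambda_range" in d:
            d["lambda_range"] = tuple(d["lambda_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
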