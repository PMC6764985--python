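"""Pipeline configuration.

Defaults follow the study protocol where it states one: 6-h regularization
step, a 36 deg S latitude cut for the behavioural analysis, and 100 track
realizations for multiple imputation.  Everything is overridable from a YAML
file or CLI flags.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .params import DEFAULT_ARGOS_ERROR_SD_KM


@dataclass
class PipelineConfig:
    step_hours: float = 6.0
    lat_cut: float = -36.0
    m_realizations: int = 100
    n_restarts: int = 10
    seed: int = 0
    error_sd_km: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_ERROR_SD_KM))
    area_file: str | None = None  # None -> packaged simplified areas
    gap_split_days: float = 7.0
    configs: tuple = (1, 2, 3, 4)
    criterion: str = "aic"
    min_locs: int = 10

    def validate(self):
        if self.step_hours <= 0:
            raise ValueError("step_hours must be positive")
        if self.m_realizations < 1:
            raise ValueError("m_realizations must be >= 1")
        if not set(self.configs) <= {1, 2, 3, 4}:
            raise ValueError("configs must be a subset of {1,2,3,4}")
        if self.criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.configs, list):
            cfg.configs = tuple(cfg.configs)
        return cfg.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["configs"] = list(self.configs)
        return d

    def hash(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
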