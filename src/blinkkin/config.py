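"""Pipeline configuration: one validated record of every tunable, with a
stable hash that output files embed so any result can be traced to the exact
settings that produced it."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from .errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every tunable of the extract → segment → features → stats → classify
    pipeline, with the study-anchored defaults."""

    fps: float = 240.0
    roi: tuple | None = None  # (row_start, row_stop, col_start, col_stop)
    pre_s: float = 0.25
    post_s: float = 0.4625
    min_prominence_frac: float = 0.5
    min_separation_s: float = 0.5
    spline_p: float = 0.99996
    normalize: str = "minmax"
    zero_tol: float = 0.01
    sustain: int = 3
    discard_indices: tuple = (10, 21, 26)
    classifier: str = "lda"
    scheme: str = "kfold"
    n_folds: int = 10
    beta: int = 10
    n_boot: int = 100
    beta_mode: str = "average-of-features"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if not 0 <= self.spline_p <= 1:
            raise ConfigError(f"spline_p must be in [0, 1], got {self.spline_p}")
        if self.normalize not in ("minmax", "maxdiv"):
            raise ConfigError(f"normalize must be minmax|maxdiv, got {self.normalize}")
        if self.scheme not in ("kfold", "loo"):
            raise ConfigError(f"scheme must be kfold|loo, got {self.scheme}")
        if self.roi is not None:
            self.roi = tuple(int(v) for v in self.roi)
            if len(self.roi) != 4:
                raise ConfigError("roi must have 4 entries (r0, r1, c0, c1)")
        self.discard_indices = tuple(int(i) for i in self.discard_indices)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi"] = list(self.roi) if self.roi is not None else None
        d["discard_indices"] = list(self.discard_indices)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
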