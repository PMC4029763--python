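"""Run configuration: one serialisable object per end-to-end run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .approaches import (
    DEFAULT_HIGH_DAYS,
    DEFAULT_LOW_DAYS,
    Approach1Config,
    Approach2Config,
    Approach3Config,
)
from .simulate import DEFAULT_SEED, TruncationWindow


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproduction run needs, YAML round-trippable."""

    seed: int = DEFAULT_SEED
    crl_grid_mm: tuple[float, float, float] = (5.0, 110.0, 1.0)  # start, stop, step
    n_per_crl: int = 100
    truncation: TruncationWindow = TruncationWindow()
    approach1: Approach1Config = Approach1Config()
    approach2: Approach2Config = Approach2Config()
    approach3: Approach3Config = Approach3Config()
    reporting_grid_mm: tuple[float, float, float] = (10.0, 100.0, 5.0)
    outdir: str = "trunkdate_run"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        kwargs: dict = {}
        for key in ("seed", "n_per_crl", "outdir"):
            if key in d:
                kwargs[key] = d[key]
        for key in ("crl_grid_mm", "reporting_grid_mm"):
            if key in d:
                kwargs[key] = tup(d[key])
        if "truncation" in d:
            kwargs["truncation"] = TruncationWindow(**d["truncation"])
        if "approach1" in d:
            a = dict(d["approach1"])
            for k in ("augment_low_days", "restrict_crl", "sensitivity_cutoffs"):
                if k in a:
                    a[k] = tup(a[k])
            kwargs["approach1"] = Approach1Config(**a)
        if "approach2" in d:
            a = dict(d["approach2"])
            for k in ("augment_low_days", "augment_high_days"):
                if k in a:
                    a[k] = tup(a[k])
            kwargs["approach2"] = Approach2Config(**a)
        if "approach3" in d:
            a = dict(d["approach3"])
            for k in ("ga_eval_days", "centile_levels"):
                if k in a:
                    a[k] = tup(a[k])
            kwargs["approach3"] = Approach3Config(**a)
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the resolved configuration, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
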