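"""Run configuration: every tunable knob of the pipeline in one record.

The full configuration is serialized verbatim into every report so a run
can be reproduced from its outputs alone.  Values may come from a flat TOML
file; command-line flags override file values.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Pipeline constants.

    Defaults encode the design rules: ~100-bp target windows, 20-nt
    protospacers with a 12-nt seed, zero tolerated off-targets under the
    seed-exact NGG/NAG rule, 200-bp minimum cut separation.
    """

    window: int = 100
    min_window: int = 30
    protospacer_length: int = 20
    pam_slack: int = 3
    max_mm_total: int = 3
    max_mm_seed: int = 0
    pams: tuple[str, ...] = ("NGG", "NAG")
    min_separation: int = 200
    efficiency_floor: float = 0.0
    efficiency_table: str | None = None  # TSV path; None = shipped default
    adjacency_flank: int = 10
    k_alternates: int = 5
    max_amplifiable: int = 5000
    warn_amplifiable: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window",
            "min_window",
            "protospacer_length",
            "min_separation",
            "max_amplifiable",
            "warn_amplifiable",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.min_window > self.window:
            raise ValueError("min_window cannot exceed window")
        if self.protospacer_length != 20:
            raise ValueError("only 20-nt protospacer scanning is supported")
        if self.max_mm_seed < 0 or self.max_mm_total < 0:
            raise ValueError("mismatch bounds must be non-negative")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pams" in data:
            data["pams"] = tuple(data["pams"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return replace(self, **clean) if clean else self

    def as_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    def load_weights(self) -> dict[tuple[int, str], float] | None:
        if self.efficiency_table is None:
            return None
        from .screening import load_weight_table

        return load_weight_table(self.efficiency_table)
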