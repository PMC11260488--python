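"""Run configuration and seed derivation.

Every stochastic stage receives a derived seed = run seed + a fixed
stage offset, so one run-level seed reproduces an entire pipeline while
stages remain independently re-runnable. Offsets are small constants
and derived seeds stay below 2^31.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: fixed per-stage seed offsets (run_seed + offset)
STAGE_OFFSETS = {
    "events": 11,
    "cross": 23,
    "pool_evolved": 37,
    "pool_ancestral": 41,
    "growth": 53,
    "trace": 67,
    "evolve": 79,
    "bsa": 97,
}

_MOD = 2**31


def stage_seed(run_seed: int, stage: str) -> int:
    """Derive the seed for a named stage from the run-level seed."""
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_OFFSETS)}")
    return (int(run_seed) + STAGE_OFFSETS[stage]) % _MOD


@dataclass
class RunConfig:
    """Serializable run-level configuration (YAML round-trip lossless)."""

    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"seed": self.seed, "params": self.params},
                              sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return cls(seed=int(raw.get("seed", 0)), params=dict(raw.get("params", {})))
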