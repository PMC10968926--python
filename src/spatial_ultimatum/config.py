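"""Run configuration: YAML key/value file plus flag overrides.

The config file mirrors the CLI flags one-to-one.  Defaults are the
baseline scenario (n=50, D=100, L=1, f=1/2, m=1, T=100, 10 replicates).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .engine import GameParams, REPLACEMENT_RULES
from .strategies import Emotion

__all__ = ["RunConfig", "parse_config", "write_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to launch a replicated run."""

    side: int = 50
    money_init: float = 100.0
    lives_init: int = 1
    fraction: float = 0.5
    min_stake: float = 1.0
    steps: int = 100
    delta_anger: float = 0.0
    delta_fear: float = 0.0
    delta_sadness: float = 0.0
    replacement: str = "copycat_majority"
    replicates: int = 10
    seed: int = 0
    out_dir: str = "results"
    snapshot_every: int = 0  # steps between lattice dumps; 0 = never

    def game_params(self) -> GameParams:
        deltas = {
            Emotion.ANGER: self.delta_anger,
            Emotion.FEAR: self.delta_fear,
            Emotion.SADNESS: self.delta_sadness,
        }
        deltas = {e: d for e, d in deltas.items() if d != 0.0}
        return GameParams(
            side=self.side,
            money_init=self.money_init,
            lives_init=self.lives_init,
            fraction=self.fraction,
            min_stake=self.min_stake,
            steps=self.steps,
            deltas=deltas,
            replacement_rule=self.replacement,
        )


_FIELD_TYPES = {
    "side": int,
    "money_init": float,
    "lives_init": int,
    "fraction": float,
    "min_stake": float,
    "steps": int,
    "delta_anger": float,
    "delta_fear": float,
    "delta_sadness": float,
    "replacement": str,
    "replicates": int,
    "seed": int,
    "out_dir": str,
    "snapshot_every": int,
}

_SHORT_RULES = {"copycat": "copycat_majority", "richest": "richest_neighbor"}


def parse_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a validated RunConfig from an optional YAML file plus overrides.

    ``overrides`` (CLI flags) take precedence over file values; ``None``
    entries in overrides are ignored.  Unknown keys and out-of-range
    values raise ``ValueError`` naming the offending key.
    """
    values: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} is not a key/value mapping")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val

    unknown = set(values) - set(_FIELD_TYPES)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    coerced: dict[str, Any] = {}
    for key, val in values.items():
        try:
            coerced[key] = _FIELD_TYPES[key](val)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"config key {key!r}: cannot read value {val!r}") from exc
    if "replacement" in coerced:
        coerced["replacement"] = _SHORT_RULES.get(
            coerced["replacement"], coerced["replacement"]
        )
        if coerced["replacement"] not in REPLACEMENT_RULES:
            raise ValueError(
                f"config key 'replacement': must be one of {REPLACEMENT_RULES}"
            )

    cfg = RunConfig(**coerced)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    try:
        cfg.game_params()  # runs all GameParams range checks
    except ValueError as exc:
        # surface the offending key name, not just the symptom
        raise ValueError(f"invalid configuration: {exc}") from exc
    if cfg.replicates < 1:
        raise ValueError("config key 'replicates': must be >= 1")
    if cfg.seed < 0:
        raise ValueError("config key 'seed': must be >= 0")
    if cfg.snapshot_every < 0:
        raise ValueError("config key 'snapshot_every': must be >= 0")


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize the resolved config; parse(write(cfg)) round-trips."""
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
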