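"""Run configuration: defaults, config-file parsing, CLI-flag precedence.

The defaults are the headline study conditions: M=100 agents, capacity
B=60, stepsize mu=0.01, T=300 periods, 1000 runs per ensemble. The config
file is a flat ``key = value`` text format whose keys use the model's
symbols directly (M, B, mu, T, regime, runs, seed); '#' starts a comment.
Command-line flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .core import REGIMES, SimulationParams

__all__ = ["RunConfig", "ConfigError", "parse_config", "read_config_file"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-domain configuration values."""


_INT_KEYS = {"M", "B", "T", "runs", "seed"}
_FLOAT_KEYS = {"mu", "b"}
_STR_KEYS = {"regime"}
_KNOWN_KEYS = _INT_KEYS | _FLOAT_KEYS | _STR_KEYS


@dataclass(frozen=True)
class RunConfig:
    M: int = 100
    B: int = 60
    mu: float = 0.01
    T: int = 300
    regime: str = "partial"
    b: float = 1.0
    runs: int = 1000
    seed: int = 0

    def validate(self) -> "RunConfig":
        checks = [
            ("M", self.M >= 1, "must be >= 1"),
            ("B", self.B >= 0, "must be >= 0"),
            ("mu", self.mu >= 0, "must be >= 0"),
            ("T", self.T >= 1, "must be >= 1"),
            ("b", self.b > 0, "must be > 0"),
            ("runs", self.runs >= 1, "must be >= 1"),
            ("regime", self.regime in REGIMES, f"must be one of {REGIMES}"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigError(
                    f"invalid value for {name}: {getattr(self, name)!r} ({msg})"
                )
        return self

    def to_params(self, regime: str | None = None) -> SimulationParams:
        return SimulationParams(
            n_agents=self.M,
            capacity=self.B,
            stepsize=self.mu,
            horizon=self.T,
            regime=regime or self.regime,
            benefit=self.b,
            seed=self.seed,
        )


def read_config_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        try:
            if key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            else:
                values[key] = value
        except ValueError as exc:
            raise ConfigError(f"line {lineno}: bad value for {key}: {value!r}") from exc
    return values


def parse_config(
    config_file: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Merge defaults, an optional config file, and CLI overrides (flags win)."""
    values: dict = {}
    if config_file is not None:
        values.update(read_config_file(config_file))
    for key, value in (overrides or {}).items():
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        if value is not None:
            values[key] = value
    valid_fields = {f.name for f in fields(RunConfig)}
    assert set(values) <= valid_fields
    return RunConfig(**values).validate()
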