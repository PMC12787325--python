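"""Run configuration: every knob that affects pipeline results, in one place.

A config can be loaded from a plain-text YAML key-value file and overridden
field-by-field (the CLI layers its flags on top).  Everything here is echoed
into the run manifest so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config"]

GAP_POLICIES = ("error", "ffill")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    Attributes
    ----------
    m_max:
        Largest candidate model order (number of lagged minutes), default 5.
    window:
        Observation window in minutes; fits never look further back than
        this, and ingestion truncates each participant to this many minutes.
        Default 1440 (24 h).
    eval_fraction:
        Tail fraction of the prediction stream entering Err, default 0.2.
    stability_fraction:
        Tail fraction of the parameter trajectory entering the mean/SD
        convergence summary, default 0.2.
    gap_policy:
        "error" (reject series with missing minutes) or "ffill"
        (forward-fill gaps up to ``max_gap_fill`` minutes each).
    max_gap_fill:
        Per-gap cap, in minutes, on forward filling.
    bpm_low, bpm_high:
        Sanity bounds; rows outside are dropped with a logged reason.
    seed:
        Random seed — consumed only by synthetic-data generation; the
        analysis pipeline itself is deterministic.
    output_dir:
        Where result artefacts are written.
    """

    m_max: int = 5
    window: int = 1440
    eval_fraction: float = 0.2
    stability_fraction: float = 0.2
    gap_policy: str = "error"
    max_gap_fill: int = 5
    bpm_low: float = 20.0
    bpm_high: float = 250.0
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.m_max < 1:
            raise ConfigError(f"m_max must be >= 1, got {self.m_max}")
        for name in ("eval_fraction", "stability_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.window < 2 * self.m_max + 2:
            raise ConfigError(
                f"window={self.window} must be >= 2*m_max+2={2 * self.m_max + 2}"
            )
        if self.gap_policy not in GAP_POLICIES:
            raise ConfigError(
                f"gap_policy must be one of {GAP_POLICIES}, got {self.gap_policy!r}"
            )
        if self.max_gap_fill < 1:
            raise ConfigError("max_gap_fill must be >= 1")
        if not 0 < self.bpm_low < self.bpm_high:
            raise ConfigError(
                f"bpm bounds must satisfy 0 < low < high, "
                f"got ({self.bpm_low}, {self.bpm_high})"
            )

    def replace(self, **kwargs) -> "RunConfig":
        """A copy with the given fields overridden (None values ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from defaults, an optional YAML file, then overrides."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a key-value document")
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
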