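"""Analysis, simulation and experiment configuration.

Defaults mirror the study conditions: 1 ms PSTH bins over a -500 to
+100 ms window, a 500 ms pre-stimulus baseline, a 50 ms response window,
a mean + 3 SD evoked-response threshold, a mean + 2 SD potentiation-peak
rule over 8 baseline blocks, 120 stimulations per block, and a minimum of
5 consecutive supporting blocks for a channel-level potentiation call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Any, Optional

import yaml

__all__ = ["AnalysisConfig", "SimulationConfig", "ExperimentConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed configuration files or values."""


@dataclass(frozen=True)
class AnalysisConfig:
    bin_width_ms: float = 1.0
    window_ms: tuple[float, float] = (-500.0, 100.0)
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    response_window_ms: tuple[float, float] = (0.0, 50.0)
    #: SD multiplier of the block-PSTH evoked-response threshold.
    evoked_sd_multiplier: float = 3.0
    #: SD multiplier of the per-bin potentiation-peak rule.
    peak_sd_multiplier: float = 2.0
    #: Expected number of blocks in the average baseline response.
    n_profile_blocks: int = 8
    #: "Similar latency" matching half-width for potentiation peaks.
    latency_tolerance_ms: float = 2.0
    #: Minimum consecutive supporting blocks for a potentiation call.
    min_consecutive_blocks: int = 5
    #: Run length at or above which the call is labelled 'run7'.
    strong_run_length: int = 7
    #: Veto scope: 'pre_drug' (pre-drug baseline blocks only) or
    #: 'all_pre_bicuculline' (strict mode, every pre-bicuculline block).
    veto_scope: str = "pre_drug"
    #: Number of consecutive veto-scope blocks that must carry a
    #: similar-latency peak before the pre-drug veto applies. 1 = any
    #: single pre-drug peak disqualifies the latency.
    veto_min_run: int = 1
    #: Allow one missing block inside a supporting run (off by default).
    allow_gap: bool = False
    #: 'percent_of_baseline' (100 = no change) or 'percent_change' (0 = no change).
    normalization: str = "percent_of_baseline"

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_ms", tuple(self.window_ms))
        object.__setattr__(self, "baseline_window_ms", tuple(self.baseline_window_ms))
        object.__setattr__(self, "response_window_ms", tuple(self.response_window_ms))
        if self.veto_scope not in ("pre_drug", "all_pre_bicuculline"):
            raise ConfigError(f"unknown veto_scope {self.veto_scope!r}")
        if self.normalization not in ("percent_of_baseline", "percent_change"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.min_consecutive_blocks < 1 or self.veto_min_run < 1:
            raise ConfigError("run lengths must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 16
    n_responsive: int = 6
    n_potentiating: int = 4
    baseline_rate_hz: float = 30.0
    potentiation_gain: float = 2.0
    ramp_blocks: int = 4
    onset_jitter_blocks: int = 2
    drug_scale: float = 1.0
    new_component_latency_ms: Optional[float] = None


@dataclass(frozen=True)
class ExperimentConfig:
    """Full simulate/analyze configuration for one experiment."""

    experiment: str = "exp3"  # 'exp1', 'exp2' or 'exp3'
    flash_delay_s: float = 0.25
    block_size: int = 120
    #: Optional override of blocks per condition epoch, e.g.
    #: {'pre': 4, 'pairing': 3}; keys must be epoch keywords of the
    #: experiment's protocol factory.
    epoch_blocks: Optional[dict] = None
    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2", "exp3"):
            raise ConfigError(f"unknown experiment {self.experiment!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["analysis"]["window_ms"] = list(self.analysis.window_ms)
        d["analysis"]["baseline_window_ms"] = list(self.analysis.baseline_window_ms)
        d["analysis"]["response_window_ms"] = list(self.analysis.response_window_ms)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ExperimentConfig":
        raw = dict(raw)
        sub: dict[str, Any] = {}
        for name, sub_cls in (("analysis", AnalysisConfig), ("simulation", SimulationConfig)):
            block = raw.pop(name, {}) or {}
            allowed = {f.name for f in fields(sub_cls)}
            for key in block:
                if key not in allowed:
                    raise ConfigError(f"unknown key {name}.{key!r}")
            sub[name] = sub_cls(**block)
        allowed = {f.name for f in fields(cls)} - {"analysis", "simulation"}
        for key in raw:
            if key not in allowed:
                raise ConfigError(f"unknown key {key!r}")
        return cls(analysis=sub["analysis"], simulation=sub["simulation"], **raw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        return cls.from_dict(raw)
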