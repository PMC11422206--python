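"""Pipeline configuration: one structured text (YAML) file, CLI-overridable.

Collects every constant the analysis depends on — protocol timing, filter
settings, baseline window, event thresholds, significance level, seed — so a
run is reproducible from the config alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocol import (
    DEFAULT_BASELINE_S,
    DEFAULT_CUFF_RAMP_S,
    DEFAULT_OCCLUSION_S,
    DEFAULT_REPERFUSION_S,
    ProtocolSchedule,
    build_schedule,
)

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # paths
    input_dir: str = "data"
    output_dir: str = "results"
    # protocol
    baseline_s: float = DEFAULT_BASELINE_S
    occlusion_s: float = DEFAULT_OCCLUSION_S
    reperfusion_s: tuple[float, ...] = DEFAULT_REPERFUSION_S
    cuff_ramp_s: float = DEFAULT_CUFF_RAMP_S
    sampling_rate: float = 10.0
    # filtering / normalization
    filter_order: int = 10
    cutoff_hz: float = 0.8
    baseline_window: tuple[float, float] = (150.0, 750.0)
    # event thresholds
    bound_threshold: float = 0.10
    decay_fraction: float = 0.63
    spike_horizon_s: float = 120.0
    slope_window_s: float = 30.0
    # statistics
    alpha: float = 0.05
    trim_outliers: bool = True
    # simulation
    groups: list = field(
        default_factory=lambda: [
            {"label": "G1", "pressure": "50", "n": 9},
            {"label": "G2", "pressure": "SBP+50", "n": 14},
            {"label": "G3", "pressure": "250", "n": 12},
        ]
    )
    n_sessions: int = 2
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bound_threshold", "decay_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.cutoff_hz < self.sampling_rate / 2:
            raise ValueError("cutoff_hz must be below the Nyquist frequency")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.reperfusion_s = tuple(float(x) for x in self.reperfusion_s)
        self.baseline_window = tuple(float(x) for x in self.baseline_window)

    def schedule(self) -> ProtocolSchedule:
        return build_schedule(
            self.baseline_s, self.occlusion_s, self.reperfusion_s, self.cuff_ramp_s
        )

    def digest(self) -> str:
        """Short stable hash of the scientific configuration, for provenance.

        Paths are excluded so identical analyses in different directories
        produce identical outputs.
        """
        payload = dataclasses.asdict(self)
        payload.pop("input_dir")
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict:
        return {
            "config_sha": self.digest(),
            "filter": f"butterworth_order{self.filter_order}_lp{self.cutoff_hz}Hz_zero_phase",
            "baseline_window_s": f"[{self.baseline_window[0]:g},{self.baseline_window[1]:g})",
            "bound_threshold": self.bound_threshold,
            "decay_fraction": self.decay_fraction,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config file (optional) and apply keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
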