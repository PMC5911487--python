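"""Run configuration: analysis parameters and generator settings, YAML-backed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .data import SynthConfig
from .exceptions import InvalidParameterError


@dataclass
class AnalysisConfig:
    """Parameters of a detection run.

    Durations are seconds.  ``threshold_mode`` is either ``reference-default``
    (2.1 / -2.3) or ``recalibrate`` (derive from sham inputs); the mode in
    force is echoed into every results file.
    """

    window_response: float = 0.4
    window_baseline: float = 0.6
    n_iter: int = 5000
    exclusion: float = 1.0
    threshold_mode: str = "reference-default"
    threshold_upper: float = 2.1
    threshold_lower: float = -2.3
    efficacy_levels: list = field(
        default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0]
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("window_response", "window_baseline", "exclusion"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.threshold_mode not in ("reference-default", "recalibrate"):
            raise InvalidParameterError(
                "threshold_mode must be 'reference-default' or 'recalibrate'"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SimulateConfig:
    """Settings for the ``simulate`` CLI command."""

    n_fovs: int = 1
    n_trials: int = 190
    pulse_s: float = 0.5
    gap_s: float = 2.5
    stim_efficacy: float = 0.4
    stim_spikes: int = 1
    stim_cell_fraction: float = 0.5
    synth: SynthConfig = field(default_factory=SynthConfig)


def _split_known(d: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    return d


def load_analysis_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**_split_known(raw, AnalysisConfig))


def load_simulate_config(path) -> SimulateConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return load_simulate_config_dict(raw)


def load_simulate_config_dict(raw: dict) -> SimulateConfig:
    raw = dict(raw)
    synth_raw = raw.pop("synth", {}) or {}
    synth = SynthConfig(**_split_known(synth_raw, SynthConfig))
    return SimulateConfig(**_split_known(raw, SimulateConfig), synth=synth)
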