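"""Run configuration: one nested, YAML-round-trippable object.

``RunConfig`` gathers every tunable of the pipeline — instrument geometry,
phase-grid rules, peak-fit thresholds, indexing tolerances, EDP sign and
correction tables, and the tilt reference — with defaults equal to the
values documented on the individual modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .edp import DEFAULT_FACTOR_TABLE
from .forward import InstrumentConfig, PhaseRules
from .geometry import TiltReference, make_reference
from .lamellar import AnalysisSettings

__all__ = ["RunConfig", "load_config", "save_config"]

DEFAULT_COMPOSITIONS = (0.0, 0.1, 0.25, 0.5, 1.0, 2.5)  # mol%
DEFAULT_TEMPERATURES = (16.0, 19.0, 22.0, 25.0, 28.0, 31.0, 34.0, 37.0, 40.0, 43.0)


@dataclass
class RunConfig:
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    waxs_instrument: InstrumentConfig = field(
        default_factory=InstrumentConfig.waxs_default
    )
    rules: PhaseRules = field(default_factory=PhaseRules)
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    factor_table: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_TABLE)
    )
    tilt_reference: TiltReference = field(default_factory=lambda: make_reference(6.40, 1.83, 32.6))
    compositions: tuple[float, ...] = DEFAULT_COMPOSITIONS
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    seed: int = 0
    out_dir: str = "lamdiff_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factor_table"] = {int(k): float(v) for k, v in self.factor_table.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "instrument" in d:
            inst = dict(d["instrument"])
            if "beam_center" in inst:
                inst["beam_center"] = tuple(inst["beam_center"])
            if "background" in inst:
                inst["background"] = tuple(inst["background"])
            d["instrument"] = InstrumentConfig(**inst)
        if "waxs_instrument" in d:
            inst = dict(d["waxs_instrument"])
            if "beam_center" in inst:
                inst["beam_center"] = tuple(inst["beam_center"])
            if "background" in inst:
                inst["background"] = tuple(inst["background"])
            d["waxs_instrument"] = InstrumentConfig(**inst)
        if "rules" in d:
            d["rules"] = PhaseRules(**d["rules"])
        if "settings" in d:
            d["settings"] = AnalysisSettings(**d["settings"])
        if "factor_table" in d:
            d["factor_table"] = {int(k): float(v) for k, v in d["factor_table"].items()}
        if "tilt_reference" in d:
            tr = d["tilt_reference"]
            d["tilt_reference"] = make_reference(
                tr["d_ref"], tr["d_w_ref"], tr["theta_ref"]
            )
        if "compositions" in d:
            d["compositions"] = tuple(d["compositions"])
        if "temperatures" in d:
            d["temperatures"] = tuple(d["temperatures"])
        return cls(**d)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
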