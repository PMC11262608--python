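"""YAML configuration: screen geometry, filter, validity and simulator
parameters under the keys ``screen``, ``ivt``, ``validity`` and
``simulation``.  Absent keys fall back to the package defaults."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .events import IVTParams
from .geometry import ScreenGeometry
from .simulate import SimulationParams
from .trials import TrialValidityParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


class PipelineConfig:
    """Bundle of all tunable parameter groups."""

    def __init__(
        self,
        screen: ScreenGeometry | None = None,
        ivt: IVTParams | None = None,
        validity: TrialValidityParams | None = None,
        simulation: SimulationParams | None = None,
    ):
        self.screen = screen or ScreenGeometry()
        self.ivt = ivt or IVTParams()
        self.validity = validity or TrialValidityParams()
        self.simulation = simulation or SimulationParams()

    def to_dict(self) -> dict:
        d = {
            "screen": asdict(self.screen),
            "ivt": asdict(self.ivt),
            "validity": asdict(self.validity),
            "simulation": asdict(self.simulation),
        }
        # YAML-friendly tuples
        for group in d.values():
            for k, v in group.items():
                if isinstance(v, tuple):
                    group[k] = list(v)
        return d


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    def build(cls, key, tuple_fields=()):
        kwargs = dict(raw.get(key) or {})
        for f in tuple_fields:
            if f in kwargs and isinstance(kwargs[f], list):
                kwargs[f] = tuple(kwargs[f])
        return cls(**kwargs)

    return PipelineConfig(
        screen=build(ScreenGeometry, "screen"),
        ivt=build(IVTParams, "ivt"),
        validity=build(TrialValidityParams, "validity"),
        simulation=build(
            SimulationParams,
            "simulation",
            tuple_fields=("blink_duration_ms_range", "gain_bounds"),
        ),
    )


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
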