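"""Plain-text (YAML) session configuration.

Every default of the simulator can be overridden from one file, e.g.::

    mode: adaptive
    seed: 7
    frame_rate: 60
    controller:
      sjf_intercept: 0.035      # jumping-force reconstruction coefficients
      sjf_slope: -0.14
      static_correction_high: -0.1
    weights:
      w_size: 0.3
    baseline:
      tolerance: 0.08
      hold: 100
    plan:                        # state bands come from the controller
      - [REST, 60]
      - [LOW, 60]
      - [REST, 60]
      - [HIGH, 60]
      - [REST, 60]
    states:                      # optional band overrides
      LOW: [0.7, 0.8]
      HIGH: [0.4, 0.5]
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path
from typing import Union

import yaml

from .arena import IntensityWeights
from .controller import AnxietyState, ControllerConfig, PhasePlan, StateLabel, STATES
from .experiment import SessionConfig

__all__ = ["load_config"]


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: Union[str, Path]) -> SessionConfig:
    """Load a :class:`SessionConfig` from a YAML file; absent keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}

    states = dict(STATES)
    for label, band in (raw.pop("states", None) or {}).items():
        lab = StateLabel(label)
        states[lab] = AnxietyState(lab, float(band[0]), float(band[1]))

    kwargs = {}
    if "controller" in raw:
        kwargs["controller"] = _build(ControllerConfig, raw.pop("controller"))
    if "weights" in raw:
        kwargs["weights"] = _build(IntensityWeights, raw.pop("weights"))
    if "plan" in raw:
        phases = tuple(
            (states[StateLabel(s)], float(d)) for s, d in raw.pop("plan")
        )
        kwargs["plan"] = PhasePlan(phases)
    for key, val in (raw.pop("baseline", None) or {}).items():
        kwargs[f"baseline_{key}"] = val
    kwargs.update(raw)
    return _build(SessionConfig, kwargs)
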