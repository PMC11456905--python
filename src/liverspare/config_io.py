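"""YAML run-configuration loading.

A run configuration is a nested mapping whose sections mirror the library
dataclasses, e.g.::

    n_patients: 10
    base_seed: 1
    phantom:
      functional_fraction_target: 0.5
      gtv_radius_mm: 12
    segmentation:
      ct1_threshold_ms: 800
    tiers:
      tiers:
        - {rx_gy: 50.0, lmd_limit_gy: 13.0}
        - {rx_gy: 40.0, lmd_limit_gy: 15.0}

Unknown keys raise immediately so typos do not silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cohort import RunConfig
from .dose import KernelParams
from .optimize import OarConstraint, ParallelObjective, PlanObjectives, PrescriptionTiers
from .phantom import PhantomConfig
from .pseudoct import DensityConfig
from .segmentation import SegmentationParams

_SECTIONS = {
    "phantom": PhantomConfig,
    "segmentation": SegmentationParams,
    "density": DensityConfig,
    "kernel": KernelParams,
    "objectives": PlanObjectives,
    "tiers": PrescriptionTiers,
}


def _build(cls, payload: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(payload) - set(fields)
    if unknown:
        raise KeyError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        if cls is PlanObjectives and key == "oar_constraints":
            value = [OarConstraint(**v) for v in value]
        elif cls is PlanObjectives and key == "flv_parallel" and value is not None:
            value = ParallelObjective(**value)
        elif isinstance(value, list) and isinstance(fields[key].default, tuple):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def run_config_from_dict(payload: dict) -> RunConfig:
    payload = dict(payload or {})
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in payload:
            kwargs[section] = _build(cls, payload.pop(section) or {})
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - fields
    if unknown:
        raise KeyError(f"unknown run-config keys: {sorted(unknown)}")
    kwargs.update(payload)
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return run_config_from_dict(payload or {})
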