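"""YAML experiment and simulation configuration.

An experiment config describes the arena geometry, the illumination
schedule and group metadata::

    arena:
      length_mm: 55
      width_mm: 4
      borders_mm: [13.75, 27.5, 41.25]
      choice_halfwidth_mm: 3
      gradient_width_mm: 0.67
    schedule:
      - {start_s: 0, end_s: 60, intensity_uW_mm2: 0, color: dark, lit_quadrants: []}
      - {start_s: 60, end_s: 120, intensity_uW_mm2: 22, color: red, lit_quadrants: [0, 2]}
    group_label: test
    metadata: {driver: R58E02, effector: Chrimson}

A simulation params file holds one WalkerParams mapping per group name.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .arena import ArenaSpec, IlluminationEpoch, LightColor, validate_schedule
from .walker import WalkerParams


def arena_from_dict(d: dict) -> ArenaSpec:
    return ArenaSpec(
        length=d.get("length_mm", 55.0),
        width=d.get("width_mm", 4.0),
        border_positions=tuple(d.get("borders_mm", ())),
        choice_halfwidth=d.get("choice_halfwidth_mm", 3.0),
        gradient_width=d.get("gradient_width_mm", 0.67),
    )


def epoch_from_dict(d: dict, label: str = "") -> IlluminationEpoch:
    lit = frozenset(d.get("lit_quadrants", ()))
    color = d.get("color", "dark" if not lit else "red")
    return IlluminationEpoch(
        start=float(d["start_s"]),
        end=float(d["end_s"]),
        intensity=float(d.get("intensity_uW_mm2", 0.0)),
        color=LightColor(color),
        lit_quadrants=lit,
        label=d.get("label", label),
    )


def load_experiment_config(path) -> dict:
    """Parse an experiment config file into arena / schedule / metadata."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    arena = arena_from_dict(raw.get("arena", {}))
    schedule = [
        epoch_from_dict(e, label=e.get("label", f"epoch{i}"))
        for i, e in enumerate(raw.get("schedule", []))
    ]
    validate_schedule(schedule)
    return {
        "arena": arena,
        "schedule": schedule,
        "group_label": raw.get("group_label", "group"),
        "metadata": raw.get("metadata", {}),
    }


def load_walker_params(path) -> dict[str, WalkerParams]:
    """Parse a per-group WalkerParams mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: WalkerParams(**(vals or {})) for name, vals in raw.items()}


def walker_params_to_dict(params: WalkerParams) -> dict:
    return asdict(params)
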