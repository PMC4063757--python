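"""YAML pipeline configuration.

One flat mapping holds every tunable of the pipeline; unspecified keys take
the acquisition-matched defaults below.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .tracking import TrackingConfig

DEFAULTS = {
    "sh_order": 4,
    "fa_threshold": 0.15,
    "max_angle_deg": 60.0,
    "step_mm": 1.1,
    "seeds_per_axis": 11,
    "max_steps": 2000,
    "peak_min_sep_deg": 45.0,
    "peak_rel_threshold": 0.25,
    "max_peaks": 3,
    "sphere_subdivisions": 4,
    "group_threshold": 0.20,
    "dilate_mm": 2.0,
    "min_streamlines": 1,
    "max_gm_interior": 2,
    "loop_turn_deg": 360.0,
}


@dataclass(frozen=True)
class PipelineConfig:
    tracking: TrackingConfig
    group_threshold: float = 0.20
    dilate_mm: float = 2.0
    min_streamlines: int = 1
    max_gm_interior: int = 2
    loop_turn_deg: float = 360.0


def load_config(path=None) -> PipelineConfig:
    """Read a YAML config (or defaults when ``path`` is None)."""
    values = dict(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    tracking_keys = {
        "fa_threshold", "max_angle_deg", "step_mm", "seeds_per_axis",
        "max_steps", "sh_order", "peak_min_sep_deg", "peak_rel_threshold",
        "max_peaks", "sphere_subdivisions",
    }
    tracking = TrackingConfig(**{k: values[k] for k in tracking_keys})
    return PipelineConfig(
        tracking=tracking,
        group_threshold=float(values["group_threshold"]),
        dilate_mm=float(values["dilate_mm"]),
        min_streamlines=int(values["min_streamlines"]),
        max_gm_interior=int(values["max_gm_interior"]),
        loop_turn_deg=float(values["loop_turn_deg"]),
    )


def dump_config(cfg: PipelineConfig, path) -> None:
    values = asdict(cfg.tracking)
    values.update(
        group_threshold=cfg.group_threshold, dilate_mm=cfg.dilate_mm,
        min_streamlines=cfg.min_streamlines,
        max_gm_interior=cfg.max_gm_interior,
        loop_turn_deg=cfg.loop_turn_deg,
    )
    Path(path).write_text(yaml.safe_dump(values, sort_keys=True))
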