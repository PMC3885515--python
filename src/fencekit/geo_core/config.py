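"""Central model configuration.

Every numeric threshold used by the fence rules lives here so that a single
declarative file drives the whole pipeline.  Lengths are metres, areas km².
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

#: road classes treated as paved when stratifying the survey frame
DEFAULT_PAVED_CLASSES = ("primary", "secondary")

#: land-cover classes counted as native prairie
DEFAULT_PRAIRIE_CLASSES = ("grassland", "shrubland", "mixed")


@dataclass
class ModelConfig:
    # --- tenure / land-cover area thresholds (km²) ---
    section_area: float = 2.59
    half_section_area: float = 1.3
    two_sections_area: float = 5.2
    three_sections_area: float = 7.8

    # --- road buffer geometry (m) ---
    primary_halfwidth: float = 19.0
    secondary_halfwidth: float = 11.0
    local_halfwidth: float = 11.0
    primary_cap_len: float = 38.0
    secondary_cap_len: float = 22.0
    local_cap_len: float = 22.0
    long_local_min_len: float = 1200.0

    # --- synthesis ---
    parallel_suppress_dist: float = 20.0

    # --- density raster ---
    density_search_radius: float = 10000.0
    density_cell_size: float = 1500.0

    # --- survey & accuracy ---
    accuracy_buffer: float = 30.0
    transect_length: float = 3200.0
    transect_min_spacing: float = 3500.0
    roadside_max_dist: float = 200.0
    min_structure_change_len: float = 100.0

    # --- numeric tolerances / implementation knobs ---
    length_tolerance: float = 0.01
    hole_fill_cell_size: float = 30.0
    densify_interval: float = 30.0
    local_fence_side: str = "left"  # left | right | random
    local_fence_side_seed: int = 0
    negatives_per_positive: float = 1.0
    paved_classes: tuple = DEFAULT_PAVED_CLASSES
    prairie_classes: tuple = DEFAULT_PRAIRIE_CLASSES
    #: tenure rules switched off (rule ids as in tenure_fences.RULE_ORDER)
    disabled_tenure_rules: tuple = ()

    def __post_init__(self) -> None:
        self.paved_classes = tuple(self.paved_classes)
        self.prairie_classes = tuple(self.prairie_classes)
        self.disabled_tenure_rules = tuple(self.disabled_tenure_rules)
        self.validate()

    def validate(self) -> None:
        positive = (
            "section_area", "half_section_area", "two_sections_area",
            "three_sections_area", "primary_halfwidth", "secondary_halfwidth",
            "local_halfwidth", "primary_cap_len", "secondary_cap_len",
            "local_cap_len", "long_local_min_len", "parallel_suppress_dist",
            "density_search_radius", "density_cell_size", "accuracy_buffer",
            "transect_length", "transect_min_spacing", "roadside_max_dist",
            "min_structure_change_len", "length_tolerance",
            "hole_fill_cell_size", "densify_interval",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        tol = self.length_tolerance
        if abs(self.primary_cap_len - 2 * self.primary_halfwidth) > tol:
            raise ConfigError("primary_cap_len must equal 2 x primary_halfwidth")
        if abs(self.secondary_cap_len - 2 * self.secondary_halfwidth) > tol:
            raise ConfigError("secondary_cap_len must equal 2 x secondary_halfwidth")
        if abs(self.local_cap_len - 2 * self.local_halfwidth) > tol:
            raise ConfigError("local_cap_len must equal 2 x local_halfwidth")
        if not (self.half_section_area <= self.section_area
                <= self.two_sections_area <= self.three_sections_area):
            raise ConfigError(
                "area thresholds must be ordered half <= one <= two <= three sections")
        if self.local_fence_side not in ("left", "right", "random"):
            raise ConfigError("local_fence_side must be left, right or random")

    # -- serialisation --------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["paved_classes"] = list(self.paved_classes)
        data["prairie_classes"] = list(self.prairie_classes)
        data["disabled_tenure_rules"] = list(self.disabled_tenure_rules)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def halfwidth_for(self, road_class: str) -> float:
        return {
            "primary": self.primary_halfwidth,
            "secondary": self.secondary_halfwidth,
            "local": self.local_halfwidth,
        }[road_class]

    def cap_len_for(self, road_class: str) -> float:
        return {
            "primary": self.primary_cap_len,
            "secondary": self.secondary_cap_len,
            "local": self.local_cap_len,
        }[road_class]
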