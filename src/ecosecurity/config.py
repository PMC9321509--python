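"""Pipeline configuration: every tunable the printed parameter tables carry.

Defaults reproduce the published scheme: sensitivity composite weights
0.43/0.39/0.18, service weights 0.45/0.30/0.25, resistance factor weights
0.095/0.213/0.236/0.118/0.173, the 500 m source-merge gap, the 8 km^2
source area floor, the 1 km^2 important-node floor, and the five-class
natural-breaks zoning.  A YAML file overrides any subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

from .assess import SENSITIVITY_WEIGHTS, SERVICE_WEIGHTS
from .resistance import FACTOR_WEIGHTS
from .zoning import DEFAULT_POLICY_MAPPING

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # assessment
    sensitivity_weights: tuple[float, float, float] = SENSITIVITY_WEIGHTS
    service_weights: tuple[float, float, float] = SERVICE_WEIGHTS
    superposition_weights: tuple[float, float] = (0.5, 0.5)
    n_classes: int = 5
    relief_window: int = 37  # odd focal window (cells) for topographic relief

    # source identification
    merge_gap_m: float = 500.0
    min_source_area_km2: float = 8.0
    patch_connectivity: int = 8

    # resistance
    resistance_weights: dict = field(default_factory=lambda: dict(FACTOR_WEIGHTS))
    monotone_roads: bool = False

    # corridors and nodes
    corridor_mode: str = "adjacent_pairs"
    swath_percentile: float = 0.05
    node_min_area_km2: float = 1.0

    # zoning
    zoning_basis: str = "cost_distance"  # or "resistance"
    policy_mapping: dict = field(default_factory=lambda: dict(DEFAULT_POLICY_MAPPING))

    # synthetic landscape
    seed: int = 0
    n_rows: int = 200
    n_cols: int = 200
    cellsize: float = 1000.0

    def validate(self) -> None:
        if self.corridor_mode not in ("adjacent_pairs", "all_pairs"):
            raise ValueError(f"bad corridor_mode {self.corridor_mode!r}")
        if self.zoning_basis not in ("cost_distance", "resistance"):
            raise ValueError(f"bad zoning_basis {self.zoning_basis!r}")
        if self.relief_window < 1 or self.relief_window % 2 == 0:
            raise ValueError("relief_window must be a positive odd integer")
        for name, w in (("merge_gap_m", self.merge_gap_m),
                        ("min_source_area_km2", self.min_source_area_km2),
                        ("node_min_area_km2", self.node_min_area_km2)):
            if w < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(w <= 0 for w in self.resistance_weights.values()):
            raise ValueError("resistance weights must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Config from defaults, then a YAML file, then keyword overrides."""
    data: dict = {}
    if path is not None:
        import yaml

        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update(overrides)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("sensitivity_weights", "service_weights", "superposition_weights"):
        if key in data:
            data[key] = tuple(data[key])
    if "policy_mapping" in data:
        data["policy_mapping"] = {int(k): v for k, v in data["policy_mapping"].items()}
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
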