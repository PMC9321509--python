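"""End-to-end orchestration of the security-pattern construction.

Stage order follows the method's framework: multi-factor assessment ->
source identification -> resistance surface -> corridors and pinch points
-> safety zoning.  :func:`run_pipeline` executes any prefix-closed subset
of stages on a landscape bundle and returns a manifest of per-stage
summaries; grids are optionally written to an output directory with
checksums recorded, so two runs on identical inputs are verifiably
identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assess as asmod
from .assess import (EcoAssessment, SensitivityLayers, ServiceLayers,
                     composite_importance, composite_sensitivity)
from .config import PipelineConfig
from .connectivity import (Corridor, NodeSet, corridor_network, cost_distance,
                           current_flow, extract_nodes)
from .grid import Grid, euclidean_distance, focal_range, minmax_normalize, write_grid
from .resistance import ResistanceSurface, reclass_factor, weighted_overlay
from .sources import SourceSet, filter_by_area, label_patches, landuse_composition, merge_nearby
from .synth import LandscapeBundle
from .zoning import SafetyZoneMap, policy_partition, safety_zones

__all__ = ["PipelineState", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("assess", "sources", "resistance", "corridors", "zones")

#: which earlier stages each stage needs
STAGE_DEPS = {
    "assess": (),
    "sources": ("assess",),
    "resistance": (),
    "corridors": ("sources", "resistance"),
    "zones": ("sources", "resistance"),
}


@dataclass
class PipelineState:
    bundle: LandscapeBundle
    config: PipelineConfig
    assessment: EcoAssessment | None = None
    sensitivity: SensitivityLayers | None = None
    services: ServiceLayers | None = None
    sources: SourceSet | None = None
    surface: ResistanceSurface | None = None
    corridors: list[Corridor] = field(default_factory=list)
    nodes: NodeSet | None = None
    zones: SafetyZoneMap | None = None
    summaries: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage implementations


def stage_assess(state: PipelineState) -> None:
    cfg, b = state.config, state.bundle
    r_raw = asmod.rainfall_erosivity(b.monthly_precip)
    relief = focal_range(b.dem, cfg.relief_window)
    r_g = asmod.grade_factor(r_raw, "R")
    ls_g = asmod.grade_factor(relief, "LS")
    c_g = asmod.grade_factor(b.vegcover, "C")
    k_g = asmod.grade_soil_texture(b.soil_texture)
    i_g = asmod.grade_factor(b.aridity, "I")
    w_g = asmod.grade_factor(b.wind_days, "W")

    sens = SensitivityLayers(
        sswl=asmod.sswl(r_g, k_g, ls_g, c_g),
        sse=asmod.sse(ls_g, r_g, k_g, c_g),
        sld=asmod.sld(i_g, w_g, k_g, c_g),
        weights=cfg.sensitivity_weights,
    )
    composite_sensitivity(sens)

    annual = b.monthly_precip[0].copy(
        sum(m.values for m in b.monthly_precip))
    slope = asmod.slope_degrees(b.dem)
    fsio = slope.copy(np.clip(slope.values / 90.0, 0.0, 1.0))
    npp_n = minmax_normalize(b.npp)
    fpre = minmax_normalize(annual)
    ftem = minmax_normalize(b.temperature)
    falt = minmax_normalize(b.dem)
    fsic = b.soil_texture.copy(b.soil_texture.values / asmod.N_TEXTURE_CLASSES)
    # graded soil erodibility rescaled onto (0, 1] for the Spro formula
    k_norm = k_g.grid.copy(k_g.grid.values / 9.0)

    serv = ServiceLayers(
        wr=asmod.water_retention(npp_n, fsic, fpre, fsio),
        spro=asmod.soil_conservation(npp_n, k_norm, fsio),
        sbio=asmod.biodiversity_service(npp_n, fpre, ftem, falt),
        weights=cfg.service_weights,
    )
    composite_importance(serv)

    assessment = asmod.superpose_environment(
        sens.composite, serv.composite,
        weights=cfg.superposition_weights, n_classes=cfg.n_classes)
    state.sensitivity, state.services, state.assessment = sens, serv, assessment

    vals = assessment.environment_class.valid_values()
    state.summaries["assess"] = {
        "class_percent": {int(k): round(float(100.0 * (vals == k).sum() / vals.size), 3)
                          for k in range(1, cfg.n_classes + 1)},
    }


def stage_sources(state: PipelineState) -> None:
    cfg = state.config
    patches = label_patches(state.assessment.environment_class, cfg.n_classes,
                            cfg.patch_connectivity)
    merged = merge_nearby(patches, cfg.merge_gap_m)
    sources = filter_by_area(merged, cfg.min_source_area_km2)
    if sources.n_patches == 0:
        log.warning("no source patch survives the %.1f km^2 area filter",
                    cfg.min_source_area_km2)
    composition = landuse_composition(sources, state.bundle.landuse)
    state.sources = sources
    state.summaries["sources"] = {
        "n_patches_raw": patches.n_patches,
        "n_patches_merged": merged.n_patches,
        "n_sources": sources.n_patches,
        "total_area_km2": round(sources.total_area_km2(), 3),
        "landuse_percent": {k: round(v["percent"], 2) for k, v in composition.items()},
    }


def stage_resistance(state: PipelineState) -> None:
    cfg, b = state.config, state.bundle
    slope = asmod.slope_degrees(b.dem)
    d_county = euclidean_distance(b.dem, b.county_roads)
    d_highway = euclidean_distance(b.dem, b.highways)
    raw = {
        "landuse": b.landuse,
        "vegcover": b.vegcover,
        "slope": slope,
        "dist_county_road": d_county,
        "dist_highway": d_highway,
    }
    factors = [reclass_factor(raw[name], name,
                              weight=cfg.resistance_weights[name],
                              monotone=cfg.monotone_roads)
               for name in raw]
    state.surface = weighted_overlay(factors)
    vals = state.surface.grid.valid_values()
    state.summaries["resistance"] = {
        "min": round(float(vals.min()), 3),
        "mean": round(float(vals.mean()), 3),
        "max": round(float(vals.max()), 3),
        "weights": dict(cfg.resistance_weights),
    }


def stage_corridors(state: PipelineState) -> None:
    cfg = state.config
    corridors = corridor_network(state.surface, state.sources, cfg.corridor_mode)
    connected = [c for c in corridors if c.connected]
    currents = []
    for c in connected:
        cur = current_flow(state.surface, state.sources, c.source_a, c.source_b,
                           cfg.swath_percentile)
        if cur is not None:
            currents.append(cur)
    if currents:
        nodes = extract_nodes(currents, cfg.node_min_area_km2,
                              cfg.patch_connectivity)
    else:
        empty = state.surface.grid.copy(np.zeros(state.surface.grid.shape))
        from .sources import PatchSet
        nodes = NodeSet(empty, PatchSet(empty, []), PatchSet(empty, []))
    state.corridors, state.nodes = corridors, nodes
    state.summaries["corridors"] = {
        "n_corridors": len(connected),
        "n_disconnected_pairs": len(corridors) - len(connected),
        "total_length_m": round(sum(c.length_m for c in connected), 1),
        "n_important_nodes": nodes.important_nodes.n_patches,
        "n_general_nodes": nodes.general_nodes.n_patches,
    }


def stage_zones(state: PipelineState) -> None:
    cfg = state.config
    if cfg.zoning_basis == "cost_distance":
        basis = cost_distance(state.surface, state.sources).cost
    else:
        basis = state.surface.grid
    zones = safety_zones(basis, cfg.n_classes)
    policy_partition(zones, cfg.policy_mapping)
    state.zones = zones
    state.summaries["zones"] = {
        "zone_percent": {z: round(t["percent"], 3) for z, t in zones.areas.items()},
        "policy_percent": {p: round(t["percent"], 3)
                           for p, t in zones.policy_areas.items()},
    }


_STAGE_FUNCS = {
    "assess": stage_assess,
    "sources": stage_sources,
    "resistance": stage_resistance,
    "corridors": stage_corridors,
    "zones": stage_zones,
}

_STATE_ATTR = {"assess": "assessment", "sources": "sources",
               "resistance": "surface", "corridors": "nodes", "zones": "zones"}


def run_pipeline(
    bundle: LandscapeBundle,
    config: PipelineConfig | None = None,
    stages: tuple[str, ...] = STAGES,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the requested stages in framework order; return the manifest.

    Raises ``ValueError`` naming the stage to run first when a requested
    stage's dependency result is missing from both the stage list and the
    in-memory state.
    """
    config = config or PipelineConfig()
    config.validate()
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    state = PipelineState(bundle=bundle, config=config)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        for dep in STAGE_DEPS[stage]:
            if dep not in ordered and getattr(state, _STATE_ATTR[dep]) is None:
                raise ValueError(
                    f"stage '{stage}' needs the output of stage '{dep}'; "
                    f"run '{dep}' first")
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](state)
    manifest = {
        "parameters": config.to_dict(),
        "truth": dict(bundle.truth),
        "stages": state.summaries,
    }
    if out_dir is not None:
        manifest["outputs"] = _write_outputs(state, Path(out_dir))
    state.summaries = manifest["stages"]
    manifest["_state"] = state
    return manifest


def _checksum(grid: Grid) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(grid.values).tobytes())
    h.update(str((grid.cellsize, grid.origin)).encode())
    return h.hexdigest()[:16]


def _write_outputs(state: PipelineState, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    grids: dict[str, Grid] = {}
    if state.assessment is not None:
        grids["sensitivity_class"] = state.assessment.sensitivity_class
        grids["importance_class"] = state.assessment.importance_class
        grids["environment_class"] = state.assessment.environment_class
    if state.sources is not None:
        grids["source_labels"] = state.sources.label_grid
    if state.surface is not None:
        grids["resistance"] = state.surface.grid
    if state.nodes is not None:
        grids["current"] = state.nodes.current
        grids["important_nodes"] = state.nodes.important_nodes.label_grid
    if state.zones is not None:
        grids["safety_zones"] = state.zones.zone_grid
        if state.zones.policy_grid is not None:
            grids["policy"] = state.zones.policy_grid
    outputs = {}
    for name, g in grids.items():
        path = out_dir / f"{name}.asc"
        write_grid(g, path, "ascii_grid")
        outputs[name] = {"path": str(path), "sha256_16": _checksum(g)}
    return outputs
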