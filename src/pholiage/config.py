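"""Run configuration (YAML/JSON), result writers and run metadata.

A run config names one tree, one stand, one gap, one species' physiology,
the sky and the numerical resolutions.  Unknown keys are rejected and
validation errors name the offending key (e.g. ``gap.radius``).  Angles are
degrees in files; lengths are metres and fluxes μmol m^-2 s^-1 throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import __version__
from .geometry import (
    Gap,
    LeafAngleDistribution,
    Scene,
    VegetationStand,
    build_tree,
)
from .light import SkyModel, build_sky
from .photosynthesis import SpeciesPhysiology

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "build_scene",
    "build_physiology",
    "build_sky_from",
    "scene_to_dict",
    "scene_from_dict",
    "write_results",
    "read_results",
    "run_metadata",
]

log = logging.getLogger(__name__)

FractionSpec = Union[str, list[list[float]]]


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


def _parse_fractions(spec: FractionSpec) -> LeafAngleDistribution:
    if isinstance(spec, str):
        if spec.lower() != "spherical":
            raise ConfigError(
                f"leaf_angle_fractions: unknown preset {spec!r} (only 'spherical')"
            )
        return LeafAngleDistribution.spherical()
    angles = tuple(float(pair[0]) for pair in spec)
    fracs = tuple(float(pair[1]) for pair in spec)
    return LeafAngleDistribution(angles, fracs)


class TreeConfig(_Model):
    height: float = Field(gt=0)
    crown_volume: float = Field(gt=0)
    lw_ratio: float = Field(gt=0)
    leaf_area: float = Field(gt=0)
    lad: float | None = Field(default=None, gt=0)
    leaf_angle_fractions: FractionSpec = "spherical"


class StandConfig(_Model):
    height: float = Field(gt=0)
    lai: float = Field(ge=0)
    leaf_angle_fractions: FractionSpec = "spherical"


class GapConfig(_Model):
    radius: float = Field(ge=0)


class SkyConfig(_Model):
    type: Literal["uoc", "soc"] = "uoc"
    n_elevation: int = Field(default=9, ge=1)
    n_azimuth: int = Field(default=12, ge=1)
    io: float = Field(default=1000.0, ge=0)


class NumericsConfig(_Model):
    crown_grid: int | tuple[int, int, int] = 16
    absorptance: float = Field(default=1.0, gt=0, le=1)
    mc_seed: int | None = None


class SpeciesConfig(_Model):
    name: str = ""
    n_o: float = Field(gt=0)
    pmax_slope: float = Field(gt=0)
    r_d: float = Field(ge=0)
    quantum_yield: float = Field(gt=0)
    theta: float = Field(default=0.7, ge=0, le=1)


class SweepConfig(_Model):
    radii: list[float] | None = None
    lai_values: list[float] | None = None
    heights: list[float] | None = None
    mode: Literal["control", "liberated"] = "control"
    fixed_gap_radius: float = Field(default=0.5, ge=0)
    normalization_radius: float = Field(default=2.5, gt=0)


class RunConfig(_Model):
    tree: TreeConfig
    stand: StandConfig
    species: SpeciesConfig
    gap: GapConfig = GapConfig(radius=0.0)
    sky: SkyConfig = SkyConfig()
    numerics: NumericsConfig = NumericsConfig()
    sweep: SweepConfig = SweepConfig()


def read_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    log.debug("read_config(%s): %s", path, cfg.model_dump())
    return cfg


def build_scene(cfg: RunConfig) -> Scene:
    tree = build_tree(
        height=cfg.tree.height,
        crown_volume=cfg.tree.crown_volume,
        lw_ratio=cfg.tree.lw_ratio,
        leaf_area=cfg.tree.leaf_area,
        lad=cfg.tree.lad,
        leaf_angles=_parse_fractions(cfg.tree.leaf_angle_fractions),
    )
    stand = VegetationStand(
        height=cfg.stand.height,
        lai=cfg.stand.lai,
        leaf_angles=_parse_fractions(cfg.stand.leaf_angle_fractions),
    )
    return Scene(tree=tree, stand=stand, gap=Gap(cfg.gap.radius))


def build_physiology(cfg: RunConfig) -> SpeciesPhysiology:
    sp = cfg.species
    return SpeciesPhysiology(
        n_o=sp.n_o,
        pmax_slope=sp.pmax_slope,
        r_d=sp.r_d,
        quantum_yield=sp.quantum_yield,
        theta=sp.theta,
        name=sp.name,
    )


def build_sky_from(cfg: RunConfig) -> SkyModel:
    return build_sky(
        n_elevation=cfg.sky.n_elevation,
        n_azimuth=cfg.sky.n_azimuth,
        sky_type=cfg.sky.type,
        i_o=cfg.sky.io,
    )


def _fractions_to_spec(dist: LeafAngleDistribution) -> FractionSpec:
    if dist.is_spherical:
        return "spherical"
    return [[a, f] for a, f in zip(dist.angles_deg, dist.fractions)]


def scene_to_dict(scene: Scene) -> dict:
    """Serialise a scene to the config schema (tree volume + l:w form)."""
    tree = scene.tree
    return {
        "tree": {
            "height": tree.height,
            "crown_volume": tree.crown_volume,
            "lw_ratio": tree.crown_length / tree.crown_width,
            "leaf_area": tree.leaf_area,
            "lad": tree.lad,
            "leaf_angle_fractions": _fractions_to_spec(tree.leaf_angles),
        },
        "stand": {
            "height": scene.stand.height,
            "lai": scene.stand.lai,
            "leaf_angle_fractions": _fractions_to_spec(scene.stand.leaf_angles),
        },
        "gap": {"radius": scene.gap.radius},
    }


def scene_from_dict(data: dict) -> Scene:
    tree_cfg = TreeConfig.model_validate(data["tree"])
    stand_cfg = StandConfig.model_validate(data["stand"])
    gap_cfg = GapConfig.model_validate(data.get("gap", {"radius": 0.0}))
    dummy = RunConfig(
        tree=tree_cfg,
        stand=stand_cfg,
        gap=gap_cfg,
        species=SpeciesConfig(n_o=1.0, pmax_slope=1.0, r_d=0.0, quantum_yield=0.01),
    )
    return build_scene(dummy)


def write_results(table: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write a result table as CSV (UTF-8, '.' decimal) or JSON records."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")
    log.debug("wrote %d rows to %s", len(table), path)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


def run_metadata(cfg: RunConfig, command: str = "") -> dict:
    """Reconstructible description of a run: config hash, resolutions, versions."""
    dump = cfg.model_dump()
    canonical = json.dumps(dump, sort_keys=True)
    return {
        "command": command,
        "config": dump,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "versions": {
            "pholiage": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
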