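"""Run configuration: a single YAML file with geometry / forcefield /
protocol / analysis sections, shared by all CLI subcommands."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .core import NanostarGeometry
from .simulate import ForceField, LangevinParams, SimulationProtocol

logger = logging.getLogger("nanolink")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def load_config(path: str | Path | None) -> dict:
    """Parse the YAML run configuration (empty dict when no file given)."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return data


def geometry_from_config(cfg: dict) -> NanostarGeometry:
    section = cfg.get("geometry", {})
    if "bead_coords" in section:
        return NanostarGeometry(
            bead_coords=np.array(section["bead_coords"], dtype=float),
            patch_coords=np.array(section["patch_coords"], dtype=float),
            patch_diameter=float(section.get("patch_diameter", 0.2)),
        )
    return NanostarGeometry.default(
        patch_diameter=float(section.get("patch_diameter", 0.2))
    )


def forcefield_from_config(cfg: dict) -> ForceField:
    section = cfg.get("forcefield", {})
    return ForceField(
        epsilon=float(section.get("epsilon", 1.0)),
        morse_depth=float(section.get("morse_depth", 20.0)),
        morse_alpha=float(section.get("morse_alpha", 8.0)),
        morse_cutoff=float(section.get("morse_cutoff", 0.5)),
    )


def protocol_from_config(cfg: dict) -> SimulationProtocol:
    section = cfg.get("protocol", {})
    return SimulationProtocol(
        equilibration=float(section.get("equilibration", 100.0)),
        production=float(section.get("production", 1000.0)),
        frame_interval=float(section.get("frame_interval", 50.0)),
        stress_interval=float(section.get("stress_interval", 0.1)),
    )


def langevin_from_config(cfg: dict, seed: int) -> LangevinParams:
    section = cfg.get("protocol", {})
    return LangevinParams(
        dt=float(section.get("dt", 0.01)),
        friction=float(section.get("friction", 1.0)),
        temperature=float(section.get("temperature", 1.0)),
        seed=seed,
    )
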