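"""Run configuration: validated YAML with defaults echoed into outputs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .equilibrium import Conditions, SpeciesLadder
from .geometry import GeometryParams, ParameterError

__all__ = ["RunConfig", "load_config", "default_config_dict"]

_KNOWN_KEYS = {
    "geometry",
    "ladder",
    "conditions",
    "boxcount",
    "seed",
    "out_dir",
    "stages",
    "verbosity",
}
_GEOMETRY_KEYS = {
    "hexamer_width",
    "monomer_radius",
    "ring_radius",
    "dihedral_level1",
    "dihedral_level2",
    "planar",
}
_LADDER_KEYS = {"K_dim", "K_hex", "K_f1", "K_f2"}
_CONDITION_KEYS = {
    "total_subunit_conc",
    "pH",
    "pKa",
    "n_protonatable_per_fractal_interface",
    "ligand_conc",
    "K_L",
    "coupling_order",
}
_BOXCOUNT_KEYS = {"box_sizes", "offsets"}
_ALL_STAGES = [
    "generate",
    "interfaces",
    "rasterize",
    "boxcount",
    "saxs",
    "equilibrium",
    "mp",
]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    ladder: SpeciesLadder = field(default_factory=SpeciesLadder)
    conditions: Conditions = field(default_factory=Conditions)
    box_sizes: tuple | None = None
    offsets: tuple | None = None
    seed: int = 0
    out_dir: str = "fractasm_out"
    stages: list = field(default_factory=lambda: list(_ALL_STAGES))
    verbosity: int = 1

    def resolved_dict(self) -> dict:
        """Fully resolved configuration (all defaults applied)."""
        return {
            "geometry": asdict(self.geometry),
            "ladder": asdict(self.ladder),
            "conditions": asdict(self.conditions),
            "boxcount": {"box_sizes": self.box_sizes, "offsets": self.offsets},
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": list(self.stages),
            "verbosity": self.verbosity,
        }


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration; unknown keys are rejected."""
    if isinstance(path_or_dict, (str, Path)):
        doc = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        doc = dict(path_or_dict)
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(doc, _KNOWN_KEYS, "config")
    _check_keys(doc.get("geometry", {}) or {}, _GEOMETRY_KEYS, "geometry")
    _check_keys(doc.get("ladder", {}) or {}, _LADDER_KEYS, "ladder")
    _check_keys(doc.get("conditions", {}) or {}, _CONDITION_KEYS, "conditions")
    _check_keys(doc.get("boxcount", {}) or {}, _BOXCOUNT_KEYS, "boxcount")
    stages = doc.get("stages", list(_ALL_STAGES))
    bad = set(stages) - set(_ALL_STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    try:
        geometry = GeometryParams(**(doc.get("geometry", {}) or {}))
        ladder = SpeciesLadder(**(doc.get("ladder", {}) or {}))
        conditions = Conditions(**(doc.get("conditions", {}) or {}))
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    bc = doc.get("boxcount", {}) or {}
    return RunConfig(
        geometry=geometry,
        ladder=ladder,
        conditions=conditions,
        box_sizes=tuple(bc["box_sizes"]) if bc.get("box_sizes") else None,
        offsets=tuple(tuple(o) for o in bc["offsets"]) if bc.get("offsets") else None,
        seed=int(doc.get("seed", 0)),
        out_dir=str(doc.get("out_dir", "fractasm_out")),
        stages=list(stages),
        verbosity=int(doc.get("verbosity", 1)),
    )


def default_config_dict() -> dict:
    return json.loads(json.dumps(RunConfig().resolved_dict()))
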