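"""File formats: bead-model PDB, assembly JSON, event/profile CSV, PNG.

The package's canonical interchange format for assemblies is JSON
(positions, bonds, provenance); coarse-grained bead models are also
written as PDB (one HETATM per monomer, nm converted to Angstrom, one
chain per hexamer, residue number per dimer) for viewing in standard
structure software.  Images are 8-bit PNG/TIFF with 0 background and
255 foreground.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from PIL import Image

from .fractaldim import RasterImage
from .geometry import (
    Assembly,
    Dimer,
    GeometryParams,
    Hexamer,
    Monomer,
)
from .mp import MPEventSet
from .structure import BeadModel, ScatteringProfile

__all__ = [
    "assembly_to_json",
    "assembly_from_json",
    "write_assembly_json",
    "read_assembly_json",
    "write_pdb",
    "read_pdb_beads",
    "write_image",
    "read_image",
    "write_events_csv",
    "read_events_csv",
    "write_profile_csv",
    "read_profile_csv",
]

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


# ---------------------------------------------------------------------------
# assembly JSON
# ---------------------------------------------------------------------------

def assembly_to_json(assembly: Assembly) -> dict:
    p = assembly.params
    return {
        "format": "fractasm-assembly",
        "version": 1,
        "level": assembly.level,
        "params": {
            "hexamer_width": p.hexamer_width,
            "monomer_radius": p.monomer_radius,
            "ring_radius": p.ring_radius,
            "dihedral_level1": p.dihedral_level1,
            "dihedral_level2": p.dihedral_level2,
            "planar": p.planar,
        },
        "hexamers": [
            {
                "id": h.id,
                "dimer_ids": list(h.dimer_ids),
                "center": [float(x) for x in h.center],
                "orientation": h.orientation,
                "lattice": list(h.lattice) if h.lattice is not None else None,
            }
            for h in assembly.hexamers
        ],
        "dimers": [
            {
                "id": d.id,
                "monomer_ids": list(d.monomer_ids),
                "hexamer_id": d.hexamer_id,
                "corner_direction": [float(x) for x in d.corner_direction],
                "slot": d.slot,
            }
            for d in assembly.dimers
        ],
        "monomers": [
            {
                "id": m.id,
                "dimer_id": m.dimer_id,
                "position": [float(x) for x in m.position],
                "participates": bool(m.participates),
            }
            for m in assembly.monomers
        ],
        "fractal_bonds": [list(b) for b in assembly.fractal_bonds],
        "provenance": _jsonable(assembly.provenance),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def assembly_from_json(doc: dict) -> Assembly:
    if doc.get("format") != "fractasm-assembly":
        raise ValueError("not a fractasm assembly document")
    params = GeometryParams(**doc["params"])
    hexamers = [
        Hexamer(
            id=h["id"],
            dimer_ids=tuple(h["dimer_ids"]),
            center=np.array(h["center"], dtype=float),
            orientation=h["orientation"],
            lattice=tuple(h["lattice"]) if h.get("lattice") else None,
        )
        for h in doc["hexamers"]
    ]
    dimers = [
        Dimer(
            id=d["id"],
            monomer_ids=tuple(d["monomer_ids"]),
            hexamer_id=d["hexamer_id"],
            corner_direction=np.array(d["corner_direction"], dtype=float),
            slot=d["slot"],
        )
        for d in doc["dimers"]
    ]
    monomers = [
        Monomer(
            id=m["id"],
            dimer_id=m["dimer_id"],
            position=np.array(m["position"], dtype=float),
            participates=m["participates"],
        )
        for m in doc["monomers"]
    ]
    level = doc["level"]
    return Assembly(
        level=level,
        hexamers=hexamers,
        dimers=dimers,
        monomers=monomers,
        fractal_bonds=[tuple(b) for b in doc["fractal_bonds"]],
        params=params,
        provenance=doc.get("provenance", {}),
    )


def write_assembly_json(assembly: Assembly, path) -> None:
    Path(path).write_text(json.dumps(assembly_to_json(assembly), indent=1))


def read_assembly_json(path) -> Assembly:
    return assembly_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# PDB bead models
# ---------------------------------------------------------------------------

def write_pdb(assembly: Assembly, path) -> None:
    """Coarse-grained PDB: one HETATM per monomer, chain per hexamer.

    Coordinates are converted nm -> Angstrom; the residue number within a
    chain is the dimer index (1..3) and the bead is a carbon pseudo-atom.
    """
    st = gemmi.Structure()
    st.name = "fractasm coarse-grained bead model"
    model = gemmi.Model("1")
    for h in assembly.hexamers:
        chain = gemmi.Chain(_CHAIN_IDS[h.id % len(_CHAIN_IDS)])
        for local, d_id in enumerate(h.dimer_ids, start=1):
            d = assembly.dimers[d_id]
            res = gemmi.Residue()
            res.name = "CGB"
            res.seqid = gemmi.SeqId(local, " ")
            res.het_flag = "H"
            for m_id in d.monomer_ids:
                m = assembly.monomers[m_id]
                atom = gemmi.Atom()
                atom.name = "C"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*(np.asarray(m.position) * 10.0))
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb_beads(path) -> BeadModel:
    """Read any PDB as a bead model (all atoms, Angstrom -> nm)."""
    st = gemmi.read_structure(str(path))
    pos = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break
    if not pos:
        raise ValueError(f"no atoms in {path}")
    return BeadModel(positions=np.array(pos) / 10.0)


# ---------------------------------------------------------------------------
# images, events, profiles
# ---------------------------------------------------------------------------

def write_image(image: RasterImage, path) -> None:
    arr = (image.pixels.astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(str(path))


def read_image(path, px_per_nm: float = 1.0) -> RasterImage:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return RasterImage(pixels=arr >= 128, px_per_nm=px_per_nm)


def write_events_csv(events: MPEventSet, path) -> None:
    """Single-column CSV of event masses plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"mass_kDa": events.event_masses}).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_jsonable(events.metadata), indent=1)
    )


def read_events_csv(path) -> MPEventSet:
    path = Path(path)
    masses = pd.read_csv(path)["mass_kDa"].to_numpy()
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return MPEventSet(event_masses=masses, metadata=meta)


def write_profile_csv(profile: ScatteringProfile, path) -> None:
    df = pd.DataFrame({"q_inv_nm": profile.q, "intensity": profile.intensity})
    if profile.noise_sd is not None:
        df["noise_sd"] = profile.noise_sd
    df.to_csv(path, index=False)


def read_profile_csv(path) -> ScatteringProfile:
    df = pd.read_csv(path)
    return ScatteringProfile(
        q=df["q_inv_nm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        noise_sd=df["noise_sd"].to_numpy() if "noise_sd" in df else None,
    )
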