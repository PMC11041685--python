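"""Generators for hexamer building blocks and Sierpinski-order assemblies.

The modelled system is a homo-oligomeric enzyme whose dimers close into a
D3-symmetric hexameric ring; hexamers then join corner-to-corner through a
single dimer--dimer "fractal" interface into first- and second-order
Sierpinski triangles (18mers, 54mers) or into compact triangular lattices
(36mer-type).  All generators build planar (z = 0) coarse-grained bead
models: one bead per monomer, three dimers per hexamer, one fractal-capable
corner per dimer.  Out-of-plane dihedrals are applied only by the closure
analysis in :mod:`fractasm.structure`.

Hexamer centers live on a triangular lattice with spacing equal to
``hexamer_width``.  In axial coordinates ``(q, r)`` a hexamer sits at
``hexamer_width * (q + r/2, r*sqrt(3)/2)``.  Every hexamer carries the same
orientation (corner dimers pointing at 90, 210 and 330 degrees), which makes
the corner sites of adjacent hexamers meet pairwise inside the downward-
pointing lattice cells -- the geometric encoding of the chirally wrapped
dimer--dimer contact that passivates triangle edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryParams",
    "Monomer",
    "Dimer",
    "Hexamer",
    "Assembly",
    "build_hexamer",
    "build_sierpinski",
    "build_compact_triangle",
    "assembly_from_lattice",
    "sierpinski_lattice_cells",
    "compact_triangle_cells",
    "chaos_game",
    "pascal_parity",
    "subdivision_triangles",
    "subunit_count",
    "lattice_position",
    "CORNER_ANGLES",
]

#: Corner-dimer directions (degrees) shared by every hexamer on the lattice.
CORNER_ANGLES = (90.0, 210.0, 330.0)

SQRT3 = math.sqrt(3.0)


class ParameterError(ValueError):
    """Invalid geometry or generator parameter."""


class GeometryError(ValueError):
    """Degenerate geometric input (e.g. collinear chaos-game vertices)."""


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


@dataclass(frozen=True)
class GeometryParams:
    """Coarse-grained geometry of the hexameric building block.

    Parameters
    ----------
    hexamer_width:
        Center-to-center spacing of adjacent hexamers (nm).  The default of
        10 nm is calibrated so that a three-hexamer triangle edge spans the
        30 nm measured for the compact 36mer.
    monomer_radius:
        Bead radius of one monomer (nm).
    ring_radius:
        Distance of monomer centers from the hexamer center (nm).  Defaults
        to ``hexamer_width / 3``, the unique choice for which the radius of
        gyration doubles exactly per fractal level (self-similar scaling).
    dihedral_level1, dihedral_level2:
        Dimer--dimer interface dihedrals (degrees) characteristic of the
        hexamer-hexamer and 18mer-18mer joins.
    planar:
        Generators always build in-plane; dihedrals are applied only by the
        closure analysis.
    """

    hexamer_width: float = 10.0
    monomer_radius: float = 2.2
    ring_radius: float | None = None
    dihedral_level1: float = 60.0
    dihedral_level2: float = 34.0
    planar: bool = True

    def __post_init__(self):
        if self.ring_radius is None:
            object.__setattr__(self, "ring_radius", self.hexamer_width / 3.0)
        for name in ("hexamer_width", "monomer_radius", "ring_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("dihedral_level1", "dihedral_level2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 180.0):
                raise ParameterError(f"{name} must lie in [0, 180] deg, got {v}")


@dataclass
class Monomer:
    id: int
    dimer_id: int
    position: np.ndarray  # (3,) nm
    participates: bool = False


@dataclass
class Dimer:
    id: int
    monomer_ids: tuple[int, int]
    hexamer_id: int
    corner_direction: np.ndarray  # unit 2-vector in the assembly plane
    slot: str = "open"  # "open" | "bonded"


@dataclass
class Hexamer:
    id: int
    dimer_ids: tuple[int, int, int]
    center: np.ndarray  # (3,) nm
    orientation: float = CORNER_ANGLES[0]  # deg of the first corner dimer
    lattice: tuple[int, int] | None = None  # axial (q, r) if lattice-placed


@dataclass
class Assembly:
    """A hierarchical coarse-grained assembly of hexamers.

    ``level`` is the Sierpinski order for fractal assemblies, or the tags
    ``"compact"`` / ``"custom"``.  ``fractal_bonds`` lists realized
    dimer-id pairs (one bond per dimer at most -- edge passivation).
    """

    level: int | str
    hexamers: list[Hexamer]
    dimers: list[Dimer]
    monomers: list[Monomer]
    fractal_bonds: list[tuple[int, int]]
    params: GeometryParams
    provenance: dict = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------
    @property
    def n_subunits(self) -> int:
        return len(self.monomers)

    def monomer_positions(self) -> np.ndarray:
        return np.array([m.position for m in self.monomers], dtype=float)

    def hexamer_centers(self) -> np.ndarray:
        return np.array([h.center for h in self.hexamers], dtype=float)

    def dimer_by_id(self, dimer_id: int) -> Dimer:
        d = self.dimers[dimer_id]
        if d.id != dimer_id:  # pragma: no cover - ids are dense by construction
            d = next(x for x in self.dimers if x.id == dimer_id)
        return d

    def hexamer_by_id(self, hexamer_id: int) -> Hexamer:
        h = self.hexamers[hexamer_id]
        if h.id != hexamer_id:  # pragma: no cover
            h = next(x for x in self.hexamers if x.id == hexamer_id)
        return h

    def dimer_corner_site(self, dimer_id: int) -> np.ndarray:
        """In-plane contact site of a dimer's fractal-capable corner.

        Defined as the hexamer center plus half a hexamer width along the
        dimer's corner direction.
        """
        d = self.dimer_by_id(dimer_id)
        h = self.hexamer_by_id(d.hexamer_id)
        return h.center[:2] + d.corner_direction * (self.params.hexamer_width / 2.0)

    def dimer_com(self, dimer_id: int) -> np.ndarray:
        d = self.dimer_by_id(dimer_id)
        p = np.array([self.monomers[i].position for i in d.monomer_ids])
        return p.mean(axis=0)

    def participating_monomer(self, dimer_id: int) -> Monomer:
        d = self.dimer_by_id(dimer_id)
        for mid in d.monomer_ids:
            if self.monomers[mid].participates:
                return self.monomers[mid]
        raise GeometryError(f"dimer {dimer_id} has no participating monomer")


# ---------------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------------

def lattice_position(cell: tuple[int, int], hexamer_width: float) -> np.ndarray:
    """Cartesian (x, y) of an axial lattice cell ``(q, r)``."""
    q, r = cell
    return hexamer_width * np.array([q + r / 2.0, r * SQRT3 / 2.0])


def _dimer_cells(cell: tuple[int, int]) -> list[tuple[int, int]]:
    """Down-cell key occupied by each of a hexamer's three corner dimers.

    A down-cell C(a, b) is the downward-pointing lattice triangle whose
    member hexamers are (a, b), (a, b+1) and (a-1, b+1).  The dimer at
    90 deg of hexamer (q, r) points into C(q, r); the 210 deg dimer into
    C(q, r-1); the 330 deg dimer into C(q+1, r-1).
    """
    q, r = cell
    return [(q, r), (q, r - 1), (q + 1, r - 1)]


def sierpinski_lattice_cells(level: int) -> list[tuple[int, int]]:
    """Axial hexamer-center cells of a Sierpinski-order assembly."""
    if level < 0:
        raise ParameterError(f"level must be >= 0, got {level}")
    cells = [(0, 0)]
    for k in range(1, level + 1):
        s = 2 ** (k - 1)
        cells = (
            cells
            + [(q + s, r) for q, r in cells]
            + [(q, r + s) for q, r in cells]
        )
    return cells


def compact_triangle_cells(rows: int) -> list[tuple[int, int]]:
    """Axial cells of a close-packed upward triangle with ``rows`` rows."""
    if rows < 1:
        raise ParameterError(f"rows must be >= 1, got {rows}")
    return [(q, r) for r in range(rows) for q in range(rows - r)]


def assembly_from_lattice(
    cells: Sequence[tuple[int, int]],
    params: GeometryParams | None = None,
    *,
    level: int | str = "custom",
    assign_bonds: bool = True,
    provenance: dict | None = None,
) -> Assembly:
    """Build an assembly from hexamers placed on the triangular lattice.

    When ``assign_bonds`` is true, one fractal bond is booked per down-cell
    shared by exactly two hexamers (the generator knows which corner dimers
    meet; geometric re-derivation lives in :mod:`fractasm.interfaces`).
    Cells occupied by three hexamers host an ambiguous three-way junction
    and are left unbonded here.
    """
    params = params or GeometryParams()
    cells = list(cells)
    if len(set(cells)) != len(cells):
        raise ParameterError("duplicate lattice cells")
    w = params.hexamer_width

    hexamers: list[Hexamer] = []
    dimers: list[Dimer] = []
    monomers: list[Monomer] = []
    cell_map: dict[tuple[int, int], list[int]] = {}

    for h_id, cell in enumerate(cells):
        cxy = lattice_position(cell, w)
        center = np.array([cxy[0], cxy[1], 0.0])
        d_ids = []
        for j, ang in enumerate(CORNER_ANGLES):
            d_id = 3 * h_id + j
            m_ids = (2 * d_id, 2 * d_id + 1)
            # participating (interface-facing) monomer sits clockwise of the
            # corner; its partner's termini face outward and passivate.
            for k, m_ang in enumerate((ang - 30.0, ang + 30.0)):
                pos2 = cxy + params.ring_radius * _unit(m_ang)
                monomers.append(
                    Monomer(
                        id=m_ids[k],
                        dimer_id=d_id,
                        position=np.array([pos2[0], pos2[1], 0.0]),
                        participates=(k == 0),
                    )
                )
            dimers.append(
                Dimer(
                    id=d_id,
                    monomer_ids=m_ids,
                    hexamer_id=h_id,
                    corner_direction=_unit(ang),
                )
            )
            d_ids.append(d_id)
            cell_map.setdefault(_dimer_cells(cell)[j], []).append(d_id)
        hexamers.append(
            Hexamer(
                id=h_id,
                dimer_ids=tuple(d_ids),
                center=center,
                orientation=CORNER_ANGLES[0],
                lattice=cell,
            )
        )

    bonds: list[tuple[int, int]] = []
    if assign_bonds:
        for members in cell_map.values():
            if len(members) == 2:
                a, b = sorted(members)
                bonds.append((a, b))
                dimers[a].slot = "bonded"
                dimers[b].slot = "bonded"
        bonds.sort()

    return Assembly(
        level=level,
        hexamers=hexamers,
        dimers=dimers,
        monomers=monomers,
        fractal_bonds=bonds,
        params=params,
        provenance=provenance or {"generator": "assembly_from_lattice", "cells": cells},
    )


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def build_hexamer(params: GeometryParams | None = None) -> Assembly:
    """A single D3-symmetric hexamer: 6 monomers, 3 dimers, no bonds."""
    params = params or GeometryParams()
    return assembly_from_lattice(
        [(0, 0)],
        params,
        level=0,
        provenance={"generator": "build_hexamer"},
    )


def build_sierpinski(level: int, params: GeometryParams | None = None) -> Assembly:
    """Sierpinski-order assembly of ``3**level`` hexamers.

    Level ``k`` places three level-``k-1`` copies at the corners of an
    upward equilateral triangle (centroid spacing ``2**(k-1)`` hexamer
    widths) and adds one fractal bond per copy pair; the resulting edge
    spans ``2**k`` hexamer widths.
    """
    if level < 0:
        raise ParameterError(f"level must be >= 0, got {level}")
    params = params or GeometryParams()
    cells = sierpinski_lattice_cells(level)
    asm = assembly_from_lattice(
        cells,
        params,
        level=level,
        provenance={"generator": "build_sierpinski", "level": level},
    )
    return asm


def build_compact_triangle(rows: int, params: GeometryParams | None = None) -> Assembly:
    """Close-packed triangular (36mer-type) assembly with ``rows`` rows.

    Bonds are *not* assigned: for compact lattices the maximal consistent
    bond set is decided by :func:`fractasm.interfaces.realize_bonds`.
    """
    if rows < 1:
        raise ParameterError(f"rows must be >= 1, got {rows}")
    params = params or GeometryParams()
    return assembly_from_lattice(
        compact_triangle_cells(rows),
        params,
        level="compact",
        assign_bonds=False,
        provenance={"generator": "build_compact_triangle", "rows": rows},
    )


def subunit_count(level: int) -> int:
    """Subunits of a Sierpinski-order assembly: 6 * 3**level (6, 18, 54, 162...)."""
    if level < 0:
        raise ParameterError(f"level must be >= 0, got {level}")
    return 6 * 3 ** level


# ---------------------------------------------------------------------------
# reference fractal constructions
# ---------------------------------------------------------------------------

_EQUILATERAL = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, SQRT3 / 2.0]])


def chaos_game(
    n_points: int,
    seed: int,
    vertices: np.ndarray | None = None,
    burn_in: int = 10,
) -> np.ndarray:
    """Sample the Sierpinski attractor by the stochastic chaos game.

    Iterates the midpoint map ``p <- (p + v_r)/2`` with ``v_r`` drawn
    uniformly from the three triangle vertices, discarding ``burn_in``
    initial iterates.  Fully reproducible from ``seed``.
    """
    if n_points < 1:
        raise ParameterError(f"n_points must be >= 1, got {n_points}")
    verts = _EQUILATERAL if vertices is None else np.asarray(vertices, dtype=float)
    if verts.shape != (3, 2):
        raise GeometryError(f"expected three 2D vertices, got shape {verts.shape}")
    area2 = abs(np.cross(verts[1] - verts[0], verts[2] - verts[0]))
    if area2 < 1e-12 * max(1.0, np.abs(verts).max() ** 2):
        raise GeometryError("chaos game vertices are collinear")

    rng = np.random.default_rng(seed)
    choices = rng.integers(0, 3, size=n_points + burn_in)
    p = verts.mean(axis=0)
    out = np.empty((n_points, 2))
    for i, c in enumerate(choices):
        p = 0.5 * (p + verts[c])
        if i >= burn_in:
            out[i - burn_in] = p
    return out


def pascal_parity(n_rows: int) -> np.ndarray:
    """Boolean mask of odd binomial coefficients in Pascal's triangle.

    Entry ``[r, c]`` (``c <= r < n_rows``) is true iff ``C(r, c)`` is odd,
    via the bit identity ``(r & c) == c`` (Kummer/Lucas) -- no big-integer
    arithmetic.  Entries above the diagonal are false.
    """
    if n_rows < 1:
        raise ParameterError(f"n_rows must be >= 1, got {n_rows}")
    r = np.arange(n_rows, dtype=np.int64)[:, None]
    c = np.arange(n_rows, dtype=np.int64)[None, :]
    return ((r & c) == c) & (c <= r)


def subdivision_triangles(depth: int, vertices: np.ndarray | None = None) -> np.ndarray:
    """Filled sub-triangles of the Sierpinski set by recursive subdivision.

    Returns an array of shape ``(3**depth, 3, 2)``: the corner triangles
    kept after ``depth`` rounds of midpoint subdivision.
    """
    if depth < 0:
        raise ParameterError(f"depth must be >= 0, got {depth}")
    verts = _EQUILATERAL if vertices is None else np.asarray(vertices, dtype=float)
    tris = verts[None, :, :]
    for _ in range(depth):
        a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        tris = np.concatenate(
            [
                np.stack([a, ab, ca], axis=1),
                np.stack([ab, b, bc], axis=1),
                np.stack([ca, bc, c], axis=1),
            ]
        )
    return tris
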