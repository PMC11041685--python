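"""Fractal-interface accounting: contacts, passivation, frustration.

The fractal interface joins exactly two dimers of adjacent hexamers, and a
dimer can hold at most one such bond (its second monomer's termini face
outward and sterically passivate the edge).  Where three corner sites meet
-- the three-way junction at the center of compact triangular lattices --
at most one pairwise bond can form, because the interface cannot support a
three-fold association.  ``realize_bonds`` computes the maximum-cardinality
bond set under those two rules exactly; ``frustration_scan`` shows that at
Sierpinski stoichiometries this maximum leaves only the three triangle
corners unsatisfied and that no other placement of the same number of
hexamers does better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .geometry import (
    Assembly,
    GeometryParams,
    ParameterError,
    _dimer_cells,
    lattice_position,
)

__all__ = [
    "InterfaceGraph",
    "FrustrationRecord",
    "find_candidate_contacts",
    "realize_bonds",
    "count_unsatisfied",
    "frustration_scan",
    "lattice_max_bonds",
    "enumerate_polyhexes",
]


class ModelError(ValueError):
    """Assembly lacks the data needed for interface analysis."""


class SizeLimitError(ValueError):
    """Input exceeds the exact-solver size limit."""


@dataclass
class InterfaceGraph:
    """Candidate and realized dimer--dimer fractal contacts of an assembly."""

    assembly: Assembly
    n_dimers: int
    candidate_contacts: list[tuple[int, int]]
    junction_groups: list[frozenset[int]]
    realized_bonds: list[tuple[int, int]] = field(default_factory=list)
    contact_tolerance: float = 0.0

    @property
    def n_unsatisfied(self) -> int:
        return self.n_dimers - 2 * len(self.realized_bonds)


@dataclass
class FrustrationRecord:
    """Minimum unsatisfied-dimer count over all n-hexamer placements."""

    n_hexamers: int
    n_subunits: int
    min_unsatisfied: int
    optimal_shapes: list[tuple[tuple[int, int], ...]]
    n_shapes_scanned: int = 0

    def optimal_centers(self, params: GeometryParams | None = None) -> list[np.ndarray]:
        params = params or GeometryParams()
        return [
            np.array([lattice_position(c, params.hexamer_width) for c in shape])
            for shape in self.optimal_shapes
        ]


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def find_candidate_contacts(
    assembly: Assembly, contact_tolerance: float | None = None
) -> InterfaceGraph:
    """Enumerate candidate fractal contacts between dimers of different hexamers.

    Two dimers are candidates when their corner sites (hexamer center plus
    half a hexamer width along the corner direction) lie within
    ``contact_tolerance`` (default ``0.15 * hexamer_width``).  Junction
    groups are single-linkage clusters of >= 3 mutually proximal corner
    sites; each can host at most one realized bond.
    """
    if contact_tolerance is None:
        contact_tolerance = 0.15 * assembly.params.hexamer_width
    if contact_tolerance <= 0:
        raise ParameterError("contact_tolerance must be positive")
    for d in assembly.dimers:
        if d.corner_direction is None or np.linalg.norm(d.corner_direction) == 0:
            raise ModelError(f"dimer {d.id} has no corner direction")

    n = len(assembly.dimers)
    contacts: list[tuple[int, int]] = []
    if n > 1:
        sites = np.array([assembly.dimer_corner_site(d.id) for d in assembly.dimers])
        hex_of = np.array([d.hexamer_id for d in assembly.dimers])
        dist = squareform(pdist(sites))
        for i in range(n):
            for j in range(i + 1, n):
                if hex_of[i] != hex_of[j] and dist[i, j] <= contact_tolerance:
                    contacts.append((i, j))

    # single-linkage clusters of the contact relation; >= 3 members form a
    # junction group (the three-way meeting point of compact lattices)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in contacts:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    clusters: dict[int, set[int]] = {}
    for i, j in contacts:
        clusters.setdefault(find(i), set()).update((i, j))
    junctions = sorted(
        (frozenset(m) for m in clusters.values() if len(m) >= 3),
        key=lambda s: sorted(s),
    )

    return InterfaceGraph(
        assembly=assembly,
        n_dimers=n,
        candidate_contacts=sorted(contacts),
        junction_groups=junctions,
        contact_tolerance=contact_tolerance,
    )


# ---------------------------------------------------------------------------
# exact bond realization
# ---------------------------------------------------------------------------

MAX_EXACT_HEXAMERS = 60
_MAX_COMPONENT_CONTACTS = 24


def realize_bonds(graph: InterfaceGraph, allow_c3: bool = False) -> InterfaceGraph:
    """Realize a maximum set of fractal bonds under the passivation rules.

    Constraints: (i) each dimer participates in at most one bond; (ii) each
    junction group hosts at most one bond (dropped when ``allow_c3`` is
    true, modelling a hypothetical three-fold C3 interface).  Solved
    exactly, component by component, with lexicographic tie-breaking on
    dimer-id pairs.
    """
    if len(graph.assembly.hexamers) > MAX_EXACT_HEXAMERS:
        raise SizeLimitError(
            f"exact bond realization limited to {MAX_EXACT_HEXAMERS} hexamers, "
            f"got {len(graph.assembly.hexamers)}"
        )
    junction_of: dict[int, int] = {}
    if not allow_c3:
        for gi, grp in enumerate(graph.junction_groups):
            for d in grp:
                junction_of[d] = gi

    # connected components of the contact graph
    adj: dict[int, list[tuple[int, int]]] = {}
    for c in graph.candidate_contacts:
        adj.setdefault(c[0], []).append(c)
        adj.setdefault(c[1], []).append(c)
    seen: set[int] = set()
    bonds: list[tuple[int, int]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp_dimers = {start}
        stack = [start]
        while stack:
            d = stack.pop()
            for c in adj[d]:
                for other in c:
                    if other not in comp_dimers:
                        comp_dimers.add(other)
                        stack.append(other)
        seen |= comp_dimers
        comp_contacts = sorted(
            {c for d in comp_dimers for c in adj[d]}
        )
        if len(comp_contacts) > _MAX_COMPONENT_CONTACTS:
            raise SizeLimitError(
                f"contact component with {len(comp_contacts)} contacts exceeds "
                f"the exact-search limit of {_MAX_COMPONENT_CONTACTS}"
            )
        bonds.extend(_best_subset(comp_contacts, junction_of))

    realized = sorted(bonds)
    for d in graph.assembly.dimers:
        d.slot = "open"
    for a, b in realized:
        graph.assembly.dimers[a].slot = "bonded"
        graph.assembly.dimers[b].slot = "bonded"
    return InterfaceGraph(
        assembly=graph.assembly,
        n_dimers=graph.n_dimers,
        candidate_contacts=graph.candidate_contacts,
        junction_groups=graph.junction_groups,
        realized_bonds=realized,
        contact_tolerance=graph.contact_tolerance,
    )


def _best_subset(
    contacts: list[tuple[int, int]], junction_of: dict[int, int]
) -> list[tuple[int, int]]:
    """Exhaustive branch-and-bound: max bonds, then lexicographically least."""
    best_key: tuple | None = None
    best_set: tuple = ()

    def rec(idx: int, used: set[int], used_j: set[int], chosen: tuple):
        nonlocal best_key, best_set
        remaining = len(contacts) - idx
        if best_key is not None and len(chosen) + remaining < -best_key[0]:
            return
        if idx == len(contacts):
            key = (-len(chosen), chosen)
            if best_key is None or key < best_key:
                best_key, best_set = key, chosen
            return
        a, b = contacts[idx]
        ja, jb = junction_of.get(a), junction_of.get(b)
        feasible = (
            a not in used
            and b not in used
            and not (ja is not None and ja in used_j)
            and not (jb is not None and jb in used_j)
        )
        if feasible:  # try inclusion first: lex-smaller sets are explored first
            rec(
                idx + 1,
                used | {a, b},
                used_j | {j for j in (ja, jb) if j is not None},
                chosen + (contacts[idx],),
            )
        rec(idx + 1, used, used_j, chosen)

    rec(0, set(), set(), ())
    return list(best_set)


def count_unsatisfied(obj: Assembly | InterfaceGraph) -> int:
    """Dimers whose fractal-capable corner holds no realized bond."""
    if isinstance(obj, InterfaceGraph):
        return obj.n_dimers - 2 * len(obj.realized_bonds)
    return len(obj.dimers) - 2 * len(obj.fractal_bonds)


# ---------------------------------------------------------------------------
# lattice-level frustration scan
# ---------------------------------------------------------------------------

def lattice_max_bonds(cells: frozenset | set | list) -> int:
    """Maximum realizable bonds for hexamers on the decorated lattice.

    Each corner dimer points into a unique down-cell and each down-cell
    holds at most one bond, so the maximum is simply the number of
    down-cells bordered by at least two occupied hexamers.  Agrees with the
    geometric ``realize_bonds`` pipeline (cross-checked in tests).
    """
    cs = set(cells)
    occupancy: dict[tuple[int, int], int] = {}
    for cell in cs:
        for dc in _dimer_cells(cell):
            occupancy[dc] = occupancy.get(dc, 0) + 1
    return sum(1 for v in occupancy.values() if v >= 2)


def _canonical(cells: frozenset) -> tuple:
    """Canonical form under the parity-preserving lattice symmetries.

    Only transforms that map down-pointing lattice cells onto down-pointing
    cells are allowed (rotations by 120 deg and the vertical-axis mirror
    class): the interface bookkeeping lives on down-cells, so a 60 deg
    rotation genuinely changes a shape's bond capacity.
    """
    variants = []
    for transform in _TRANSFORMS:
        pts = [transform(q, r) for q, r in cells]
        qmin = min(p[0] for p in pts)
        rmin = min(p[1] for p in pts)
        variants.append(tuple(sorted((q - qmin, r - rmin) for q, r in pts)))
    return min(variants)


def _rot120(q, r):
    return (-q - r, q)


def _mirror(q, r):  # reflection across the vertical axis
    return (-q - r, r)


_TRANSFORMS = [
    lambda q, r: (q, r),
    _rot120,
    lambda q, r: _rot120(*_rot120(q, r)),
    _mirror,
    lambda q, r: _rot120(*_mirror(q, r)),
    lambda q, r: _rot120(*_rot120(*_mirror(q, r))),
]

_NEIGHBORS = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]

MAX_SCAN_HEXAMERS = 12


def enumerate_polyhexes(n: int) -> list[frozenset]:
    """All connected n-hexamer lattice placements, one per symmetry class."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    shapes = {frozenset([(0, 0)]): None}
    for _ in range(n - 1):
        nxt: dict[tuple, frozenset] = {}
        for shape in shapes:
            for q, r in shape:
                for dq, dr in _NEIGHBORS:
                    cell = (q + dq, r + dr)
                    if cell in shape:
                        continue
                    grown = shape | {cell}
                    nxt.setdefault(_canonical(grown), frozenset(grown))
        shapes = {v: None for v in nxt.values()}
    # return canonical translated representatives, deterministically ordered
    out = []
    for shape in shapes:
        qmin = min(q for q, _ in shape)
        rmin = min(r for _, r in shape)
        out.append(frozenset((q - qmin, r - rmin) for q, r in shape))
    return sorted(out, key=lambda s: sorted(s))


def frustration_scan(
    max_hexamers: int, params: GeometryParams | None = None
) -> list[FrustrationRecord]:
    """Exhaustively find minimal-frustration shapes for 1..max_hexamers.

    Enumerates connected hexamer placements on the triangular lattice
    (deduplicated up to parity-preserving rotation/reflection), realizes
    the maximal bond set for each, and records the minimum number of
    unsatisfied dimers together with the argmin shapes.
    """
    if max_hexamers > MAX_SCAN_HEXAMERS:
        raise SizeLimitError(
            f"exhaustive polyhex scan limited to {MAX_SCAN_HEXAMERS} hexamers"
        )
    if max_hexamers < 1:
        raise ParameterError("max_hexamers must be >= 1")
    records = []
    for n in range(1, max_hexamers + 1):
        best = None
        argmin: list[tuple] = []
        shapes = enumerate_polyhexes(n)
        for shape in shapes:
            unsat = 3 * n - 2 * lattice_max_bonds(shape)
            if best is None or unsat < best:
                best = unsat
                argmin = [tuple(sorted(shape))]
            elif unsat == best:
                argmin.append(tuple(sorted(shape)))
        records.append(
            FrustrationRecord(
                n_hexamers=n,
                n_subunits=6 * n,
                min_unsatisfied=int(best),
                optimal_shapes=argmin,
                n_shapes_scanned=len(shapes),
            )
        )
    return records
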