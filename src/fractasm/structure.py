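"""Rigid-body and scattering metrics for coarse-grained bead models.

Covers the geometric quantities used to characterise the fractal: centers
of mass, the dimer--dimer interface dihedral (4-point torsion along the
axis joining the two dimer centers of mass), rotation decomposition
between conformations (Kabsch superposition + axis--angle of the residual),
triangle-closure gap analysis, radius of gyration, the Debye scattering
forward model and Guinier fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .geometry import (
    Assembly,
    GeometryError,
    GeometryParams,
    ParameterError,
    lattice_position,
)

__all__ = [
    "BeadModel",
    "ScatteringProfile",
    "FitError",
    "center_of_mass",
    "radius_of_gyration",
    "dihedral_4point",
    "dihedral_between_dimers",
    "rotation_between_conformations",
    "closure_gap",
    "closure_root",
    "debye_profile",
    "guinier_fit",
    "mixture_rg",
    "default_q_grid",
]


class FitError(RuntimeError):
    """A scattering fit could not be performed."""


@dataclass
class BeadModel:
    """Point-bead model: positions in nm, masses in kDa (uniform default)."""

    positions: np.ndarray  # (n, 3)
    masses: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1:
            raise ParameterError("bead model needs at least one bead")
        if self.masses is None:
            self.masses = np.ones(len(self.positions))
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if (self.masses <= 0).any():
                raise ParameterError("bead masses must be positive")
            if len(self.masses) != len(self.positions):
                raise ParameterError("masses and positions length mismatch")

    @classmethod
    def from_assembly(cls, assembly: Assembly, monomer_mass: float = 44.3) -> "BeadModel":
        pos = assembly.monomer_positions()
        return cls(positions=pos, masses=np.full(len(pos), monomer_mass))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ScatteringProfile:
    """Isotropic scattering intensity on a momentum-transfer grid (nm^-1)."""

    q: np.ndarray
    intensity: np.ndarray
    noise_sd: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ParameterError("q grid must be strictly increasing")
        if np.any(self.q < 0):
            raise ParameterError("q must be non-negative")
        if np.any(self.intensity <= 0):
            raise ParameterError("intensities must be positive")


def default_q_grid(q_min: float = 0.005, q_max: float = 2.0, n: int = 400) -> np.ndarray:
    return np.linspace(q_min, q_max, n)


# ---------------------------------------------------------------------------
# rigid-body metrics
# ---------------------------------------------------------------------------

def center_of_mass(model: BeadModel) -> np.ndarray:
    total = model.masses.sum()
    if total <= 0:
        raise ParameterError("zero total mass")
    return (model.positions * model.masses[:, None]).sum(axis=0) / total


def radius_of_gyration(model: BeadModel) -> float:
    """Mass-weighted RMS distance of beads from the center of mass (nm)."""
    com = center_of_mass(model)
    d2 = ((model.positions - com) ** 2).sum(axis=1)
    return float(np.sqrt((model.masses * d2).sum() / model.masses.sum()))


def dihedral_4point(p0, p1, p2, p3, signed: bool = False) -> float:
    """Standard 4-point torsion angle (degrees) about the p1->p2 axis.

    Right-handed sign convention about the axis; range (-180, 180].
    Unsigned magnitude by default.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise GeometryError("degenerate dihedral: coincident axis points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("degenerate dihedral: collinear points")
    ang = math.degrees(
        math.atan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
    )
    return ang if signed else abs(ang)


def dihedral_between_dimers(
    assembly: Assembly, dimer_a: int, dimer_b: int, signed: bool = False
) -> float:
    """Interface dihedral between two dimers (degrees).

    4-point torsion over (outer monomer of A, com A, com B, outer monomer
    of B) where the outer monomer is the interface-participating chain;
    the axis is the line joining the two dimer centers of mass.  A planar
    assembly gives 0 (cis) by construction.
    """
    com_a = assembly.dimer_com(dimer_a)
    com_b = assembly.dimer_com(dimer_b)
    out_a = assembly.participating_monomer(dimer_a).position
    out_b = assembly.participating_monomer(dimer_b).position
    return dihedral_4point(out_a, com_a, com_b, out_b, signed=signed)


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Optimal rotation + centroids aligning ``mov`` onto ``ref``."""
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - cr, mov - cm)
    return rot, cr, cm


def rotation_between_conformations(
    reference: BeadModel,
    target: BeadModel,
    aligned_subset: np.ndarray,
    probe_subset: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Residual rotation of a probe after superposing an aligned subset.

    Superposes ``target`` onto ``reference`` by least squares on
    ``aligned_subset``, then decomposes the remaining optimal rotation of
    ``probe_subset`` into axis and angle (degrees).  Mirrors the
    free-hexamer vs in-fractal dimer-rotation comparison.
    """
    aligned_subset = np.asarray(aligned_subset, dtype=int)
    probe_subset = np.asarray(probe_subset, dtype=int)
    if len(aligned_subset) < 3 or len(probe_subset) < 3:
        raise GeometryError("subsets need >= 3 beads")
    ra = reference.positions[aligned_subset]
    ta = target.positions[aligned_subset]
    for arr in (ra, ta):
        if np.linalg.matrix_rank(arr - arr.mean(axis=0)) < 2:
            raise GeometryError("degenerate (collinear) alignment subset")
    rot, cr, cm = _kabsch(ra, ta)
    moved = rot.apply(target.positions - cm) + cr

    rp = reference.positions[probe_subset]
    mp = moved[probe_subset]
    resid, _, _ = _kabsch(rp, mp)
    rotvec = resid.inv().as_rotvec()  # rotation carrying reference probe onto target probe
    angle = math.degrees(np.linalg.norm(rotvec))
    axis = rotvec / np.linalg.norm(rotvec) if np.linalg.norm(rotvec) > 1e-12 else np.zeros(3)
    return axis, angle


# ---------------------------------------------------------------------------
# triangle closure
# ---------------------------------------------------------------------------

def _closure_frame(params: GeometryParams):
    """Hinge axes/points and the third-interface anchors of a flat 54mer.

    Three rigid first-order (18mer) units sit at the corners of the flat
    second-order triangle.  Units 1-2 and 2-3 are joined at their corner
    interfaces; the third interface (unit 3 back to unit 1) is the one
    whose closure is probed.  Anchors are the flat-configuration bond
    midpoints, rigidly attached to their units.
    """
    w = params.hexamer_width

    def site(cell, angle_deg):
        c = lattice_position(cell, w)
        a = math.radians(angle_deg)
        return np.array(
            [c[0] + 0.5 * w * math.cos(a), c[1] + 0.5 * w * math.sin(a), 0.0]
        )

    # joint 1-2: unit1 corner hexamer (1,0) SE dimer <-> unit2 hexamer (2,0) SW dimer
    j12_a, j12_b = site((1, 0), 330.0), site((2, 0), 210.0)
    # joint 2-3: unit2 hexamer (2,1) N dimer <-> unit3 hexamer (1,2) SE dimer
    j23_a, j23_b = site((2, 1), 90.0), site((1, 2), 330.0)
    # third interface: unit3 hexamer (0,2) SW dimer <-> unit1 hexamer (0,1) N dimer
    j31_a, j31_b = site((0, 2), 210.0), site((0, 1), 90.0)

    def hinge(a, b):
        axis = (b - a) / np.linalg.norm(b - a)
        return 0.5 * (a + b), axis

    return hinge(j12_a, j12_b), hinge(j23_a, j23_b), 0.5 * (j31_a + j31_b)


def closure_gap(dihedral_deg: float, params: GeometryParams | None = None) -> float:
    """Third-interface gap (nm) of a 54mer folded at a uniform dihedral.

    Units 2 and 3 are folded out of plane by ``dihedral_deg`` about their
    corner-to-corner hinge axes (hinge at the midpoint of the bonded
    corner sites); the returned gap is the distance between the two copies
    of the third-interface anchor carried by units 1 and 3.  The flat
    chain (dihedral -> 0) closes exactly; the first-order interface angle
    is too large to close the second-order triangle, so the closure root
    sits far below it.
    """
    if not (0.0 < dihedral_deg <= 180.0):
        raise ParameterError(f"dihedral must lie in (0, 180], got {dihedral_deg}")
    params = params or GeometryParams()
    (p12, a12), (p23, a23), anchor = _closure_frame(params)
    theta = math.radians(dihedral_deg)

    r2 = Rotation.from_rotvec(theta * a12)

    def apply2(x):
        return r2.apply(x - p12) + p12

    r23 = Rotation.from_rotvec(theta * a23)

    def apply3(x):
        return apply2(r23.apply(x - p23) + p23)

    return float(np.linalg.norm(apply3(anchor) - anchor))


def closure_root(
    params: GeometryParams | None = None,
    gap_tol: float = 0.1,
    theta_hi: float | None = None,
) -> float:
    """Largest dihedral (degrees) at which the third interface still closes.

    Bisection for ``closure_gap(theta) == gap_tol`` on (0, theta_hi]
    (default upper bound: the first-order interface dihedral).
    """
    params = params or GeometryParams()
    hi = theta_hi if theta_hi is not None else params.dihedral_level1
    lo = 1e-9
    if closure_gap(hi, params) <= gap_tol:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if closure_gap(mid, params) > gap_tol:
            hi = mid
        else:
            lo = mid
    return lo


# ---------------------------------------------------------------------------
# scattering
# ---------------------------------------------------------------------------

def debye_profile(model: BeadModel, q_grid: np.ndarray) -> ScatteringProfile:
    """Exact isotropic scattering of a bead model (Debye formula).

    I(q) = sum_ij sin(q r_ij)/(q r_ij) with unit bead scattering lengths;
    I(q -> 0) = n^2.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ParameterError("empty q grid")
    if np.any(q < 0):
        raise ParameterError("q must be >= 0")
    n = len(model)
    if n == 1:
        return ScatteringProfile(q=q, intensity=np.ones_like(q))
    d = pdist(model.positions)
    # sin(x)/x via np.sinc(x/pi); q=0 handled exactly (sinc(0)=1)
    x = np.outer(q, d)
    intensity = n + 2.0 * np.sinc(x / np.pi).sum(axis=1)
    return ScatteringProfile(q=q, intensity=intensity)


def guinier_fit(
    profile: ScatteringProfile, qrg_max: float = 1.3, min_points: int = 5
) -> tuple[float, float]:
    """Guinier analysis: ln I = ln I0 - q^2 Rg^2 / 3 on the low-q window.

    The window is the largest low-q run satisfying ``q * Rg_fit <= qrg_max``,
    iterated to self-consistency.  Returns ``(Rg, I0)``.
    """
    q = profile.q
    mask = q > 0
    q = q[mask]
    I = profile.intensity[mask]
    if len(q) < min_points:
        raise FitError("too few points for a Guinier fit")

    def fit(npts):
        coef = np.polyfit(q[:npts] ** 2, np.log(I[:npts]), 1)
        return coef  # slope, intercept

    npts = max(min_points, min(len(q), 15))
    for _ in range(100):
        slope, intercept = fit(npts)
        if slope >= 0:
            raise FitError("positive Guinier slope: no low-q decay")
        rg = math.sqrt(-3.0 * slope)
        new_npts = int(np.searchsorted(q, qrg_max / rg, side="right"))
        new_npts = max(min_points, min(new_npts, len(q)))
        if new_npts == npts:
            break
        npts = new_npts
    slope, intercept = fit(npts)
    if slope >= 0:
        raise FitError("positive Guinier slope: no low-q decay")
    return math.sqrt(-3.0 * slope), math.exp(intercept)


def mixture_rg(
    distribution,
    species_models: dict[int, BeadModel],
) -> float:
    """Apparent (z-average) Rg of an oligomer mixture.

    Guinier fits of mixtures weight each species by its forward scattering,
    which scales with molar concentration times mass squared:
    Rg_app^2 = sum c_n M_n^2 Rg_n^2 / sum c_n M_n^2.
    """
    conc = distribution.concentrations if hasattr(distribution, "concentrations") else dict(distribution)
    num = den = 0.0
    for n, c in conc.items():
        if c <= 0:
            continue
        if n not in species_models:
            raise ParameterError(f"no structural model for species {n}")
        rg = radius_of_gyration(species_models[n])
        m2 = float(n) ** 2
        num += c * m2 * rg ** 2
        den += c * m2
    if den == 0:
        raise ParameterError("empty mixture")
    return math.sqrt(num / den)
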