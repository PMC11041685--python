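"""Mass-photometry style quantification of oligomeric-state populations.

Single-particle mass events are histogrammed and fitted with a mixture of
Gaussians, one per candidate oligomeric species, with each component mean
anchored to ``n * monomer_mass`` within a fractional window (a stand-in
for the proprietary peak-fit of the instrument software).  Component
integrals give particle counts per species; the subunit fraction of an
n-mer follows as ``n * count_n / sum_k k * count_k`` -- the convention in
which assembly distributions are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import ParameterError

__all__ = [
    "MPEventSet",
    "MPQuantResult",
    "quantify_mp",
    "fractions_to_particles",
    "particles_to_fractions",
    "particle_fractions",
    "DEFAULT_MONOMER_MASS_KDA",
]

#: Monomer mass of the modelled citrate synthase (kDa).
DEFAULT_MONOMER_MASS_KDA = 44.3


@dataclass
class MPEventSet:
    """Simulated or measured single-particle mass events (kDa)."""

    event_masses: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.event_masses = np.asarray(self.event_masses, dtype=float)
        if self.event_masses.size < 1:
            raise ParameterError("event set needs at least one event")
        if (self.event_masses <= 0).any():
            raise ParameterError("event masses must be positive")

    def __len__(self):
        return len(self.event_masses)


@dataclass
class MPQuantResult:
    """Fitted per-species peaks and derived population fractions."""

    species: list[int]
    means: dict[int, float]
    widths: dict[int, float]
    particle_counts: dict[int, float]
    subunit_fractions: dict[int, float]
    particle_fractions: dict[int, float]
    r_squared: float
    bin_edges: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "mean_kDa": [self.means[n] for n in self.species],
                "width_kDa": [self.widths[n] for n in self.species],
                "particle_count": [self.particle_counts[n] for n in self.species],
                "particle_fraction": [self.particle_fractions[n] for n in self.species],
                "subunit_fraction": [self.subunit_fractions[n] for n in self.species],
            }
        )


def _histogram(masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Freedman--Diaconis histogram with a 5 kDa floor on the bin width."""
    q75, q25 = np.percentile(masses, [75, 25])
    iqr = q75 - q25
    width = 2 * iqr / len(masses) ** (1 / 3) if iqr > 0 else 0.0
    width = max(width, 5.0)
    lo = masses.min() - width
    hi = masses.max() + width
    nbins = max(int(math.ceil((hi - lo) / width)), 1)
    return np.histogram(masses, bins=nbins, range=(lo, lo + nbins * width))


def quantify_mp(
    events: MPEventSet | np.ndarray,
    stoichiometries=(1, 2, 6, 18, 54),
    monomer_mass: float = DEFAULT_MONOMER_MASS_KDA,
    window_frac: float = 0.1,
) -> MPQuantResult:
    """Fit anchored Gaussian peaks to a mass-event histogram.

    Each candidate species contributes one Gaussian whose mean is free
    within ``n * monomer_mass * (1 +/- window_frac)``; amplitudes and
    widths are free, and the whole mixture is fitted jointly by least
    squares (overlapping windows are thereby resolved).  Species with no
    events in their window get zero counts with a warning.
    """
    masses = events.event_masses if isinstance(events, MPEventSet) else np.asarray(events, dtype=float)
    if masses.size < 50:
        raise ParameterError(f"need >= 50 events, got {masses.size}")
    species = sorted(set(int(n) for n in stoichiometries))
    if len(species) != len(list(stoichiometries)):
        raise ParameterError("stoichiometries must be distinct")
    if any(n < 1 for n in species):
        raise ParameterError("stoichiometries must be >= 1")

    counts, edges = _histogram(masses)

    # initial parameters and bounds per species; each component is a
    # bin-integrated Gaussian (exact for widths below the bin width too),
    # parameterized by (total events, mean, sd)
    p0, lo, hi = [], [], []
    empty = []
    for n in species:
        mu = n * monomer_mass
        half = window_frac * mu
        in_win = ((masses > mu - half) & (masses < mu + half)).sum()
        if in_win == 0:
            empty.append(n)
        sigma0 = max(4.0, 0.02 * mu)
        p0 += [max(float(in_win), 1e-6), mu, sigma0]
        lo += [0.0, mu - half, 0.5]
        hi += [float(masses.size), mu + half, max(5 * sigma0, 1.0)]
    if empty:
        warnings.warn(
            f"no events within the windows of species {empty}; zero counts",
            RuntimeWarning,
        )

    from scipy.stats import norm

    def model(p):
        out = np.zeros(len(counts))
        for k in range(len(species)):
            a, mu, s = p[3 * k : 3 * k + 3]
            cdf = norm.cdf(edges, loc=mu, scale=s)
            out += a * np.diff(cdf)
        return out

    res = least_squares(
        lambda p: model(p) - counts,
        x0=p0,
        bounds=(lo, hi),
        max_nfev=20000,
    )
    p = res.x
    pred = model(p)
    ss_res = float(((counts - pred) ** 2).sum())
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    means, widths, pc = {}, {}, {}
    for k, n in enumerate(species):
        a, mu, s = p[3 * k : 3 * k + 3]
        means[n] = float(mu)
        widths[n] = float(s)
        pc[n] = float(a)
        if n in empty:
            pc[n] = 0.0
    total_p = sum(pc.values())
    pfrac = {n: (pc[n] / total_p if total_p > 0 else 0.0) for n in species}
    total_s = sum(n * pc[n] for n in species)
    sfrac = {n: (n * pc[n] / total_s if total_s > 0 else 0.0) for n in species}

    return MPQuantResult(
        species=species,
        means=means,
        widths=widths,
        particle_counts=pc,
        subunit_fractions=sfrac,
        particle_fractions=pfrac,
        r_squared=r2,
        bin_edges=edges,
    )


# ---------------------------------------------------------------------------
# convention conversions
# ---------------------------------------------------------------------------

def fractions_to_particles(
    subunit_fractions: dict[int, float], stoichiometries=None
) -> dict[int, float]:
    """Convert subunit fractions to particle (complex) fractions.

    ``particle_frac_n propto subunit_frac_n / n``; exact inverse of
    :func:`particles_to_fractions`.
    """
    items = _as_items(subunit_fractions, stoichiometries)
    raw = {n: f / n for n, f in items}
    total = sum(raw.values())
    if total <= 0:
        raise ParameterError("fractions sum to zero")
    return {n: v / total for n, v in raw.items()}


def particles_to_fractions(
    particle_fractions: dict[int, float], stoichiometries=None
) -> dict[int, float]:
    """Convert particle fractions to subunit fractions (inverse map)."""
    items = _as_items(particle_fractions, stoichiometries)
    raw = {n: f * n for n, f in items}
    total = sum(raw.values())
    if total <= 0:
        raise ParameterError("fractions sum to zero")
    return {n: v / total for n, v in raw.items()}


def particle_fractions(counts: dict[int, float]) -> dict[int, float]:
    """Normalize raw per-species particle tallies to fractions."""
    total = sum(counts.values())
    if total <= 0:
        raise ParameterError("no particles")
    return {n: c / total for n, c in counts.items()}


def _as_items(fractions, stoichiometries):
    if stoichiometries is not None:
        items = list(zip(stoichiometries, fractions))
    else:
        items = list(dict(fractions).items())
    if any(n <= 0 for n, _ in items):
        raise ParameterError("stoichiometries must be positive")
    return items
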