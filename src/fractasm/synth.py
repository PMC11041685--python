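"""Synthetic raw-data generators: MP events, noisy SAXS, degraded images.

These emulate the study's measurement modalities so the analysis pipeline
is testable end to end: single-particle mass events for oligomer mixtures
of a 44.3 kDa monomer with Gaussian mass error, Debye scattering profiles
with multiplicative noise and optional ten-frame averaging, and blur/
speckle degradation of binary silhouettes.  Every generator takes an
explicit integer seed and records it (plus the ground truth) in its
output metadata; regeneration from the same inputs is bit-identical.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.filters import gaussian as _gaussian_blur

from .equilibrium import SpeciesDistribution
from .fractaldim import RasterImage
from .geometry import ParameterError
from .mp import DEFAULT_MONOMER_MASS_KDA, MPEventSet, fractions_to_particles
from .structure import BeadModel, ScatteringProfile, debye_profile

__all__ = [
    "default_mass_error_sd",
    "simulate_mp",
    "simulate_saxs",
    "degrade_image",
]


def default_mass_error_sd(mass_kda: float) -> float:
    """Instrument mass error model: sd = max(4 kDa, 2% of species mass)."""
    return max(4.0, 0.02 * mass_kda)


def _particle_fractions(distribution) -> dict[int, float]:
    if isinstance(distribution, SpeciesDistribution):
        return fractions_to_particles(
            {n: f for n, f in distribution.subunit_fractions.items() if f > 0}
        )
    d = dict(distribution)
    total = sum(d.values())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ParameterError(f"distribution not normalized (sum {total})")
    return fractions_to_particles(d)


def simulate_mp(
    distribution,
    monomer_mass: float = DEFAULT_MONOMER_MASS_KDA,
    n_events: int = 10000,
    error_model=None,
    seed: int = 0,
) -> MPEventSet:
    """Draw single-particle mass events for an oligomer mixture.

    ``distribution`` is a :class:`SpeciesDistribution` or a mapping of
    stoichiometry to subunit fraction (normalized); particles land in
    proportion to species molar concentration.  Each event mass is
    ``n * monomer_mass`` plus Gaussian error from ``error_model``
    (callable mass -> sd; default :func:`default_mass_error_sd`).
    """
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    pfrac = _particle_fractions(distribution)
    error_model = error_model or default_mass_error_sd
    rng = np.random.default_rng(seed)
    species = sorted(pfrac)
    probs = np.array([pfrac[n] for n in species])
    draws = rng.choice(len(species), size=n_events, p=probs / probs.sum())
    true_masses = np.array([n * monomer_mass for n in species])[draws]
    sds = np.array([error_model(m) for m in true_masses])
    masses = np.abs(true_masses + rng.normal(0.0, 1.0, n_events) * sds)
    return MPEventSet(
        event_masses=masses,
        metadata={
            "seed": seed,
            "monomer_mass": monomer_mass,
            "true_particle_fractions": pfrac,
            "true_subunit_fractions": (
                dict(distribution.subunit_fractions)
                if isinstance(distribution, SpeciesDistribution)
                else dict(distribution)
            ),
            "n_events": n_events,
            "error_model": "max(4 kDa, 2% mass)" if error_model is default_mass_error_sd else "custom",
        },
    )


def simulate_saxs(
    model,
    q_grid: np.ndarray,
    noise_frac: float = 0.02,
    seed: int = 0,
    n_frames: int = 1,
    species_models: dict[int, BeadModel] | None = None,
) -> ScatteringProfile:
    """Noisy scattering profile of a bead model or oligomer mixture.

    A single :class:`BeadModel` gives its Debye profile; a distribution
    plus ``species_models`` gives the concentration-weighted mixture
    profile (molar concentration times each species' Debye intensity, the
    forward-scattering z-average).  Multiplicative Gaussian noise of
    relative sd ``noise_frac`` is applied per point, averaged over
    ``n_frames`` independent frames (the acquisition convention of ten
    one-second frames per sample).
    """
    if noise_frac < 0:
        raise ParameterError("noise_frac must be >= 0")
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if isinstance(model, BeadModel):
        base = debye_profile(model, q_grid)
        ideal = base.intensity
    else:
        if not species_models:
            raise ParameterError("mixture simulation needs species_models")
        conc = (
            model.concentrations
            if isinstance(model, SpeciesDistribution)
            else dict(model)
        )
        ideal = None
        for n, c in conc.items():
            if c <= 0:
                continue
            if n not in species_models:
                raise ParameterError(f"no structural model for species {n}")
            term = c * debye_profile(species_models[n], q_grid).intensity
            ideal = term if ideal is None else ideal + term
        if ideal is None:
            raise ParameterError("empty mixture")
    if noise_frac == 0:
        return ScatteringProfile(q=np.asarray(q_grid, float), intensity=ideal.copy())
    rng = np.random.default_rng(seed)
    frames = ideal[None, :] * (
        1.0 + noise_frac * rng.normal(size=(n_frames, len(ideal)))
    )
    avg = np.clip(frames.mean(axis=0), 1e-300, None)
    sd = ideal * noise_frac / math.sqrt(n_frames)
    return ScatteringProfile(q=np.asarray(q_grid, float), intensity=avg, noise_sd=sd)


def degrade_image(
    image: RasterImage,
    blur_px: float = 0.0,
    speckle_prob: float = 0.0,
    seed: int = 0,
) -> RasterImage:
    """Stain-like degradation: Gaussian blur, re-threshold, salt-and-pepper.

    ``speckle_prob`` >= 0.05 is rejected -- that much salt-and-pepper
    noise corrupts box-count dimension estimates.
    """
    if blur_px < 0:
        raise ParameterError("blur_px must be >= 0")
    if not (0.0 <= speckle_prob < 0.05):
        raise ParameterError("speckle_prob must lie in [0, 0.05)")
    pix = image.pixels.astype(float)
    if blur_px > 0:
        pix = _gaussian_blur(pix, sigma=blur_px, preserve_range=True)
    out = pix >= 0.5
    if speckle_prob > 0:
        rng = np.random.default_rng(seed)
        flips = rng.random(out.shape) < speckle_prob
        out = np.logical_xor(out, flips)
    return RasterImage(
        pixels=out, px_per_nm=image.px_per_nm, render_style=image.render_style
    )
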