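# Methods

This note records the models, conventions, calibrations and numerical
choices behind `fractasm`, and what its synthetic data do and do not
emulate.

## Coarse-grained geometry

One bead per monomer, two beads per dimer, three dimers per hexamer.
Monomers sit at 60° spacing on a ring of radius `ring_radius` around the
hexamer center; each dimer's fractal-capable corner points along the
bisector of its two monomers, so the three corner directions are 120°
apart.  All generators build in the z = 0 plane: class averages and
assembly schematics are 2D projections, and keeping the generators planar
makes every combinatorial quantity (counts, bonds, edges) exact.
Out-of-plane geometry enters only through the closure analysis.

**Lattice convention.**  Hexamer centers occupy a triangular lattice with
spacing `hexamer_width` (axial coordinates `(q, r)`, position
`w·(q + r/2, r·√3/2)`).  Every hexamer carries the same orientation, with
corner dimers at 90°, 210° and 330°.  Under this decoration each corner
dimer points into exactly one *downward-pointing* lattice cell, and the
corner sites of the 2–3 hexamers around such a cell fall pairwise within
0.134 `w` of one another — the geometric encoding of the chirally wrapped
dimer–dimer contact.  The default contact tolerance, 0.15 `w`, is chosen
so adjacent hexamers always register exactly one candidate contact while
non-adjacent corner sites (≥ 0.4 `w` apart) never do.

**Defaults and units.**  Lengths in nm, angles in degrees, 0-based
indices.  `hexamer_width = 10 nm` calibrates a three-hexamer edge to the
30 nm measured for the compact 36mer (and thereby a level-2 edge of
4 widths = 40 nm).  `ring_radius` defaults to `hexamer_width/3`
(≈ 3.33 nm): with the level-0 radius of gyration equal to `ring_radius`
and the centers' Rg growing by the triangle recursion, Rg_k² =
(w²/9)·4ᵏ + (r² − w²/9), so `r = w/3` is the unique choice for which the
radius of gyration doubles *exactly* per level and the mass–radius slope
is exactly log 3/log 2.  Any other value breaks exact self-similarity
through the level-0 anchor (e.g. r = 3.5 nm gives a 0–4-level slope of
1.544).  `monomer_radius = 2.2 nm` is an excluded-volume envelope; the
coarse spheres of bonded neighbours interdigitate by up to ~1.1 nm
(tolerance stated as 1.2 nm in the overlap invariant), as the real dimers
do at the interface.

**Sierpiński recursion.**  Level k places three level-(k−1) copies at the
corners of an upward equilateral triangle with *centroid* spacing
2^(k−1)·w; the resulting assembly edge spans 2ᵏ widths.  Because the
free corner dimers of each sub-block already point outward along the
correct directions, the recursion is a pure translation — no rotation or
rescaling — which is also how the self-similarity test verifies it.

**Participating monomer.**  Within each dimer the monomer clockwise of
the corner direction is flagged as the interface-participating chain.
With this chirality the planar coarse model reads a *trans* (180°)
4-point dihedral across every fractal bond; the atomistic interface
dihedral (60° within 18mers, 34° between them) is not reproducible at
bead resolution and is covered instead by constructed-input recovery
tests.

## Interface accounting

Candidate contacts are dimer pairs of different hexamers whose corner
sites (center + `w/2` along the corner direction) lie within tolerance;
junction groups are single-linkage clusters of ≥ 3 corner sites (in
generated assemblies these are exactly the three-way meeting points of
compact lattices).  `realize_bonds` maximises the bond count subject to
(i) at most one bond per dimer (edge passivation) and (ii) at most one
bond per junction group (no three-fold association), solved exactly by
branch-and-bound over each connected contact component, with
lexicographic tie-breaking for determinism.  The `allow_c3` flag drops
constraint (ii) to represent the rejected alternative of a true C3
interface; for three-dimer junctions it changes nothing, because a
matching can use only one edge of a triangle anyway.

`frustration_scan` enumerates all connected n-hexamer placements
(n ≤ 12) on the decorated lattice.  Shapes are deduplicated under the
*parity-preserving* symmetry group of order 6 (rotations by 120° plus
the mirror class that maps down-cells to down-cells): a 60° rotation
exchanges up- and down-pointing cells and genuinely changes a shape's
bond capacity (an up-triangle trimer leaves 3 dimers unsatisfied, a
down-triangle trimer 7), so the full 12-element lattice group would
merge inequivalent shapes.  On the decorated lattice the maximal bond
count equals the number of down-cells with ≥ 2 occupied neighbours —
each dimer belongs to exactly one cell — which the scan uses directly;
tests cross-check it against the geometric pipeline, naive subset
enumeration and an independent maximum-matching oracle.  At n = 9 the
level-2 Sierpiński layout is the *unique* minimiser (3 unsatisfied
dimers out of 27).

## Box-counting dimension

`rasterize` renders silhouettes: `disc` style one filled disc per
monomer; `ring` style one annulus per hexamer (the ring-shaped densities
of class averages), half-thickness `blob_radius_nm`.  Images are padded
by 5%; rendering is deterministic.

`box_count` overlays a non-overlapping regular grid and counts boxes
containing foreground, partial border boxes included.  Defaults follow
the published fixed-grid protocol: nine integer box sizes evenly spaced
85→17 px and three grid offsets at 0, ⅓ and ⅔ of the box size (the exact
grid positions used on the real class averages are unpublished;
box-size-proportional offsets keep the perturbation scale-consistent).
`fit_dimension` regresses log(count) on log(1/size) per offset; D is the
mean slope, its s.d. comes from the offsets, R² from the pooled fit.
Natural logs; positive-slope convention.

**Two documented protocols.**
*Class-average emulation* (`class_average_dimension`): ring style, the
level-1 assembly spanning ~300 px of a 350-px frame (the particle-box
convention of 2D classification), higher levels at the same pixel scale,
default sizes/offsets.  The annulus half-thickness of 1.05 nm renders
the thresholded stain-excluded protein core rather than the full 2.2 nm
envelope — the thresholding applied to the real class averages before
counting is unpublished, which is why the printed anchors carry a ±0.05
band.  Under this profile the rendered 18mer gives D = 1.57 ± 0.04 and
the 54mer D = 1.63 ± 0.07 (printed: 1.53 ± 0.02 and 1.67 ± 0.02).  The
residual offsets reflect morphology the emulation does not capture
(stain depth, blur differences between the sharp 1,491-particle 18mer
average and the 200-particle 54mer average).
*Dyadic reference* (`reference_sierpinski_dimension`): for the exact
subdivision-generated set, an octave ladder of box sizes (8 px to half
the canvas) on the aligned grid.  Box counts of the Sierpiński set
oscillate log-periodically with period log 2; octave-spaced aligned boxes
sample that oscillation at constant phase, and the fit recovers
1.587 ≈ log 3/log 2 (prints as 1.59) with mixed-phase ladders biased low
by up to 0.05.  The same octave/aligned protocol is used for the
chaos-game and Pascal-parity cross-checks.

## Rigid-body and scattering metrics

Dihedrals are standard 4-point torsions (right-handed about the A→B
center-of-mass axis, unsigned by default).  Rotation decomposition
superposes an aligned subset by least squares (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`) and returns the
axis–angle of the residual optimal rotation of the probe subset.

**Closure analysis.**  Three rigid level-1 units are chained at their
corner interfaces (hinge at the midpoint of the bonded corner sites,
axis along the site-to-site line) and folded out of plane by a uniform
hinge angle θ; `closure_gap(θ)` is the distance between the two copies
of the third-interface anchor.  The flat chain closes exactly, the gap
grows monotonically with θ (≈ 32 nm at the 60° first-order interface
angle, same order as the 210 Å obtained atomistically), and
`closure_root` bisects for the largest θ with gap ≤ 0.1 nm.  This
reproduces the qualitative claim — the first-order interface angle is
far too large to close the second-order triangle, so the second-level
join must flatten — without asserting the atomistic 34°.

**Scattering.**  `debye_profile` is the exact Debye sum with unit bead
scattering lengths (I(0) = n²).  `guinier_fit` iterates the low-q window
to self-consistency under q·R_g ≤ 1.3 (≥ 5 points).  Apparent mixture
R_g uses the z-average (M²-weighted) because Guinier fits of mixtures
weight species by forward scattering ∝ M²; with the equilibrium ladder
this reproduces the concentration-driven rise of apparent R_g.

## Equilibrium ladder

Species 1, 2, 6, 18, 54 with per-interface constants; overall βₙ is the
product over the species' interfaces (3/9/27 dimeric+hexameric;
3 first-level fractal bonds in the 18mer; 9 + 3 in the 54mer, matching
the generator's bond count).  The species set closes at 54 subunits:
no larger discrete species is identified experimentally, so the
concentration regime where apparent R_g exceeds the 54mer is outside
model scope.  Whether 54mers grow from preformed 18mers or by hexamer
addition is unresolved experimentally; a mass-action formulation is
pathway-agnostic by construction.

Each fractal interface is attenuated by g(pH) = (1+10^(pH−pKa))^(−m)
with m = 2 protonatable contacts (the two glutamate–histidine pairs per
interface) and by h(L) = (1+L/K_L)^(−p) with coupling order p = 2,
modelling competitive stabilisation of the open conformation (substrate
binding rotates the dimers opposite to fractal association).  pKa
defaults to 8.2 — never measured; chosen between the day/night
intracellular pH extremes 8.4/7.3 so the transition spans them — and is
exposed in configuration.  K_L defaults to 50 µM so disassembly
completes in the substrate mM range.

Conservation Σ n βₙ mⁿ = C is monotone in m and solved by bisection on
ln m with log-sum-exp accumulation (overall constants like β₅₄ overflow
double precision otherwise); 200 iterations leave relative conservation
residuals below 1e-12.

**Calibration (shipped defaults, fitted not measured).**
K_dim = K_hex = 10¹² M⁻¹ make monomer/dimer negligible above ~10 nM;
K_f1 = 2×10⁶ M⁻¹ puts 88% of subunits in 18mers at 50 nM, pH 7.5
(anchor: > 80% by mass photometry) and ~1% at pH 9 (complete
disassembly); K_f2 = 2×10⁴ M⁻¹ keeps 54mers below 0.5% of subunits at
450 nM while they dominate by 25 µM (anchor: large complexes only
reasonably common above ~25 µM).  `scripts/calibrate_ladder.py` scans
the constants against these anchors.  The activity index weights
subunit fractions by relative activity with α = 0.5 for fractal species,
the observed two-fold gap between wild type and the hexamer-only variant
under non-saturating substrate.

## Mass-photometry quantification

Events are histogrammed with Freedman–Diaconis bins (5 kDa floor) and
fitted jointly with one *bin-integrated* Gaussian per candidate species
(parameters: total events, mean anchored to n·44.3 kDa ± 10%, width).
Bin integration keeps the component integral exact even when the peak
width falls below the bin width, so the zero-noise limit recovers the
realized sample exactly; the joint fit resolves overlapping peaks.
Particle counts are the fitted component totals; subunit fractions
follow as n·countₙ/Σ k·countₖ.  Landing rates are assumed proportional
to species molar concentration.  The anchored-window mixture replaces
the instrument's proprietary peak fit; over 100 seeded replicates at
n = 5000 the mean recovered subunit fractions are biased by < 0.01.

## Synthetic data

`simulate_mp` samples species by particle fraction and adds Gaussian
mass error with sd = max(4 kDa, 2% of mass), a typical single-particle
mass resolution; it does *not* emulate detector nonlinearity, surface
binding bias or the low-mass detection cutoff, so recovery tests
demonstrate estimator correctness, not instrument robustness.
`simulate_saxs` adds multiplicative Gaussian noise per point with
optional ten-frame averaging; it has no solvent/contrast term, no
smearing and no inter-particle structure factor, so it validates the
Guinier stage, not beamline data reduction.  `degrade_image` blurs,
re-thresholds at 0.5 and applies salt-and-pepper flips; ≥ 5% speckle is
rejected outright, and the box-count estimate is verified stable
(± 0.08) up to ~0.3–0.5% speckle — at 1% an average 17-px box already
catches ~2 flipped pixels and the fixed-grid estimate shifts by ~0.12,
which is a property of the protocol, not an estimator defect.  All
generators take explicit integer seeds, record them with the ground
truth in output metadata, and regenerate bit-identically.

## Known limitations

* Geometry is planar and rigid; dihedral magnitudes, the 4.0°/4.2°
  symmetry-breaking dimer rotations and interface energetics are out of
  scope (recovery of constructed rotations is tested instead).
* The box-count emulation cannot reproduce the printed class-average
  dimensions more tightly than ±0.05 without the unpublished
  thresholding of the real images.
* The equilibrium ladder is phenomenological: constants are calibrated
  to population anchors, the 36mer and sporadic intermediate assemblies
  are not species, and no kinetics are modelled.
* Exact bond realization is limited to 60 hexamers and the frustration
  scan to 12 (exhaustive enumeration); both raise explicit size-limit
  errors beyond that.
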