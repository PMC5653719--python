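# Methods

## Transport model

Photon packets propagate in full 3-D through a stack of homogeneous plane
layers; depositions are scored on a 2-D (y, z) Cartesian grid, ignoring
x.  The beam is uniform over its width in y, normally incident, and
translation-invariant in x (an infinite slot).  This resolves the tension
between a 2-D scoring geometry and 3-D azimuthal scattering sampling:
angles are sampled physically in 3-D, and the slot symmetry makes the
(y, z) marginal exact.

One step of the walk: draw a free path s = −ln(R)/(μₐ+μₛ) with
R ∈ (0, 1]; if the path crosses a layer interface it is truncated there,
unpolarized Fresnel reflection or Snell refraction is applied (total
internal reflection beyond the critical angle), and a fresh path is drawn
in the new medium (statistically exact for exponential paths).  At each
interaction the packet deposits ΔW = W·μₐ/(μₐ+μₛ) into the cell holding
the interaction point, then deflects by a Henyey-Greenstein cosine
(inverse CDF; the isotropic branch cos θ = 2R − 1 at g = 0) and a uniform
azimuth.  Launch applies the normal-incidence specular reflection
(≈ 2.1 % for n = 1.34) as a deterministic weight reduction, tallied as
escaped.

Termination is a hard threshold: a packet dies when W < W₀/100; its
residual weight is tallied separately, not deposited, so
absorbed + escaped + residual = launched holds to floating-point
round-off in every run and is asserted in the tests.  (Whether the
original study deposited or discarded the residual is not stated; the
separate tally lets either interpretation be recovered.)  An optional
survival roulette (off by default) keeps the same bookkeeping identity
exactly by tallying the survivor's weight boost as negative residual.
Photons crossing the lateral or bottom grid edges escape (absorbing
boundary); a 10⁵-event cap per photon (interactions plus boundary
events) guards pathological parameter sets.

The hot loop is compiled with numba; one seeded Mersenne stream per run
makes reruns bit-identical for a fixed seed.  Free-path draws use
R ∈ (0, 1] (as 1 − random()), angle and boundary draws use [0, 1).

## Default study models

* `wavelength_study`: 80 μm epidermis, 5 % melanin volume fraction,
  melanin-free dermis; 8 mm scoring depth, 50 mm lateral extent, 5 μm
  cells.  Used for 300–750 nm monochromatic sweeps at 30 mm beam width.
* `beamwidth_study`: 80 μm epidermis at 4.3 % melanin (skin type 2),
  5560 μm dermis; 60 mm lateral extent for beams up to 40 mm.  Broadband
  runs on this model use a 525–1100 nm filtered flashlamp band (that is
  the band quoted for the original beam-width experiments); the generic
  IPL generator default is the full 400–1200 nm band with a 400 nm
  cutoff filter.

Layer constants (thermal k, ρ, c; refractive index; anisotropy) are the
standard epidermis/dermis values tabulated in `skinmc.model`; a hair row
is carried as data but no hair geometry is modelled.

## Optical coefficient table

No numeric μₐ(λ)/μₛ(λ) table exists for the original study, so the
package ships one pinned parametric table (`skinmc/coefficients.py`):

* melanosome absorption μₐ,mel = 33 mm⁻¹ · (λ/500 nm)⁻³·³³, scaled by the
  layer's melanin volume fraction;
* bloodless baseline (both layers)
  μₐ,base = 0.022 + 8.53·exp(−(λ−154)/66.2) mm⁻¹;
* reduced scattering μₛ′ = 3.0 mm⁻¹ · (λ/500 nm)⁻¹·⁴⁵, converted through
  μₛ = μₛ′/(1 − g) with g = 0.789 (wavelength-independent).

The functional forms are the standard tissue-optics parameterisations;
the four free constants were fixed once so that the 750 nm / 1 %
criterion depth of the wavelength-study model lands in the 4–6 mm range
reported for red light in skin, and are not adjusted per experiment.
All constants sit inside published ranges (melanosome interiors
≈ 200–1000 cm⁻¹ at 500 nm; dermal μₛ′ ≈ 10–50 cm⁻¹ at 500 nm).  Two
deliberate simplifications: no water term (the flat 0.022 mm⁻¹ floor
keeps μₐ monotone over 300–750 nm and matches the melanin-only
chromophore model, at the cost of over-penetrating beyond ≈ 1150 nm) and
no blood (see limitations).

## Penetration analysis

"Intensity" for contouring is deposited energy per cell normalized to
the grid maximum — not a fraction of incident fluence.  The 1 %
criterion depth is the deepest cell at or above 1 % of that maximum.

At desk-scale budgets (10⁵–10⁶ photons versus the 10⁹ of the original
runs) single 5 μm cells near the contour hold only tens of deposition
events, so the raw cell-wise extremum is noise-dominated.  The analysis
therefore offers a lateral band average: under a wide beam the map is
translation-invariant near the axis, so averaging the central band
(default: central 25 % of the beam width) estimates the same maximum and
the same contour depth with roughly 50× less variance.  Sweeps and the
acceptance script use the band estimator; the raw cell-wise rule remains
the default of `contour_depth` for analytic maps.

The infinite-beam reference is built by lateral superposition of a
pencil-beam (one cell wide) response: on a laterally unbounded grid the
on-axis infinite-beam profile equals the y-sum of the pencil response.
Pencil runs for this purpose use a widened (160 mm) lateral grid so no
weight is lost through the sides; bottom-face escape is part of the
shared geometry and does not bias the finite/infinite ratio.  The
"on-axis" value in the fluence ratio is a ±1 mm band mean — narrow
against any ≥ 5 mm beam but wide enough to average cell noise (a 3-cell
band would carry 30–50 % noise at these budgets).

The plateau (critical) beam width is the smallest sweep width from which
every 1 % depth up to the widest beam stays within 5 % (relative) of the
widest beam's depth; `None` when only the widest point qualifies.  The
5 % default sits above Monte Carlo noise at the default budgets.

## Heat stage

The 2-D heat equation ρc ∂T/∂t = ∂y(k ∂yT) + ∂z(k ∂zT) + H is advanced
by Peaceman–Rachford ADI (implicit y solve, then implicit z solve, both
tridiagonal), unconditionally stable for the homogeneous problem.
Conductivities vary with depth only; interface values use the harmonic
mean, giving a conservative flux-form discretization — with insulated
boundaries and no source, Σρc·T is preserved to solver round-off.
Boundaries default to insulated on all faces (conservative for peak
temperatures and makes conservation testable); a fixed-temperature
bottom face is available.  The source H is the Monte Carlo
deposited-energy matrix per cell volume (1 cm slab thickness in x),
scaled by the pulse train's instantaneous power fraction: the train's
total energy is split equally across on-phases and H is zero when off.
Default Δt = 0.1 ms resolves millisecond IPL pulses; accuracy, not
stability, sets it.  The solver is exercised by property tests
(equilibrium, conservation, 2-D Gaussian heat-kernel agreement within
1 % RMS, linearity in source energy); no published numeric exists for
this stage.

## Synthetic data

The spectrum generator emulates a filtered xenon flashlamp: a smooth
visible hump near 560 nm plus a weaker near-infrared shoulder near
900 nm, hard-zeroed below the cutoff filter and normalized.  It
reproduces the qualitative band shape, not any measured lamp: no line
structure, no detector calibration.  Test fixtures with closed-form
structure (pure absorber slab for Beer–Lambert, isotropic scatterer for
symmetry, analytic exponential maps for contours) are generated from
parameters and a seed only.  Consequently, passing tests show the
transport, analysis and thermal machinery are correct under the model's
assumptions; they do not validate the optical table against measured
skin.

## Known limitations

* The dermis is bloodless and waterless by construction.  Blood raises
  dermal visible absorption several-fold; without it the 13.5 %
  (1/e²) criterion contour terminates at the epidermis–dermis boundary
  (≈ 0.08 mm) instead of reaching a few tenths of a millimetre, and
  near-infrared penetration beyond ≈ 1150 nm is overestimated without
  water.
* The epidermis–dermis transition is abrupt; no graded boundary option.
* The beam is a uniform slot: no Gaussian profiles, no finite rectangular
  spots, no axisymmetric (disc) geometry.  Slot beams diverge less
  laterally than discs, so finite/infinite fluence ratios are upper
  bounds relative to an axisymmetric reading of the same beam width.
* No polarization, fluorescence or time-resolved transport; no skin
  compression; no Arrhenius damage integral or perfusion cooling in the
  heat stage.
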