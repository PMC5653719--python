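# skinmc

Monte Carlo simulation of light transport in layered human skin, with
penetration-depth analysis and an ADI heat-diffusion stage.

`skinmc` answers a practical dosimetry question for intense-pulsed-light
(IPL) and laser skin therapy: **how deep does optical energy actually go**,
and how does that depth depend on wavelength, beam width and skin tone?
It is aimed at medical-physics and biophotonics users who need
reproducible fluence maps and penetration metrics rather than clinical
predictions.

## Model

Skin is a stack of plane layers — an 80 μm melanin-pigmented epidermis
over a melanin-free dermis — scored on a uniform 2-D Cartesian grid
(default 5 μm cells) over (y, z), with the surface at z = 0.  Photon
packets of weight *W* = 1 are launched normally onto the surface, take
exponential free paths with attenuation μₐ + μₛ, and at each interaction
deposit

ΔW = W · μₐ / (μₐ + μₛ)

into the local cell.  Scattering deflections are drawn from the
Henyey-Greenstein phase function by its inverse CDF,

cos θ = (1/2g) [1 + g² − ((1 − g²)/(1 − g + 2gR))²],  φ = 2πR,

with anisotropy g = 0.789 for all layers.  Fresnel reflection / Snell
refraction (including total internal reflection) act at the air–epidermis
surface (n = 1.34) and the epidermis–dermis interface (n = 1.37).
Packets terminate when W falls below 1/100 of the launch weight; the
residual is tallied, not deposited, so every run satisfies exact energy
bookkeeping (absorbed + escaped + residual = launched).

Penetration depth at criterion *f* is the maximum depth at which the
deposited energy is ≥ *f* of the maximum deposited energy anywhere in the
grid (a fraction of the *deposited* maximum, not of the incident
fluence).  Wavelength-dependent μₐ(λ), μₛ(λ) come from a pinned
parametric tissue-optics table (`skinmc/coefficients.py`); broadband
sources sample their wavelength per photon from a discrete emission
spectrum.  The absorbed-energy matrix can drive a 2-D transient heat
solver (ρc ∂T/∂t = ∇·(k∇T) + H) using the alternating-direction-implicit
scheme with per-layer thermal constants.

## Worked example

```python
import skinmc as sk

model = sk.build_default_skin("wavelength_study")   # 5% melanin epidermis
table = sk.CoefficientTable()                       # pinned optical table
src = sk.SourceSpec.monochromatic(750.0, beam_width_mm=30.0,
                                  photon_count=300_000, seed=1)
res = sk.run_simulation(model, table, src)
fmap = sk.normalize(res, src, "per_max_deposition")
pen = sk.contour_depth(fmap, 0.01, band_halfwidth_um=3750.0)
print(f"escaped fraction {res.escaped_weight / res.photons_launched:.3f}")
print(f"1% penetration depth {pen.depth_um:.0f} um")
```

prints

```
escaped fraction 0.543
1% penetration depth 5345 um
```

i.e. over half of the incident 750 nm light is re-emitted or
reflected, and the cell deposition falls to 1 % of the grid maximum about
5.3 mm below the surface — red light reaches the deep dermis.  The same
pipeline drives the command line:

```bash
skinmc simulate --variant wavelength_study --wavelength 750 --photons 1000000 --out runs/750nm
skinmc sweep-beam --widths 1,5,10,20,40 --photons 500000 --out runs/widths
skinmc ratio --width 10 --depths 1,2,3 --out runs/ratio
```

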