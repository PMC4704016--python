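# lamdiff

Lamellar SAXS/WAXS analysis for multilamellar lipid bilayer stacks:
Bragg-peak indexing and d-spacings, gel/fluid phase classification and
coexistence detection, binary phase-diagram assembly, electron-density-
profile (EDP) reconstruction with truncation correction, water-layer and
chain-tilt geometry — plus a forward diffraction simulator that generates
every input with known ground truth, so the whole chain is testable
without beamline data.

## Who this is for

Membrane biophysicists analysing powder-averaged small/wide-angle X-ray
scattering from lipid vesicle pellets (e.g. DPPC host bilayers doped with
a polyunsaturated guest lipid such as DHA-PE), where the questions are:
which lamellar phases are present at each composition and temperature,
what are their repeat distances, how thick are bilayer and water layer,
and how tilted are the gel-phase chains.

## The model

A stack of bilayers with repeat distance `d` diffracts at `q_h = 2πh/d`;
the repeat distance follows from the fundamental as `d = 2π/q₁`.  The two
lamellar phases have distinct signatures within a detector window
truncated at `q_max = 0.45 Å⁻¹`:

- **gel (Lβ′)** — long-range stacking order: ≥3 sharp orders, plus a
  wide-angle chain-packing reflection near `q = 1.57 Å⁻¹`;
- **fluid (Lα)** — fluctuation-limited order: exactly 2 broad orders and
  no sharp WAXS peak.

Two interleaved series with distinct `d` (>5% apart) mean gel/fluid
coexistence — laterally separated domains stack like-with-like.

Relative electron-density profiles are reconstructed by cosine synthesis
from Lorentz-corrected order amplitudes,

    |F_h| = √(I_h·h²),   ρ(z) = Σ_h α_h |F_h| cos(2πhz/d),

with phase signs `α_h ∈ {−1,+1}` defaulting to the centrosymmetric PC
convention `(−,−,+)`.  The head-to-head distance `d_pp` is the separation
of the two headgroup maxima; a 3-order synthesis underestimates it by
about 10%, repaired by a multiplicative correction keyed to the order
count (`×1.10` for 3 orders, none for ≥4).  The water layer is
`d_w = d − d_pp`.  Gel-phase chain tilt follows from a reference-
calibrated span: `L_eff = (d_ref − d_w,ref)/cos θ_ref` and
`θ = arccos(d_pp/L_eff)`.

## Worked example

```python
import lamdiff as ld

# synthesize one coexistence sample (0.1 mol% guest lipid, 25 C)
points = ld.generate_phase_grid([0.1], [25.0], seed=42)
p = points[0]

res = ld.LamellarModel(p.saxs, p.waxs).fit()
print(res.summary())
e = res.edp("gel")
print(f"d_pp = {e.d_pp:.2f} nm, d_w = {e.d_w:.2f} nm")
print(f"tilt = {res.tilt('gel').theta:.1f} deg")
```

prints

```
Lamellar diffraction analysis
============================================================
sample: dha0.1_T25   0.1 mol%   25 C
phase state: coexistence

phase       d (nm)     +/-  orders   q1 (1/A)
---------------------------------------------
gel          5.015      --       3     0.1253
fluid        7.064      --       2     0.0889

WAXS chain peak: q = 1.570 1/A (d20 = 4.002 A)
d_pp = 3.32 nm, d_w = 1.69 nm
tilt = 52.2 deg
```

The sample is recognised as two coexisting lamellar populations: a gel
stack at `d ≈ 5.0 nm` with three indexed orders and a fluid stack at
`d ≈ 7.1 nm` with two.  The gel EDP gives a corrected bilayer thickness
of 3.32 nm and a 1.69 nm water layer; against the fully hydrated
reference geometry (d = 6.4 nm, d_w = 1.83 nm, θ = 32.6°) that thickness
implies a strongly increased chain tilt.

The same workflow is scriptable from the shell:

```bash
lamdiff simulate --out sim          # labelled synthetic phase grid
lamdiff analyze --out ana sim/*_saxs.dat
lamdiff edp series.json --out edp --scan-signs
lamdiff tilt --dpp 3.33
```

## Layout

- `lamdiff.forward` — bilayer EDP models, structure factors, profile and
  2D powder-image synthesis, labelled phase-grid generation
- `lamdiff.reduction` — azimuthal integration, silver-behenate q calibration
- `lamdiff.peakfit` — baseline, peak detection, nonlinear peak fitting
- `lamdiff.lamellar` — series indexing, classification, phase diagrams
- `lamdiff.edp` — Fourier reconstruction, d_pp, truncation correction, d_w
- `lamdiff.geometry` — chain tilt and WAXS chain-packing spacings
- `lamdiff.model` — `LamellarModel`/`LamellarResults` fit interface
- `lamdiff.cli` — `lamdiff` command-line workflow

See `docs/methods.md` for model assumptions, parameter defaults and
limitations.
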