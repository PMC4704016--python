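# Methods

## Scope and model

`lamdiff` analyses powder-averaged lamellar diffraction from multilamellar
lipid vesicles.  The in-memory unit is a 1D `ScatteringProfile` (intensity
in counts versus scattering vector q in Å⁻¹); real-space bilayer lengths
are in nm and WAXS chain-packing spacings in Å.  The analysis chain is
baseline estimation → peak detection → nonlinear peak fitting → lamellar
indexing → phase classification → (optionally) electron-density
reconstruction and tilt geometry.  A forward simulator produces profiles
and 2D powder images from fully specified ground-truth models, which is
how the chain is validated.

## Forward model

**Bilayer form factor.**  The relative electron-density profile across
one bilayer is a centrosymmetric sum of Gaussians (headgroup maxima at
±z_head, chain/methyl deficit at the centre).  Its cosine transform is
analytic:

    F(q) = Σ_i s_i A_i √(2π) σ_i exp(−q²σ_i²/2) cos(q z_i)

Symmetry is enforced at construction; the ground-truth head-to-head
distance is `d_pp_true = 2 z_head`.

**Stacking structure factor.**  Orders h ≥ 1 are unit-height Gaussians at
`2πh/d` with FWHM `w₁·h^β`, scaled by `exp(−η h²)`.  β and η are a
compact surrogate for fluctuation (Caillé-type) disorder: gel defaults
(w₁ = 0.0015 Å⁻¹, β = 0, η = 0) give resolution-limited orders; fluid
defaults (w₁ = 0.005 Å⁻¹, β = 2, η = 0.55) suppress everything beyond
h = 2.  A full Caillé lineshape is deliberately out of scope — the
observable being reproduced is the order-count contrast (3+ sharp versus
2 broad), not lineshape tails.

**Intensity.**  Expected counts are

    λ(q) = background(q) + exposure · Σ_pop φ · S(q) · F(q)² / q^L

with the powder-lamellar Lorentz exponent L = 2 (configurable), a
linear-plus-constant background (default 30 − 20q counts), and Poisson
sampling with a fixed seed (identical seed ⇒ byte-identical output).
Coexisting populations add incoherently (no cross terms): phase-separated
domains stack like-with-like, so each population diffracts as its own
stack.  In WAXS mode a single Gaussian chain-packing peak (default
q = 1.57 Å⁻¹, 1.486 Å⁻¹ for the pure host) is added for gel-bearing
samples.

**Instrument defaults** emulate a synchrotron SAXS station: wavelength
1.127 Å (11 keV), sample-detector distance 1.7 m, q-window
0.02–0.45 Å⁻¹ in 600 bins, exposure scaled so a gel first order carries
~3×10⁴ peak counts.  2D powder images map pixel radius to q via
`q = (4π/λ) sin(θ/2)`, `θ = atan(r/D)`, and are Poisson-sampled on a
16-bit grid.

**Gel default shape.**  Headgroup Gaussians σ = 0.12 nm at
z_head = 0.3347·d with a deep narrow methyl trough (A = 1.4, σ = 0.126 nm).
These are *effective* widths, sharper than a real phosphate distribution:
they are chosen once so the forward model reproduces two structural facts
of tilted-gel diffraction — a measurable but weak third order
(I₃/I₁ ≈ 0.4%) and a ≈10% underestimate of d_pp by a 3-order Fourier
synthesis (the systematic error the correction factor repairs).  Scaling
z_head with d keeps relative order intensities (and hence the 3-order gel
/ 2-order fluid signatures) stable across the realistic d range
(gel 4.5–5.5 nm, fluid 6.5–7.5 nm).  Fluid defaults use broad heads
(σ = 0.40 nm) at z_head = 0.2829·d and a shallow wide trough.

**Phase-grid rules** are data, not code.  Defaults encode the studied
binary system: a gel-only pocket below 0.2 mol% and 23 °C; a coexistence
band spanning ~7 °C up to the fluid onset at 30 °C for every mixture
containing the guest lipid; pure-host melting at 42 °C with the
pretransition (ripple) region above 34 °C *flagged* on the gel label
rather than given an invented scattering signature.  Repeat distances:
mixture gel 4.99 nm at 20 °C with +0.005 nm/°C; pure-host gel fixed at
6.40 nm; fluid 7.00 nm at 25 °C falling to 6.65 nm at 40 °C.  Coexistence
splits volume 50/50 between populations — the true lever rule is unknown
and nothing downstream depends on the split.

## Reduction

Azimuthal integration assigns pixels to uniform half-open q bins spanning
the pixel q range (final bin closed, so counts are conserved exactly).
The bin statistic is the **mean** count, making profiles comparable
across geometries; empty bins are NaN, never zero-filled; per-bin
uncertainty is √(Σcounts)/n_pixels.  q calibration against silver
behenate (default d₀₀₁ = 58.83 Å — note the more common reference value
is 58.38 Å; the default is overridable, not silently corrected) fits a
single multiplicative scale through the origin; beam-centre refinement,
polarization and flat-field corrections are out of scope.

## Peak fitting

The baseline is an asymmetric-least-squares (Whittaker) smoother,
smoothness 10⁷ and asymmetry 10⁻⁴, i.e. an envelope hugging the lower
edge of the noise band.  Detection takes local maxima of the
median-recentred residual with both height and prominence ≥ k·σ (default
k = 5), σ estimated by the median absolute deviation so it works on
arbitrary text profiles, not only Poisson counts.  The height criterion
matters: prominence alone reaches several σ on wide noise excursions.

Fits are windowed nonlinear least squares (lmfit), Gaussian for SAXS
orders and pseudo-Voigt for WAXS chain peaks; windows overlapping by
>25% are merged and fitted jointly.  Each window includes a free constant
that absorbs the envelope-baseline offset — without it, weak-peak areas
are biased high by ~10%.  Windows are fitted *unweighted*: with
resolution-limited peaks only 2–3 bins wide, inverse-variance weights let
the background-level flanks dominate and bias areas low by up to 20%;
ordinary least squares is unbiased at these signal levels (verified
against noiseless profiles to <0.5%).  Failed fits are dropped and
logged.

## Indexing and classification

Candidate fundamentals are q₀/h for each fitted peak (h ≤ 3); a candidate
matches peaks at integer multiples within a relative tolerance of 1.5%.
A series must be a **consecutive run of orders starting at the
fundamental** — a d-spacing inferred from gapped high orders is
ambiguous, and the restriction is what makes the greedy accept-best-
remove-repeat strategy provably match exhaustive best-partition search on
resolvable peak sets (verified on 200 random cases against a full
set-partition oracle).  The fundamental is refined by weighted least
squares of q_h on h.  Leftover single peaks become one-order series with
phase `unknown`.

Classification: gel iff ≥3 orders, or 2 sharp orders plus a WAXS peak in
1.45–1.65 Å⁻¹; fluid iff exactly 2 broad orders; otherwise unknown
(including single-order series — one peak is not enough evidence).
"Sharp" means first-order FWHM below 3 instrumental bin widths
(configurable).  The decision uses only peak counts, widths and the WAXS
window, so it is invariant to overall intensity scaling.  Coexistence
requires two multi-order series with repeat distances >5% apart, guarding
against one series split by fit jitter.  Per-composition melting
temperature T_m is the midpoint between the warmest non-fluid and coolest
fluid-only sample when both exist (the boundary sample otherwise); the
expected gel → coexistence → fluid ordering with temperature is checked
and violations are flagged, not hidden.

## Electron-density reconstruction

Amplitudes `|F_h| = √(I_h h²)` (Lorentz exponent 2 for powder lamellae,
configurable; the intensity entering is the fitted area).  Orders must be
consecutive from h = 1; a genuinely zero area is accepted, a missing
order is rejected.  The synthesis is evaluated on the non-negative
half-grid and mirrored, so ρ(z) = ρ(−z) holds bit-for-bit.  Default
signs follow the centrosymmetric PC-gel convention ((−,−,+), (−,−,+,−),
(−,−,+,−,+)); with the default gel forward model the true signs of
F(2πh/d) at three orders are exactly (−,−,+).  A sign-scan utility
reconstructs all 2ⁿ choices and ranks them by a documented plausibility
heuristic (headgroup maxima away from both 0 and d/2, methyl trough at
the centre, near-water density at the gap midpoint) so the choice can be
audited rather than trusted.

d_pp is the separation of the two density maxima on either side of the
centre, refined by local quadratic interpolation; a maximum on the grid
boundary raises a flag (likely wrong signs).  The truncation correction
is a fixed multiplicative factor keyed to the order count
({3: 1.10, otherwise 1.00}); two-order fluid reconstructions receive no
correction.  The 10% three-order factor is consistent with the forward
model: across the realistic gel-model family the 3-order synthesis
underestimates 2·z_head by 6–12% (mean ≈ 9%), so the corrected estimate
recovers the truth to ~1% on average (the recovery test asserts <5%).
d_w = d − d_pp, with 0 < d_pp < d enforced.

## Tilt geometry

The only tilt model implemented is reference-calibrated:
`L_eff = (d_ref − d_w,ref)/cos θ_ref` from a fully hydrated DPPC gel
reference (6.40 nm, 1.83 nm, 32.6°), then `θ = arccos(d_pp/L_eff)`.
θ decreases strictly as d_pp grows; d_pp > L_eff is rejected (no real
angle).  For d_pp = 3.33 nm this construction gives ≈52.1°; reference
parameters are exposed rather than hard-coding any particular published
angle, since the verbal geometric argument does not fix a unique formula.
WAXS chain spacing is the plain identity d = 2π/q (so 1.537 Å⁻¹ ↦
4.088 Å — the mathematically consistent value).

## What the synthetic data does and does not show

The generator reproduces: order-count and width contrast between phases,
incoherent two-phase coexistence, instrument q-truncation, Poisson
counting statistics, isotropic powder rings, and a ground-truth EDP whose
truncated synthesis shows the documented systematic error.  It does not
model: Caillé tails and diffuse scattering, ripple-phase (Pβ′) patterns
(flagged only), mosaic/oriented samples, detector artefacts (flat-field,
polarization, saturation beyond 16-bit clipping), absolute intensities,
or composition-dependent lineshape changes.  Passing tests therefore
demonstrate correctness of the analysis chain under idealised but
physically structured conditions; they do not validate performance on
degraded real-beamline data.

## Problem sizes and numerical choices

Tests and the acceptance script use the default 600-bin profiles, a
6-composition × 10-temperature grid (60 points) for phase-diagram
recovery, 50 seeded gel datasets for EDP parameter recovery, 200 random
cases for the indexing oracle, and 64×64–128×128 pixel images for
reduction checks — sizes at which every statistical property is already
stable.  All randomness flows through explicit integer seeds
(per-grid-point streams are derived by hashing, keeping them independent
of grid ordering).  Reconstruction grids have odd point counts (z = 0
included); quadratic peak refinement falls back to the grid point at
boundaries; the baseline iteration caps at 50 with convergence reported,
not raised.

## Known limitations

- The greedy indexer is provably optimal only for resolvable peak sets
  (no two reflections within the fit resolution) and consecutive-order
  series; pathological overlapping-series cases can differ from the
  global optimum.
- The truncation factor is calibrated for gel-like density profiles; for
  qualitatively different profiles (e.g. interdigitated phases) the
  3-order bias need not be 10%.
- Fluid-phase EDPs inherit bias from fluctuation damping (the fitted
  areas fold in exp(−ηh²)), so fluid d_pp is qualitative; only gel-phase
  recovery is quantitatively validated.
- q calibration fits scale only; beam-centre error is not modelled.
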