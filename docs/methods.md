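# Methods

This note records the models, parameter choices, numerical decisions and
known limitations of the package, module by module.

## Decay data (`tatdose.decay`)

Per-decay emission inventories for F-18, the At-211 chain (At-211,
Po-211, Bi-207), I-131 (with Xe-131m) and Lu-177 are compiled from
published ICRP-107-style decay tables into `data/nuclides.json` (schema
documented in the file).  Continuous β± spectra are stored as mean energy
plus endpoint; dose bookkeeping uses the mean, microdosimetric sampling
uses an allowed-shape spectrum reconstructed from the endpoint.

Chain flattening assumes transient equilibrium: daughters with half-life
below the truncation (default 24 h) decay "instantly" and their emissions
are folded in, scaled by branching.  Longer-lived daughters are dropped
and reported: Bi-207 (31.6 y) after the At-211 α branch and Xe-131m
(11.8 d, 1.2% branch) after I-131 contribute negligible dose on
treatment time scales.  For At-211 this yields ≈1.0 α per decay with mean
α energy ≈ 6.8 MeV (41.8% At-211 α at 5.87 MeV, 58.2% Po-211 α at
7.45 MeV), the quantity that drives all α-dose results.

Tally convention: α particles form the "α dose"; electrons, positrons and
photons (via their secondary electrons — no kerma approximation at the
bookkeeping level) form the "β dose".

Units are fixed package-wide: MeV, hours, Bq, Gy, keV/µm, g/cm³; the only
energy conversion constant is 1 MeV = 1.602176634e−13 J
(`tatdose.constants`).

## Lineal-energy spectra (`tatdose.microspec`)

d(y) in a spherical water domain (r_d = 0.282 µm, y₀ = 93.4 keV/µm —
HSG-cell MKM values, fixed) is estimated by a chord-length × LET model:

1. choose an emission line with probability ∝ yield × energy (dose
   weighting); photons are first converted to a Compton electron sampled
   from the exact Klein–Nishina distribution; β± lines sample an
   allowed-shape spectrum from the endpoint;
2. choose a point on the slowing-down track uniformly in energy lost
   (i.e. ∝ local energy deposition) — residual energy E′ ~ U(0, E₀);
3. look up the local electronic stopping power L(E′) in liquid water
   (embedded ICRU-49/ICRU-37-style table, log-log interpolated; clamped
   at the table ends during sampling);
4. draw a µ-randomness chord l (pdf l/2r_d² on [0, 2r_d]) and deposit
   ε = min(L·l, E′), scored with weight ε into a log-spaced y histogram
   (default 200 bins over [0.1, 1000] keV/µm).

Lineal energy uses the ICRU mean chord, y = ε/(4r_d/3).  The saturation
integral y* and z*₁D = 0.1602·y*/(π r_d²) Gy are bin-midpoint
quadratures.  Spectrum mixing (per-voxel or per-nuclide) is the exact
dose-weighted linear combination, so z*₁D mixes linearly — the
implementation exploits this identity and the tests verify it.

What the model omits: δ-ray escape and energy-deposition straggling
(track-structure effects), which broaden d(y) in reality.  The model's
low-dose EQD2/dose limits come out at ≈5.6 for the At-211 chain and
≈0.78 for F-18 (n = 2×10⁵), a few percent above track-structure-based
values — the direction expected when δ-ray escape from a sub-µm site is
neglected.  The reference radiation for α₀ is monoenergetic 300 keV
electrons (z*₁D,ref ≈ 0.97 Gy, α₀ ≈ 0.19 Gy⁻¹ at the default
parameters); choosing 100 keV–1 MeV electrons instead moves z*₁D,ref by
a few tenths of a Gy and the F-18 ratio by a few percent — small against
the F-18 band because the F-18 secondary-electron spectrum largely
overlaps the reference spectrum, and negligible for At-211 where
β·z*₁D ≈ 1.9 dominates α₀.

## MKM conversion (`tatdose.mkm`)

Defaults α = 0.251 Gy⁻¹, β = 0.0615 Gy⁻², µ = 1.5 h⁻¹, X = 2 Gy
(EQD2, α/β = 4.08); all parameters and the domain geometry are loadable
from a JSON parameter file.  Per-voxel G uses that voxel's own fitted
λ_eff = λ_phy + λ_bio; neighborhood smoothing of decay constants is not
applied (self-dose dominates for α emitters).

Numerical choices: survival underflow is clamped at the smallest positive
normal double with a warning counter; VOI survival excludes voxels below
a dose floor (default 1e−9 Gy) when doses are supplied, since such voxels
were never irradiated by the field being evaluated; the "EQDX of the mean
dose" (heterogeneity-ignored) route uses dose-weighted mean z*₁D and G so
that only the spatial dose heterogeneity is removed.  The inversion
identity eqdx(S) is exact for the reference treatment's survival
ln S = −(α+βX)·D; a single acute fraction of size X maps to EQDX = X to
1e−9 (tested).

## Kinetics (`tatdose.kinetics`)

Mono-exponential fits A(t) = A₀·e^(−λ_eff·t) on decay-uncorrected frame
averages at frame midpoints (a `decay_corrected` flag restores physical
decay first, since vendors differ).  Initialization is an
activity-weighted log-linear regression on positive frames, refined by
damped Gauss–Newton with backtracking; the same vectorized code path
serves single curves and whole volumes, so scalar and voxelwise results
agree exactly.  λ_eff is constrained to ≥ 0.1·λ_phy: λ_bio may be
negative (tracer accumulation, flagged) but never cancels physical decay.
Voxels whose peak activity is below 1e−4 of the volume maximum skip the
fit and integrate by trapezoid plus an analytic physical-decay tail
(flagged per voxel).  Ã = A₀/λ_eff by construction (the tail beyond the
last frame is the fitted exponential).  On noiseless data the fit
recovers parameters to 1e−6 relative; under Poisson noise at ~10⁴
counts/frame the λ_eff estimator is unbiased within ~2% with ~5% spread
(100-replicate test).

## CT phantom (`tatdose.phantom`)

Schneider-style piecewise-linear HU → density with anchors at air
(−1000 HU, 1.21e−3), inflated lung (−740, 0.26), adipose (−98, 0.93),
water (0, 1.00), soft tissue/muscle (100, 1.075) and skeletal bone
(2000, 1.92); clamped to [−1024, 3000] HU with a warning counter.  The
material table is reduced to four classes (air, lung, soft tissue, bone;
edges −950/−200/120 HU) because the photon engine only needs density and
coarse attenuation properties; a finer bin table can be loaded from JSON.
Voxel mass = density × voxel volume exactly; all mass bookkeeping
(Eq-style VOI weighting, DMH) flows from this map.

## Dose engine (`tatdose.dose`)

Charged particles deposit locally (α ranges ~60–70 µm and β ranges
≲ 2 mm versus mm-scale voxels; an optional Gaussian β blur is
deliberately not applied by default).  Photons use an analytic
point kernel in radiological distance x = µρr:

    K(r) = µ_en ρ · e^(−x) · B(x) / (4πr²),   B(x) = 1 + a·x·e^(b·x)

with embedded water/air/lung/bone µ/ρ and µ_en/ρ tables at the relevant
line energies (log-log interpolated).  The Berger amplitude
a = (µ/µ_en − 1)(1 − b)² is fixed analytically by two constraints: the
r → 0 limit equals the first-collision kerma, and the infinite-medium
integral equals exactly 1 (energy conservation).  The remaining shape
parameter b(E) was calibrated against the package's own Monte Carlo
oracle on a 32³ × 4 mm water phantom (b ≈ 0.25–0.35 below 0.5 MeV,
falling to ~0 at 1.1 MeV); with it, kernel voxel doses agree with the MC
within 15% wherever the MC statistical error is below 3%, and the median
agreement is within ~5%.  Because b absorbs some finite-volume scatter
escape, the kernel is tuned for human-torso-scale grids.

Discretization: the kernel is tabulated on an odd (2N−1)³ voxel grid
(shift-free FFT convolution); voxels within 4 voxel-widths of the source
average the kernel over 4³ sub-voxel samples (the 1/r² profile is too
steep for center-point evaluation); the source voxel receives the
analytic cumulative deposit over the mean escape path (3R_eq/4) of a
uniform source in the volume-equivalent sphere.  Heterogeneity is handled
by a single mass-weighted mean density in the kernel with per-voxel mass
division at deposit time — low-density voxels correctly receive more dose
per unit deposited energy, but the kernel shape itself is not locally
density-corrected.  Bremsstrahlung, annihilation-in-flight and X-ray
cascades beyond the embedded lines are neglected (listed in provenance).

The MC oracle is an analog photon Monte Carlo: Woodcock (delta) tracking
through the voxel grid, Compton scattering with exact Klein–Nishina
energy/angle sampling (incoherent cross-section from the KN formula and
Z/A per material), the remainder of the total attenuation treated as
photoelectric absorption, photons below 10 keV absorbed on the spot, and
batch statistics (default 10 batches) for per-voxel uncertainties.  It is
a test oracle for the kernel engine, not a production dose engine.

## Synthetic data (`tatdose.synthetic`)

The default phantom is a 64×64×48 grid of 4 mm voxels: a soft-tissue
body, two air-filled lungs (−700 HU), two kidneys (~64 mL each), a
bladder and a 17 mL tumor, painted as ellipsoids in listed order.
Activity concentrations at injection (50 Bq/mL body, 200 lungs, 4000
kidneys, 6000 bladder, 2500 tumor per MBq-scale injection) and clearance
constants (0.02–0.15 h⁻¹) emulate a kidney-dominated amino-acid-type
tracer; frames follow a nine-frame, 90-minute schedule.  Counting noise
is Poisson with a scanner sensitivity of 0.02 detected counts per decay
(~600 counts per kidney voxel in an early frame), and a 4 mm FWHM
Gaussian PSF emulates reconstruction resolution.

What it does not emulate: sinogram-level reconstruction artifacts,
scatter/randoms, partial-volume bias beyond the PSF, respiratory motion,
or intra-organ kinetic heterogeneity.  Passing the recovery tests
therefore demonstrates correctness of the fitting and dose chain under
the stated noise model, not robustness to all clinical PET effects.

## Pipeline (`tatdose.pipeline`, CLI)

Stages: phantom build → voxelwise kinetic fit → dose maps → EQDX map →
per-VOI table (mass, mean component doses, EQDX via mass-weighted
survival and via mean dose, DMH CSV per VOI).  Every run writes a
provenance record (config hash, seeds, package version, engine settings,
warning counters); identical configs give bit-identical outputs.  An
`activity_sweep` utility rescales dose maps (dose is exactly linear in
injected activity) and tabulates the EQDX/dose ratio together with the
heterogeneity-ignored and µ = 0 variants, reproducing the expected
qualitative behaviour: for an α emitter the ratio falls with activity,
and both simplifications bound the full EQDX from above at high activity.

## Problem sizes

Default spectra use 2×10⁵ samples per component (sampling noise on the
low-dose ratios ≈ 0.3%).  The kernel-vs-MC validation uses a 32³ water
phantom with 8×10⁶ histories in 16 batches; pipeline tests use a
32×32×24 phantom; the full default phantom runs the entire chain in a
few seconds.

## Known limitations

* No track-structure physics in d(y); the α spectra are segment-LET
  approximations (few-percent high bias on low-dose RBE ratios).
* Photon transport is a buildup-kernel approximation validated on
  torso-scale water grids; strongly heterogeneous geometries (lung/bone
  interfaces) only get bulk density scaling.
* Single-exponential kinetics only; no compartment models, no PET
  reconstruction modelling.
* No DICOM I/O; volumes are NIfTI with JSON sidecars, tables CSV.
* Radiobiological parameters are cell-line (HSG) surrogates; organ-level
  EQDX values inherit that uncertainty and microscopic (sub-voxel)
  radionuclide heterogeneity is out of scope.
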