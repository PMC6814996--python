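# Methods

This note records the models, parameters, numerical choices and known
limitations of `lungbragg`, in the spirit of a model-documentation page.

## Geometry and coordinates

All volumes are regular rectilinear voxel grids in millimetres; world
coordinates attach to voxel centers, indices are 0-based.  Beams lie in
the axial plane: gantry 0° enters from anterior and travels +y, 270° from
the patient's right travelling +x, direction `(-sin θ, cos θ, 0)`.  Any
consistent convention would do; this one is fixed and used everywhere
(spot placement, dose, isodose rays, margin construction).

## Phantoms

**Slab** (`build_slab_phantom`): tissue (10 mm) | lung (80 mm, relative
density 0.26) | tissue, with a box CTV spanning 34–47 mm downstream of the
lung exit (13 mm deep, 24 mm wide by default) inside a 60 mm lateral
cross-section at 1 mm spacing.  This is the canonical worst-case geometry
for degradation and PTV-concept studies.  `lung_mm = 0` degenerates to a
homogeneous water phantom.

**Patient-like** (`build_patient_like_phantom`): an elliptic-cylinder
tissue body (half-axes 130 × 95 mm) containing a single ellipsoidal lung
compartment (72 × 62 × 40 mm) in which a spherical, water-equivalent CTV
is carved out of the lung.  The sphere is placed on the beam ray so that
the *measured* geometric path through lung voxels to the CTV centroid
equals the requested depth; placement is refined against the voxelized
lung mask (up to 4 Newton steps, tolerance 0.3 voxel) and verified by an
exact Siddon ray trace.  A seed jitters the aim point laterally (±5 mm)
for reproducible variety.  Optional spinal-cord/trachea-like OARs
(cylinders or spheres) are placed distal to the CTV along the beam.

Only the covariates that drive the degradation effect — tumor volume,
depth in lung, presence of a distal OAR — are emulated.  Real anatomies
(two lungs, mediastinum, chest-wall curvature, heterogeneous lung density)
are not.  The lung chord bounds achievable depths at roughly 100 mm, so
the very deepest clinical configurations (≈12 cm of lung) are outside this
generator's range; the builder reports the maximum achievable depth when
asked for more.

Mean lung density defaults to 0.26 (ICRU-lung-like) and is configurable;
tumors are water-equivalent (density 1.0).

## Pristine beam model

* **Range–energy**: `R(E) = alpha E^p` with `alpha = 0.0022 cm/MeV^p`,
  `p = 1.77` — standard water values, shared between the engine and the
  test oracle.  The default machine window is 60–230 MeV: slightly wider
  than the 70–221 MeV span of the lateral-spot calibration so that shallow
  proximal layers behind a realistic chest wall remain plannable.
* **Depth dose**: the analytic power-law curve
  `D(z) ∝ (R−z)^{1/p−1} + (β + γpβ)(R−z)^{1/p}` (stopping term plus linear
  fluence loss, `β = 0.012 cm⁻¹`, `γ = 0.6`), bin-averaged analytically
  near its integrable singularity, then convolved with a Gaussian range
  spread combining straggling (`0.012 R^0.935` cm) and a 1% relative beam
  energy spread in quadrature.  The energy-spread term is physically
  standard for synchrotron beamlines and is what gives low-energy peaks a
  realistic width; without it, 3 mm energy-layer spacing would produce an
  unphysically rippled spread-out Bragg peak.  The sampled curve is
  shifted so its maximum sits exactly at `R(E)` and normalized to a
  physical peak of 1 per unit weight with a constant RBE of 1.1 folded in;
  absolute dose scale is set by the optimizer, so this normalization is a
  pure convention.
* **Lateral profile**: one Gaussian per spot with depth-independent sigma
  from log-linear interpolation of the two in-air FWHM calibration points
  (70 MeV → 32.5 mm, 221 MeV → 8.1 mm), clamped with a warning outside
  that span.  In-patient scatter growth with depth is deliberately
  omitted — the analysis concerns depth-dose degradation, not penumbra.
* **WEPL**: exact Siddon-style voxel traversal (`wepl_trace`) for
  reference and calibration; the dose engine uses a beam-aligned
  resampled cumulative integral (trilinear, lattice step = voxel size)
  for per-voxel water-equivalent depth and lung path.

## Degradation model

`sigma^2 = P_mod × L_geom`, with `L_geom` the geometric (not
water-equivalent) path through lung voxels, matching how tumor depth in
lung is defined.  The default sweep is 100, 250, 450, 800 μm, spanning
published porcine-lung measurements (300–750 μm, average 450) and
dehydrated human-sample values (50–250 μm) with buffer on both ends; a
single scalar `P_mod` per run (spatial maps are out of scope).

*Convolution mode* degrades the depth-dose with a discrete normalized
Gaussian kernel (support 4σ, replicate-padded proximally, zero-padded
distally; depth-integral conserved to <0.1%).  Per-voxel sigmas are looked
up in a precomputed σ-family of degraded curves (σ step 0.25 mm, bilinear
interpolation over σ × depth).

*Density-sampling mode* redraws each lung voxel independently from the
two-component law {0, ρ_hi} with `ρ_hi = ρ0 + P_mod/(d ρ0)` and
`P(ρ_hi) = ρ0/ρ_hi`, giving mean ρ0 and variance `P_mod/d` per voxel and
hence range variance `P_mod × L` over a path `L`.  A density ceiling
(default 4.0) rejects configurations whose high component would be
unphysically dense; the error advises smaller `P_mod` or larger voxels.

**Known bias between the modes.**  Among all nonnegative per-voxel
distributions with the required mean and variance, the two-point law with
an atom at zero has the *smallest* possible third moment — yet that
minimum, `κ₃ = L P (P/ρ0 − ρ0 d)`, is still positive at lung densities,
so the sampled range kernel is right-skewed while the convolution kernel
is Gaussian by definition.  The resulting discrepancy between the two
formulations on the 80 mm slab is ≈0.2% of peak at 100 μm, ≈1.6% at
450 μm and ≈2.5% at 800 μm (20 000 realizations), and is invariant under
voxel-size refinement.  It is a structural property of modelling a
nonnegative medium with an independent per-voxel law, not a sampling
artifact; the cross-validation test records it.

## Planning

PTV concepts: (a) isotropic 3 mm Euclidean dilation of the CTV;
(b) asymmetric beam-frame dilation, 5 mm proximal / 7 mm distal / 3 mm
lateral; (c) the isotropic mask plus a boosted prescription map — 3%
extra in the proximal margin, 6% in the distal margin, classified per
margin voxel by the beam-frame direction to its nearest CTV voxel (45°
cones; purely lateral margin voxels keep the base prescription).

Energy layers sit at 3 mm water-equivalent spacing covering the PTV WEPL
extent (interpreted as WEPL rather than geometric depth, since layers are
naturally range-spaced); each layer's lateral grid is spaced
0.45 × FWHM(E) and covers the PTV beam-eye projection expanded by one
sigma.  Weights are found by non-negative least squares (scipy NNLS)
against the per-voxel prescription over the PTV, with penalty rows added
iteratively (up to 6 outer passes, relative-objective tolerance 1e-6) for
voxels above 115% of prescription, and a small Tikhonov term (1e-4 of the
mean squared column norm) that suppresses degenerate edge-spot solutions.
The optimizer reports the achieved V95 and a `converged` flag — it never
fails silently.  Influence matrices are computed once on the nominal
phantom; modulated scenarios reuse the optimized weights unchanged, which
is precisely the effect under study.

## Analysis

* `D_x%` uses the lower-adjacent sorted-voxel rule
  (ascending index `floor((1 − x/100) n)`), a conservative choice in the
  absence of a stated interpolation convention.
* The gamma index is *local* (criterion = % of the reference voxel's own
  dose), 3%/1 mm by default, including voxels at ≥20% (or ≥80%) of the
  maximum reference dose.  The evaluated dose is trilinearly interpolated
  on a sub-voxel lattice of step DTA/10 within a search ball of radius
  3 × DTA; the production search is exhaustive with early exit and matches
  a brute-force oracle bit-for-bit on small grids.  Reports use a
  pass-rate-exact mode that stops refining a voxel once its pass/fail
  status is certain (the gamma map then upper-bounds failing voxels).
* Isodose shifts are distal-crossing differences (evaluated − nominal,
  negative = shorter range) with linear interpolation along rays at
  0.25 mm steps; the "maximum shift" is the max-|shift| over a 7×7 fan of
  beam-parallel rays through the PTV projection, reported with its sign.
  A level the modulated dose never reaches anywhere is flagged as
  *vanished* rather than given a number.

## Experiment runner and reproducibility

`run_single_field` chains phantom → plan → two-scenario dose → report and
writes CSVs (metrics, gamma, shifts, DVH curves, central-axis profiles)
whose headers embed the configuration hash and seed; `run_matrix` loops
angles, adds the summed-field comparison and a trend summary, and records
per-cell failures without aborting the rest.  Identical configuration and
seeds reproduce byte-identical outputs.  Default problem sizes — 1 mm
slabs of ≈0.6 M voxels and 2 mm patient-like grids of ≈0.7 M voxels, with
convolution-mode recalculation — were chosen so a full matrix runs in
minutes on a single CPU; density-sampling 3-D doses default to 20
realizations and are the expensive path.

## Limitations

No Monte Carlo transport (nuclear halo, large-angle scatter and
multiple-Coulomb-scattering depth dependence are absent), no variable RBE,
no motion or interplay, no DICOM import, no multi-field simultaneous
optimization, no OAR constraints in the objective, and a single scalar
modulation power per run.  Passing tests demonstrate the internal
consistency of this model chain and the qualitative physics of Bragg-peak
degradation; they do not certify agreement with measured patient doses.
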