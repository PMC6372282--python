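# Methods

This note records the models implemented in `sonoprint`, the defaults and
their units, what the synthetic data do and do not emulate, and the design
choices made where the design was genuinely open. It states no result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Acoustic medium model

Soft tissue is treated as acoustically homogeneous water
(ρ = 1000 kg/m³, c = 1500 m/s). Inside the skull, density and sound speed
are affine in the CT Hounsfield value, anchored at HU 0 → water and at a
reference value `hu_ref` (default 2000, configurable — CT calibrations
differ and no universal endpoint exists) → compact bone
(ρ_max = 2200 kg/m³, c_max = 3100 m/s). Attenuation follows the porosity
power law α_att = α₀ f^b φ^β with φ = (ρ_max − ρ)/(ρ_max − ρ_water),
α₀ = 8 dB/cm/MHz^b, b = 1.1, β = 0.5; dB→Np conversion uses
20/ln 10 = 8.6859. The porosity law describes mineralized bone, so it is
applied only to skull-labelled voxels with HU > 0; a skull-labelled voxel
at HU ≤ 0 contains no bone and is treated as water. Attenuation (pressure
decay, includes scattering) and absorption (heating) are kept distinct:
tissue absorption is 0.21 dB/cm/MHz^b and skull absorption scales linearly
with density up to a ceiling of α₀/3 ≈ 2.67 dB/cm/MHz^b.

## Focused field

The transducer is a spherical section with 63 mm radius of curvature and
64 mm aperture. The steady-state monochromatic field is computed by a
discretized Rayleigh surface integral over the cap (midpoint rule on a
polar θ×φ grid, default 60×120 points), which in water agrees with the
classical closed-form on-axis solution for a uniform focused bowl to
better than 0.1% and with an independent Gauss–Legendre quadrature of the
same integral to within 2% (both are test assertions). A full-wave
time-domain solver is deliberately **not** used: the reported quantities
(steady-state peak pressure, pulse intensities) are properties of the
linear steady state, and absolute amplitude is anchored by rescaling to
the free-water calibration (1.2 MPa at 130 V, linear in drive voltage),
exactly as a measured transducer calibration would anchor a simulation.
Heterogeneous media attenuate each voxel by exp(−∫α dl) along the
straight apex-to-voxel ray; refraction and reverberation in bone are not
modelled, which biases transcranial focal pressure high and displaces the
focus less than a wave solver would. This is acceptable here because the
package's thermal claims are bounds, not point predictions.

"Spatial apodization r = 0.35" is not defined by any standard; it is
implemented as a radial Gaussian amplitude taper whose rim amplitude is
0.35 of the centre. At 250 kHz the focusing gain is low (~10), so the
axial intensity peak sits ~6.6 mm proximal of the geometric focus — a real
property of low-gain bowls, asserted in the tests.

## Bioheat model

Pennes' equation ρC ∂T/∂t = κ∇²T + q − wρ_bC_b(T − T_a) is solved by an
explicit forward-Euler / 7-point-Laplacian scheme. The perfusion term is
implemented as a cooling term with the standard sign (some prints of the
equation carry a "+" that would make blood flow heat tissue without
bound). The heat source is q = α_abs P²/(2ρc) with c the sound speed —
the only dimensionally consistent reading — i.e. q equals absorption times
acoustic intensity. Defaults: κ = 0.528 / 0.4 W/m/K and
C = 3600 / 1300 J/kg/K for tissue / skull; w = 0.008 s⁻¹,
ρ_b = 1030 kg/m³, C_b = 3620 J/kg/K, T_a = 37 °C; initial temperatures
37 °C in tissue and skull, 24 °C in the water cone; timeline 60 s pre,
40 s on, 300 s post; Dirichlet boundaries pinned at their initial values.
Perfusion acts only in brain-tissue voxels (it is a brain-homogeneous
parameter set; skull and water are not perfused).

Numerics: the time step obeys the von Neumann bound
dt ≤ 0.9 · Δx²/(6 max κ/ρC) and an unstable request is refused with the
computed bound. The scheme is validated against the perfusion-only
exponential closed form (τ = ρC/(wρ_bC_b) ≈ 120.7 s, within 1%), the 1D
heat kernel (2% L∞), a discrete maximum principle, and first-order time
convergence. Pulsing is folded into a duty-cycle-averaged source by
default; thermal time constants (≳100 s) exceed the 100 ms burst period by
three orders of magnitude, and an explicitly pulsed mode (validated to
agree within 5% at resolvable step sizes) exists behind a flag.

The acceptance run uses a 64³ grid at 0.5 mm with the package's own
free-water Rayleigh field rescaled to a 0.88 MPa focal peak (evaluated on
an axisymmetric (ρ,z) section and revolved onto the grid); the problem
size is a package choice that keeps the focal region and its diffusion
neighbourhood well inside the Dirichlet boundary.

## Synthetic data

The head phantom is an ellipsoidal skull shell (elevated HU, configurable
thickness) around brain tissue (HU ≈ 40 with mild texture), with a
cylindrical water coupling cone on top and air background. It reproduces
the geometric and material contrasts the dosimetry needs; it is not a
macaque anatomy.

The BOLD generator emulates a 3-subject × 3-run × 2-condition design with
800 volumes at TR 2 s on a small grid (default 14×14×10 voxels of 2 mm).
Eight bilateral ROIs in two networks carry latent Gaussian signals whose
*sample* correlation equals the prescribed coupling matrix exactly (the
white-noise sample is empirically whitened before Cholesky mixing), plus
unit-variance voxel noise. The default coupling is block-structured: 0.6
within network, 0.15 between. The stimulation condition modifies the
population matrix before mixing: within-network entries of the seed's
network ×1.3 (capped at 0.95), the seed's out-of-network entries ×0.6,
followed by projection to the nearest unit-diagonal PSD matrix. These
effect sizes are package defaults chosen so that a three-subject design
has usable power; they are not empirical claims about stimulation
magnitude. An optional global confound is a slow (~30 s) shared component
loaded 1.0 on meningeal voxels, 0.35 on grey matter and 0.05 on deep
white matter — a vascular-like source strongest near the pial surface and
sinuses. Motion parameters are smoothed low-amplitude random walks.

What passing tests show, and do not show: recovery, power and confound
rejection are demonstrated against this generative model, which has no
haemodynamic response, no spatial autocorrelation beyond the smoothing
step, no scanner drift beyond what the filters target, and far fewer
voxels than real data. Results quantify the correctness of the machinery,
not expected effect sizes in vivo.

## Preprocessing

Order: drop first 5 volumes → high-pass → dynamic band-stop → confound
regression → low-pass → 3 mm FWHM Gaussian smoothing → demean.

Temporal filters are zero-phase spectral projections on the DCT-II basis
(bin k ↔ frequency k/(2N·TR)). The choice is forced by the cutoffs: a
2000 s high-pass on a ~1590 s run cannot be represented by any causal IIR
design, and projection filters are exactly idempotent with unit passband
gain, which preserves the correlation structure the connectivity stage
depends on. Band-stop bands are detected from the amplitude spectra of
the first three principal components: bins exceeding 5× a 21-bin rolling
median *and* 3× the global median (the second guard suppresses
spectrum-edge misfires) are merged into bands and widened by 2 bins.

Compartment confounds are the mean plus first five SVD component
timecourses of the (demeaned) within-mask voxel×time matrix, with a
deterministic sign convention (largest-magnitude sample positive). The
motion expansion is the memoryless second-degree Volterra polynomial: 6
linear + 21 quadratic = 27 demeaned regressors (a lag-1 variant is
available). Regression is per-voxel OLS with an intercept;
rank-deficient columns are dropped with a warning. The diagnostic variant
extracts compartment confounds from white matter alone, leaving the
meningeal global signal in the data.

## Connectivity and inference

Fisher z = atanh(r) is clipped to [−2, 2] per voxel pair *before* any
averaging (the clipping stage is otherwise ambiguous; clipping first makes
every downstream average respect the bound). Seed maps average over ROI
members within each hemisphere, then across hemispheres. Percentile
coupling maps use the linearly interpolated 98th percentile of each
voxel's coupling to all others (self excluded). Group reduction is a
plain SVD of the time-concatenated, column-centred data, keeping the top
k = 200 component pseudo-volumes; downstream coupling operators treat the
reduced series as pre-centred (cosine of loadings), which makes full-rank
reduction exactly lossless.

The permutation test compares the cosine similarity of the two
condition-mean fingerprints against a null built by relabelling run-level
fingerprints into two equal groups. Lower similarity means a larger
condition difference, so the p-value is one-tailed toward dissimilarity.
Complementary assignments are identified (the statistic is symmetric in
group exchange) and the identity labelling is excluded, giving
C(18,9)/2 − 1 = 24309 distinct relabellings for a 9-vs-9 design —
enumerated exhaustively, with exact-proportion p-values floored at
1/(n+1). Unbalanced designs fall back to Monte Carlo with
p = (b+1)/(n+1). Fingerprints enter the test per run (18 observations),
the reading consistent with the 24309 count.

## Known limitations

- No refraction/mode conversion in bone; transcranial pressure is a ray
  approximation anchored by free-water calibration.
- No CEM43 dose integral; the thermal output is peak ΔT per compartment.
- Volumetric smoothing only; no cortical-surface geometry anywhere.
- The synthetic BOLD model is a linear Gaussian mixture; its planted
  effect sizes are conventions, not measurements.
- Registration, brain extraction and motion-parameter estimation are out
  of scope; compartment labels and motion tables are accepted as inputs.
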