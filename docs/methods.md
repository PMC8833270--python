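# Methods

## Signal model

A multi-echo spoiled gradient-echo voxel containing water and fat
fractions W and F (W + F ≤ 1) is modelled as

    S_i = M0 (W + F e^{i 2π f_f TE_i}) e^{−R2* TE_i} e^{i 2π φ TE_i}

where φ (Hz) is the total field offset — the sum of the local field from
sources inside the region of interest and the harmonic background field
from sources outside — and f_f is the fat chemical-shift frequency,
−3.5 ppm × γB0 (≈ −223.5 Hz at 1.5 T; fat resonates below water, a sign
the model must fix by convention since only the product f_f·TE is
observable). The model has no T1/flip-angle term: TR and flip angle are
carried in the protocol for provenance only. There is no phase at TE = 0;
the temporal-guided unwrapping below relies on that property.

The susceptibility-to-field map is diagonal in k-space,
f(k) = D(k)·χ(k) with the Lorentz-corrected kernel
D(k) = 1/3 − k_z²/|k|², D(0) = 0 and B0 along the grid z axis. D(0) = 0
means only susceptibility *contrasts* are observable; maps are relative,
no reference region is subtracted, and the forward model removes the
volume mean of χ before convolving.

## Reconstruction chain

Per echo: wrapped phase → unwrap → ÷(2π TE_i) → LBV → V-SHARP →
polynomial detrend; then a T2*-weighted average of the per-echo fields,
then dipole inversion. Reading the processing order this way (each stage
per echo, combination last) is a choice; the combination step is described
as merging "the image of each echo", which fits combination-last.

**Unwrapping.** The Laplacian method computes ∇²φ_true from sin/cos of
the wrapped phase (both continuous across wraps) and inverts the 7-point
finite-difference Laplacian diagonalized by a DCT-II (mirror/Neumann
boundary, zero mean). The smooth Poisson estimate is then snapped back to
the data modulo 2π (global offset from the circular mean of the
difference, per-voxel wrap count rounded): the result is exactly congruent
to the input, and estimation error is confined to isolated wrap mistakes
where the phase is spatially undersampled instead of spreading smoothly.
For echo trains the first echo is unwrapped spatially and later echoes are
wrap-corrected against the TE-scaled first-echo phase: at long TE the
phase next to a strong source changes by more than π per voxel (at χ = −2
ppm and 2.5 mm slices this already happens at the second echo near sphere
poles), where any purely spatial unwrapper must fail; the TE-scaled
prediction stays within half a cycle wherever the first echo was right.
Harmonic phase components beyond π that the Laplacian cannot see are left
to background removal.

**LBV.** The background field inside the ROI is the harmonic function
matching the total field on the one-voxel boundary shell; it is computed
by conjugate gradients on the interior Dirichlet problem (7-point
Laplacian, tolerance 1e-6, max 1000 iterations, DCT-Poisson
preconditioner on the bounding box — typically a few dozen iterations).
Non-convergence raises with the last relative residual. The valid mask is
the ROI eroded by one voxel.

**V-SHARP.** Spherical-mean-value filtering with kernel radii 1–25 mm at
2 mm steps: each voxel uses the largest kernel fully inside the ROI;
kernels larger than the grid are dropped. The residual (δ − SMV) filter is
deconvolved once, with the largest kernel, by truncated k-space division
(threshold 0.05). The valid mask is the ROI eroded by the smallest kernel
radius, and always by at least one voxel — a kernel radius below the voxel
pitch rasterizes to the identity, which would leave boundary voxels
unfiltered.

**Detrending.** Ordinary least squares on all 3D monomials of total
degree ≤ 4 (35 terms), coordinates normalized to [−1,1] per axis over the
mask bounding box for conditioning; rank deficiency raises with the
condition number. Removes residual slowly-varying field the harmonic
models miss.

**Echo combination.** Weights w_i ∝ TE_i e^{−TE_i R2*}, normalized per
voxel, with R2* estimated from the data by the complex log-linear fit;
where all weights underflow the first echo is used. The pipeline uses the
empirical form w_i ∝ TE_i |S_i|, which is identical under mono-exponential
decay (M0 cancels in the normalization) but additionally down-weights
echoes lost to intravoxel dephasing next to strong sources — exactly the
voxels whose late-echo phase is spatially undersampled.

**Fat correction (human chain).** Dividing S_i by (W + F e^{i2πf_f TE_i})
before fitting is the only reading that makes ln S_i = A + B TE_i a true
line: as printed, the fat factor would otherwise sit TE-dependent inside a
TE-independent intercept. After demodulation M0 = |exp(A)|,
R2* = −Re(B) (clipped at 0, clip fraction logged), φ = Im(B)/(2π). The
echo-dimension phase is unwrapped temporally before the log; fields beyond
1/(2·ΔTE) = 71.4 Hz alias to φ − 1/ΔTE with a *small* residual when the
echo spacing is uniform — an undetectable failure mode documented in the
tests. Fat-free wrapped phases wrap(2πφTE_i) of the first three echoes
re-enter the standard chain, so strong-gradient regions are re-masked by
the same spatial machinery. The fit mask keeps voxels with first-echo
magnitude above 5% of the volume's 99th percentile.

**Inversion.** argmin_χ ‖W_t(F⁻¹DFχ − f/γB0·10⁻⁶)‖₂ by LSQR
(tolerance 1e-4, 200 iterations; weights uniform for the phantom chain,
magnitude for the human chain). The streak-reduction pass replaces the
k-space content of the first-pass map on the ill-conditioned cone
(|D| < 0.1) with that of a Gaussian low-pass prior (sd 5 mm, applied in
k-space); every off-cone frequency is bit-identical to the first pass. On
noisy, streaky inputs this reduces error; on a noise-free fully-masked
simulation the cone content of the LSQR solution is mostly signal, and
the pass trades a little interior amplitude for artifact robustness
(interior sphere means move from ~7–12% to ~16–19% below truth).

## Digital phantom

Five spheres (radii 1–5 mm ascending), χ = −2.0 ppm and 800 HU against a
gelatin background of 0 ppm / 20 HU, collinear with neighbour spacings
15.3, 25.4, 20.4, 27.5 mm (the CT-measured reference values), centred in
a 120×160×110 mm container surrounded by air (+9.4 ppm, −1000 HU). The
hydroxyapatite χ and HU are plausible values for dense calcification, not
measured ones, and are exposed in the config. Rasterization uses
supersample³ subvoxel occupancy (default 4³); labels assign voxels with
occupancy > 0.5. Default acquisition: six echoes, TE 5.7–40.7 ms step
7.0 ms, TR 45 ms, flip 20°, 1.5 T, 1×1×2.5 mm voxels on a 192×192×64
grid (in-plane voxel size follows from the 384 mm field of view over a
384 matrix). M0 = 100 inside the container with R2* 20 s⁻¹ (gelatin) and
100 s⁻¹ (spheres). The forward field is computed with ≥2× zero padding so
the periodic dipole convolution does not alias the r⁻³ tails; the spatial
mean over the container is removed before synthesis, emulating the
scanner's centre-frequency adjustment.

The simulator applies first-order intravoxel dephasing: magnitude is
attenuated by ∏_ax sinc(g_ax h_ax TE) with g the local field gradient.
This reproduces the signal voids seen around real hydroxyapatite and, via
the apparent-R2* rise, lets the magnitude-weighted echo combination
suppress late echoes precisely where their phase is spatially
undersampled. Without it, a point-sampled simulation overstates the
usable late-echo phase in exactly the regions where it is wrong.

Not emulated: multi-peak fat spectra, T1/flip-angle weighting, eddy
currents, B0 drift, coil phase offsets (phase is exactly ∝ TE, which the
temporal unwrap guidance exploits — real data with a TE=0 phase offset
would need an extra intercept), CT point-spread blurring, and patient
anatomy. Passing tests therefore demonstrate correctness of the numerics
and internal consistency of the model, not clinical performance.

## Metrics

CT segmentation thresholds at 130 HU (the clinical calcium-scoring
level); for the synthetic CT this equals the voxel set with sphere
occupancy ≥ (130−20)/780 = 0.141. QSM has no absolute scale, so the
automated stand-in for manual delineation thresholds at half of the most
negative value ("half-min"), pruning 26-connected components below 2
voxels. Components are ordered along the axis of greatest centroid spread
(the phantom's arrangement axis); volumes are voxel count × voxel volume;
centroids are unweighted world-coordinate means; cross-modality pairing is
greedy nearest-centroid within 10 mm. FWHM is measured on a trilinear
line profile through each component centroid along the arrangement axis
(256 samples), baseline from the median of the outer 20% of samples,
width between the outermost linearly interpolated half-level crossings;
the QSM profile is negated first.

**Known limitation — delineation levels.** The CT threshold sits at 14%
of the sphere/background contrast and therefore includes the
partial-volume shell (about +30% volume for a 5 mm sphere at 2.5 mm
slices), while half-min delineates at 50% and recovers approximately the
true volume. The QSM-vs-CT volume regression slope on the synthetic
phantom is consequently ≈0.77 even for an error-free reconstruction; the
1 mm sphere (peak recovered |χ| below half of the map minimum) is not
detected at all. Observers delineating manually evidently work closer to
the visible-extent level than to half-maximum — their in-profile widths
(FWHM) differ between modalities even where their volumes agree — so the
half-min surrogate is conservative about small and borderline lesions.

## Problem sizes and runtime

The bundled studies run at 192×192×64 (reference geometry, ~1–2 min per
chain on one CPU) and a reduced 80×80×24 variant used for determinism and
equivalence checks (~20 s). The LSQR and CG solvers are matrix-free
(FFT/stencil operators), so memory stays below ~1 GB at the reference
size.

## Determinism and degenerate inputs

All noise passes through a single integer seed (`numpy` Generator);
identical config + seed reproduces every output byte-for-byte, and each
study report embeds the seed and a hash of the full configuration.
Degenerate inputs fail loudly with typed errors: empty masks, overlapping
spheres, non-rigid resampling transforms, fraction maps outside [0,1],
non-increasing echo times, masks too small for the polynomial basis or the
smallest SHARP kernel, profiles without a peak, and regressions with
zero-variance abscissa. A flat susceptibility map has no diamagnetic
signal and half-min segmentation refuses it rather than thresholding
noise.
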