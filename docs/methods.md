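# Methods

## Forward model and simulator

The simulator emits non-attenuating sinusoidal shear waves from point
sources: `u(r, t) = sin(2πr/λ − 2πft)` with `r` the distance (mm) from the
source to each voxel center, sampled at P phase offsets spread evenly over
one vibration period. The wavelength follows from the shear stiffness via
`λ = sqrt(μ/ρ_d)/f`; at the defaults (μ = 3 kPa, f = 60 Hz,
ρ_d = 1000 kg/m³) λ = 28.868 mm ≈ 9.6 voxels at 3 mm isotropic spacing.
Three "motion-encoding directions" are emulated as three independent
point-source fields at the common wavelength, so the vector curl can be
formed exactly as for in vivo data. Voxel (0,0,0) is centered at the
physical origin; indexing is 0-based throughout.

What the simulator does **not** emulate: attenuation, viscoelastic loss
(the simulated loss modulus is ≈ 0), reflections and mode conversion at
interfaces, B1/coil shading, physiological noise, and the spatial noise
correlations of parallel-imaging reconstructions. Passing tests therefore
demonstrate the *postprocessing* properties (edge behavior, noise-bias
correction self-consistency, mask-first independence) — not accuracy on
in vivo data, whose ground truth is unknown.

Default geometry choices, exposed as parameters: spherical shells are
centered in an 80³ grid with outer radius 24 voxels (the shell thicknesses
15/13/11/9 are prescribed; the radius and grid extent are this package's
defaults). Shell masks use Euclidean distance in voxel units with a closed
outer and open inner boundary. Point sources sit 250 mm from the grid
center along three fixed oblique directions — outside the field of view,
far enough that wavefronts are nearly planar across the object.

## Processing chain

1. **First temporal harmonic.** `H = (2/P) Σ_p u_p exp(2πi p/P)`,
   normalized so a unit-amplitude sinusoid gives |H| = 1. (The
   normalization is a convention; it cancels in all SNR ratios and in the
   inversion.) The harmonic is taken before the spatial derivatives —
   both operators are linear, so the order is immaterial, and this order
   is cheaper.
2. **Curl.** Central differences `[-1, 0, 1]/2h` per axis. In adaptive
   mode, voxels with only one in-mask neighbor along an axis use the
   one-sided (nearest-neighbor) difference, so no in-mask voxel is lost;
   the one-sided estimate is first-order accurate and effectively samples
   the derivative half a voxel inward, which is the main source of the
   residual edge error. In traditional mode the kernel is applied
   verbatim to the masked data (zeros outside), so edge voxels carry
   strongly biased values — this is deliberate: it is the behavior whose
   artifacts the adaptive kernels remove, and it is required to reproduce
   the thinning-shell bias. For slicewise 2-D data the third displacement
   component and all z-derivatives are taken as zero.
3. **Smoothing.** Separable `(1−x²)²(1−y²)²(1−z²)²` kernel over a 5×5×5
   window (endpoint weights are exactly zero, so the effective support is
   3×3×3). Adaptive mode renormalizes each voxel's kernel to the sum of
   its in-mask weights (constants are preserved exactly up to the edge);
   traditional mode lets zeros leak in. Complex fields are smoothed
   componentwise (linearity).
4. **Inversion.** 3-point Laplacian per axis, deliberately *not*
   edge-adaptive (adaptivity covers steps 2-3 only); this leaves the
   1-voxel residual rim in adaptive elastograms. `G = −ρ_d ω² C/∇²C`
   with a relative division floor of 1e-9 on |∇²C| (voxels below it are
   invalid, not exceptions). Component elastograms are combined as an
   amplitude-weighted average of the complex moduli (weights = smoothed
   curl amplitudes), then converted once to stiffness — combining moduli
   before conversion was chosen for symmetry; a flag to combine
   stiffnesses instead is trivial to add and made no measurable
   difference at these noise levels. Whether the weights should use
   smoothed or unsmoothed amplitudes is not determined by first
   principles; the smoothed amplitude (available immediately after step
   3) is used.
5. **Summaries.** ROI medians exclude `edge_exclusion` voxels from the
   ROI edge (6-connected erosion; erosion first, then invalid voxels are
   dropped). A 3×3×3 median filter exists for display only and never
   feeds quantitative output.

On an exact plane wave the whole chain collapses to the closed form
`G = ρ_d ω² h²/(2(1−cos kh))` — 3.1089 kPa for a 3 kPa medium at 60 Hz and
h = 3 mm — because smoothing and curl scale numerator and denominator
identically; the test suite verifies the chain against this oracle to
better than 0.1%.

## Edge-artifact measurements

Distance from the mask edge is the 6-connected (city-block) distance, so
the outermost in-mask voxels have distance 1. The **interior plateau** is
the median stiffness over valid voxels at distance ≥ 5. The **artifact
width** is the largest distance whose 1-voxel ring has a median relative
*underestimation* `(plateau − μ)/plateau` above 5%; ring medians make the
measure robust to isolated outliers, and the signed deviation targets the
underestimation rim (adaptive processing also produces a ~14% ring of
*over*estimation at distance 2 — a consequence of the half-voxel phase
shift of the one-sided edge derivative propagating through the
non-adaptive Laplacian — which is not part of the underestimation rim).
Measured on the noise-free shell simulation the width is 3 voxels
(traditional) and 1 voxel (adaptive) at every shell thickness.

The **erosions-to-plateau** metric is the smallest erosion count e with
`|median(e) − median(e+1)|/median(e+1) < 1%`. A caveat discovered with
this implementation: because the median is robust, the metric is
insensitive whenever edge-artifacted voxels are a minority of the ROI —
for the 15-voxel shell the traditional-mode full-ROI median sits within
0.2% of its converged value at *every* erosion level even though a third
of its voxels are severely underestimated, and the metric reports 0. On
the thinnest (9-voxel) shell, where artifact voxels are the majority, it
reports 2. The artifact width is the sensitive and reliable measure of
how many erosions traditional processing actually needs (3); the
plateau metric is retained with its documented 1% threshold for
completeness.

## SNR maps and bias correction

SNR is computed per curl component as the harmonic curl amplitude divided
by the standard deviation of the motion-off curl in sliding 3×3×3
neighborhoods (in-mask voxels only, pooled over motion-off offsets).
Regional SNR is summarized by the *median of the most likely SNRs*: with
fixed 0.5-wide histogram bins from zero, the smallest set of
highest-count bins jointly holding at least half the voxels is selected
(greedily by count, contiguity not forced) and the median is taken over
samples inside the span of those bins. For the right-skewed SNR
histograms of brain data this lies between the mode and the median; the
bin width is a parameter (0.5 SNR units by default, chosen so skewed
histograms at typical brain SNR of 2-15 resolve a clear mode).

The correction iterates: simulate a point-source field at the trial
stiffness on a grid mimicking the acquisition (80×80×48 at 3 mm, 8 phase
offsets, source outside the FOV; no curl step — the simulated field is
scalar), smooth and invert it, take medians excluding 3 voxels from each
FOV edge without noise (μ_∞) and with zero-mean Gaussian noise of
standard deviation 1/SNR (μ_SNR), form CF = μ_∞/μ_SNR, update the trial
stiffness by Δμ = CF·μ_m − μ_∞, and stop when |Δμ| < 0.001 kPa (25
iterations maximum; non-convergence raises with the partial trace
attached). The fixed point satisfies μ_SNR(μ_sim) = μ_m: the corrected
value is the true stiffness whose simulated noisy measurement equals the
measured one. To tame the stochastic increment, CF is averaged over 5
independent noise draws per iteration, with draw seeds derived from the
single user-provided seed; convergence takes 2-3 iterations at SNR ≥ 3.
Note the fixed point also removes the discretization overestimate of the
simulated measurement (~2-4% at 3 kPa / 3 mm), so the corrected value can
sit *below* the measured one at high SNR.

## Regional pipeline

Brain masks follow the strict rule GM + WM > CSF on already-coregistered
tissue-fraction volumes; ROIs are intersections of the brain mask with
atlas labels (frontal, occipital, parietal, temporal, deep GM/WM,
cerebellum; the global ROI is the union of all non-cerebellar labels).
Segmentation, warping, and registration are out of scope — the package
consumes resliced volumes on the MRE grid. Wave data are masked by the
ROI before any kernel is applied, so the regional median is bit-identical
under arbitrary modification of exterior voxels (tested by randomizing
them). ROI medians use 1 erosion with adaptive processing; on large
homogeneous phantoms this agrees with traditional processing at 3
erosions to better than 1%.

## Experiment defaults

- Shell sweep: thicknesses 15/13/11/9, erosion levels 0-3 reported (one
  extra level computed internally so the plateau criterion is defined at
  level 3), both processing modes, noise-free, ~0.5 s per inversion on
  one core.
- Noise robustness: ball phantom (radius 24 voxels in a 64³ grid) at
  3 kPa with measurement noise σ = 0.05 on unit-amplitude waves and
  motion-off volumes at the same σ; the stress condition doubles the
  total noise standard deviation, halving the measured SNR. The extra
  noise is injected in image space at the k-space-equivalent variance
  (Parseval), and the output table flags this. Stiffness is computed per
  ROI (whole ball and two halves) with and without SNR correction.
- ROI-size precision: homogeneous 3 kPa phantom in a 48³ grid with noise
  whose standard deviation grows exponentially with radius
  (σ = 0.02·exp(r/60 mm) — an emulation of attenuation-driven SNR decay,
  not a measured profile), summarized by sliding-window medians of
  stiffness and SNR at windows 3/5/7.

Problem sizes were chosen so the full suite and the acceptance script
each complete in a few minutes on a single core while keeping ≥ 10⁴
voxels in every summarized region. In vivo quantities (cohort medians,
test-retest CVs) require human data and are not reproduced by the
simulations.

## Known limitations

- The Helmholtz model assumes local homogeneity, isotropy and linear
  elasticity; the inversion is undefined where |∇²C| vanishes (wave
  nodes), and such voxels are flagged invalid rather than filled.
- The adaptive scheme leaves a 1-voxel biased rim (non-adaptive
  Laplacian, first-order edge derivatives) plus the distance-2
  overestimation ring described above; 1 erosion removes the rim but not
  the ring, whose effect on ROI medians is small (< 0.3% on shells).
- The SNR correction models noise as white and additive in the
  displacement domain with σ = 1/SNR; correlated or multiplicative noise
  is not modeled, and the scalar (no-curl) simulation inside the loop is
  an approximation to the full vector pipeline.
- Phase unwrapping is not implemented; the phase-difference plus
  slow-phase-removal route assumes wrapped phase differences stay within
  (−π, π] after detrending.
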