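# mrepost

Edge-adaptive postprocessing and regional stiffness mapping for brain
magnetic resonance elastography (MRE).

MRE images propagating shear waves with a phase-contrast MRI sequence and
inverts them into a voxelwise stiffness map (an *elastogram*). Two biases
plague brain elastograms in practice:

- **edge artifacts** — every convolution kernel in the processing chain
  (curl, smoothing, Laplacian) straddles the brain/CSF boundary, so a rim
  of voxels several voxels deep underestimates stiffness. When brains
  shrink (atrophy), that rim becomes a larger fraction of any region of
  interest and produces a spurious "softer brain";
- **noise bias** — measurement noise has high spatial frequencies that the
  inversion reads as low wave speed, depressing stiffness as SNR falls.

`mrepost` implements a pipeline that is resistant to both: edge-aware
(adaptive) derivative and smoothing kernels that restrict their support to
in-mask voxels and renormalize, an iterative simulation-based SNR bias
correction, and a mask-first regional pipeline in which wave data are
masked by each ROI *before* any spatial kernel is applied, so the regional
estimate is provably independent of everything outside the ROI. A built-in
analytic shear-wave simulator (point sources, spherical-shell masks,
erodable phantoms) provides the validation experiments.

## The model

Each curl component C of the first temporal harmonic of the displacement
field is assumed to satisfy the Helmholtz equation

    G ∇²C + ρ ω² C = 0,

so the complex shear modulus is recovered voxelwise by direct inversion

    G = −ρ ω² C / ∇²C,        G = G′ + i G″  (storage + loss modulus),

with ρ = 1000 kg/m³ (water) and ω = 2πf. The three per-component
elastograms are combined by an amplitude-weighted average and converted to
shear stiffness (density × squared shear-wave speed of a viscoelastic
medium):

    μ = 2|G|² / (G′ + |G|).

Regional values are medians over the ROI after excluding 1 voxel (adaptive
processing) or 3 voxels (traditional processing) from the ROI edge.

## Worked example

Convert a published complex shear modulus to shear stiffness:

```python
>>> from mrepost import modulus_to_stiffness
>>> modulus_to_stiffness(2.43 + 1.21j)   # kPa in, kPa out
2.8647568421861727
```

A storage/loss modulus of 2.43 + 1.21i kPa corresponds to a shear
stiffness of 2.86 kPa.

Correct a measured regional stiffness of 3.05 kPa at a regional SNR of 4.2:

```
$ mrepost correct --stiffness 3.05 --snr 4.2 --seed 0
corrected stiffness: 2.9993 kPa (2 iteration(s))
  iter 1: mu_sim=3.0001 mu_inf=3.1212 mu_snr=3.0995 CF=1.00698 delta=-0.04986
  iter 2: mu_sim=2.9993 mu_inf=3.0713 mu_snr=3.0508 CF=1.00673 delta=-0.00080
```

Each iteration simulates a point-source acquisition at the current trial
stiffness, measures it noise-free (`mu_inf`) and with Gaussian noise of
standard deviation 1/SNR (`mu_snr`), and updates the trial stiffness with
the correction factor CF = mu_inf/mu_snr until the update falls below
0.001 kPa. The corrected value is the true stiffness whose simulated noisy
measurement reproduces the measured one.

Simulate a spherical-shell phantom and invert it:

```bash
mrepost simulate shell --stiffness 3 --thickness 15 --out sim/
mrepost invert --wave sim/wave_dir1.nii.gz --wave sim/wave_dir2.nii.gz \
    --wave sim/wave_dir3.nii.gz --mask sim/shell_mask.nii.gz \
    --mode adaptive --erode 1 --out sim/elast
# median stiffness (adaptive, 1 erosion(s)): 3.069 kPa
```

The adaptive pipeline recovers the 3 kPa ground truth with one erosion
(the +2.3% is the known discretization overestimate of the 3-point
Laplacian; the plane-wave closed form bounds it at 3.109 kPa for this
wavelength and 3 mm voxels). The simulation experiments
(`mrepost experiment shell|noise|precision`) show that traditional
processing leaves a 3-voxel underestimation rim while adaptive processing
leaves 1 voxel, that the SNR correction shrinks noise-induced errors in
every ROI of a half-SNR stress test, and that sliding-window stiffness
medians are unbiased by ROI size while their spread shrinks as the ROI
grows.

Python API for regional stiffness on real (already coregistered) data:

```python
from mrepost import (build_brain_mask, extract_roi, regional_stiffness)
brain = build_brain_mask(gm, wm, csf)            # GM + WM > CSF rule
roi = extract_roi(labels, {1}, brain)            # frontal lobes
median_kpa, elastogram = regional_stiffness(series, roi, mode="adaptive")
```

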