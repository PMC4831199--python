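# vsseg — seed-driven volume-scalable active contours for 3-D medical volumes

`vsseg` is a semi-automatic segmentation toolkit for volumetric grayscale
images (MR/CT-like) degraded by intensity inhomogeneity, noise and weak
object boundaries. The user draws a few seed strokes inside the target
(and optionally in the background); a level-set active contour then grows
from the strokes to the object boundary, driven by per-voxel *robust
statistics* rather than raw intensities.

## The model in brief

Every voxel x carries a feature vector of kernel-weighted robust local
statistics at scale σ,

f(x) = (VSMEAN(x), VSIQR(x), WIV(x)) — local mean, inter-quartile range
and robust standard deviation —

and is scored for foreground/background by a hybrid probability density

P_i(x) = (1−ω)·mean_{z∈seeds_i} p(f(x) − f(z))
       + ω·∫ K_η(x−y) p(μ_i(x) − f(y)) M_i(y) dy,   i = 1, 2,

where μ_i are the kernel-weighted feature means of the two phases
M_1 = H(φ), M_2 = 1 − H(φ), and p is a Gaussian whose width adapts to the
measured local variability WIV(x). The segmentation minimises

F(φ, P_1, P_2) = −Σ_i λ_i ∫∫ K_η(x−y) P_i(y) M_i(y) dy dx
               + ν ∫|∇H(φ)| + (μ/2)∫(|∇φ| − 1)²

by alternating closed-form P_i updates with gradient-flow steps of the
level-set field φ (narrow-band, semi-implicit Gauss–Seidel). ω blends seed
anchoring (ω→0) with purely local adaptation; at ω=1 the scheme reduces
structurally to region-scalable fitting (RSF), which is also provided as a
standalone baseline engine. Defaults: σ=0.5, η=3.0, λ1=1.0, λ2=2.0, Δt=0.1,
ω=0.4, μ=1.0, ν=0. See `docs/methods.md` for the numerical scheme and all
design choices.

The package also ships a synthetic-phantom generator (objects with known
ground truth, multiplicative bias fields at a prescribed peak-to-peak
percentage, Gaussian noise, partial-volume edge blur, random seed strokes)
and Dice / Hausdorff evaluation, so the whole pipeline is verifiable
without any data downloads.

## Worked example

```python
from vsseg import (PhantomSpec, make_phantom, make_seed_strokes,
                   VolumeScalableSegmenter, score)

# a 48^3 sphere at contrast 200/0 with 40% bias field and noise STD 10
spec = PhantomSpec(size=48, radius=12, inu=0.40, noise_std=10.0, rng_seed=7)
image, truth = make_phantom(spec)
seeds = make_seed_strokes(truth, n_strokes=2, stroke_length=8, rng_seed=11)

est = VolumeScalableSegmenter().fit(image, seeds)
s = score(est.mask_, truth, image.spacing)
print(f"converged after {est.n_iter_} iterations: {est.converged_}")
print(f"Dice = {s.dsc:.4f}")
print(f"Hausdorff = {s.hd:.2f} mm")
print(f"object volume = {s.n_a} voxels (truth {s.n_b})")
```

prints

```
converged after 159 iterations: True
Dice = 0.9647
Hausdorff = 1.00 mm
object volume = 6716 voxels (truth 7208)
```

i.e. despite the 40% bias and the noise, the contour grown from two short
strokes overlaps the ground-truth sphere with Dice 0.96 and its largest
boundary deviation is one voxel. `RegionScalableSegmenter` runs the RSF
baseline with the same interface; both are scikit-learn-style estimators
(`get_params`/`set_params`/`fit`/`fit_predict`).

## Command line

```
vsseg phantom  --out-image img.nii.gz --out-truth gt.nii.gz \
               --out-seeds seeds.nii.gz --size 64 --radius 16 \
               --inu 0.4 --noise-std 10
vsseg segment  --image img.nii.gz --seeds seeds.nii.gz --out mask.nii.gz \
               [--engine vsrf|rsf] [--omega 0.4] [--sigma 0.5] ...
vsseg evaluate --pred mask.nii.gz --truth gt.nii.gz
```

Volumes are NIfTI (`.nii`/`.nii.gz`) or NRRD (`.nrrd`); seed maps use codes
0 (unlabeled), 1 (foreground), 2 (background). Runs are deterministic for
fixed flags and RNG seeds.

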