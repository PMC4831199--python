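# Methods

`vsseg` segments a single anatomical structure from a 3-D scalar volume
(MR/CT-like intensities) given a handful of user seed strokes inside the
target and, optionally, in the background. It implements two active-contour
engines on a shared level-set core: a seed-anchored, robust-statistics,
volume-scalable model (the default) and a region-scalable fitting (RSF)
baseline driven by local intensity means.

## The model

**Features.** Every voxel x carries a 3-vector of kernel-weighted robust
statistics computed over a Gaussian neighbourhood of scale σ (voxels):

* VSMEAN(x) = (K_σ * I)/(K_σ * 1), the local mean;
* VSIQR(x), the distance between the kernel-weighted first and third
  quartiles of the window, read off the weighted empirical CDF with linear
  interpolation between adjacent order statistics (ties ordered by tap
  weight, which makes the statistic deterministic and keeps it at zero in
  locally constant regions);
* WIV(x) = sqrt(K_σ * (I − VSMEAN(x))² / (K_σ * 1)), a robust local
  standard deviation about the centre's local mean.

Kernels are sampled on the voxel lattice, truncated at radius
max(1, ceil(3σ)) and renormalised; they factorise into 1-D profiles, so the
separable statistics cost three 1-D passes. Boundaries are handled by
replicate padding, under which K*1 ≡ 1 and the statistics stay unbiased at
the volume border. Kernels are defined in voxel units and isotropic;
anisotropic spacing is not folded into the kernel.

**Voxel characterisation.** Each voxel is scored for the foreground (i=1)
and background (i=2) by a hybrid density

P_i(x) = (1−ω)·mean_z p(f(x) − f(z)) + ω·Σ_y K_η(x−y) p(μ_i(x) − f(y)) M_i(y),

where z runs over the class-i seed voxels (subsampled to at most 2000 with
a fixed RNG seed), M_1 = H(φ), M_2 = 1 − H(φ), and μ_i = K_η*(f·M_i)/K_η*M_i
are the kernel-weighted phase feature means (denominators floored at 1e-8
where a phase is locally absent). The blend weight ω ∈ [0,1] moves between
pure seed anchoring (ω=0, contour-independent) and pure local adaptation
(ω=1, seed-free; structurally the region-scalable limit). The degenerate
blends are exact: at ω=1 the seed bank is never touched, so the trajectory
is bit-identical under any relabelling of the seeds.

p is an isotropic 3-channel Gaussian whose standard deviation at x is
s(x) = max(WIV(x), floor), the measured variability of the very window
being characterised, with floor = 1% of the feature dynamic range. Flat
regions therefore get sharp, selective densities; boundaries and noisy
regions get tolerant ones. If no background seeds are given, the background
bank is drawn from the 1-voxel border shell of the volume.

**Energy.** The total functional is

F(φ, P_1, P_2) = −Σ_i λ_i ∫∫ K_η(x−y) P_i(y) M_i(y) dy dx
               + ν ∫ |∇H(φ)| + (μ/2) ∫ (|∇φ| − 1)²,

i.e. a fitting reward for covering high-density voxels with the right
phase, a surface-area smoothness term, and a distance-regularisation term
that keeps φ near a signed distance function without explicit
reinitialisation. Minimisation alternates closed-form P_i updates with
gradient-flow steps of φ.

**The flow.** With P_i fixed, the exact first variation of the fitting part
is δ(φ)(λ_1 P_1(x) − λ_2 P_2(x)): the outer x-integral contributes
∫K_η dx = 1, so no second kernel pass appears in the gradient. The update is

φ ← φ + Δt·[ δ_ε(φ) F̂ + ν δ_ε(φ) κ + μ (∇²φ − κ) ],

with κ = div(∇φ/|∇φ|) by central differences (|∇φ| floored at 1e-8), an
arctan Heaviside H_ε(z) = ½(1 + (2/π) atan(z/ε)) with ε = 1 voxel and its
Lorentzian derivative δ_ε, and the Laplacian swept in place in lexicographic
order (semi-implicit Gauss–Seidel) with replicate boundaries.

F̂ is the saturated log-likelihood ratio

F̂ = gain · clip( (log(λ_1 P_1 + z) − log(λ_2 P_2 + z)) / softness, −1, 1 ),

z a 1e-12 relative floor. This is a pointwise positive rescaling of the
variational gradient — the sign field, the zero set and the fixed points
are identical — chosen for two numerical reasons. First, raw densities span
many orders of magnitude with the feature variances, and a front whose
speed is proportional to them either crawls or explodes; the log form is
scale-free. Second, the rest position of a level-set front under a
mollified δ with heavy tails satisfies ∫δ(φ)F = 0 rather than F = 0, so any
magnitude asymmetry between the two sides drags the interface off the
decision boundary; saturating at ±softness (default 0.25 nats) makes the
near-interface magnitudes symmetric and parks the contour on the model's
own decision surface. Defaults: softness 0.25, gain 10 (≈0.3 voxel/step
peak speed at Δt = 0.1). The literal printed flow, with e_i = K_η * P_i and
per-step mean normalisation, remains available (`force_form="as_printed"`);
on sharp boundaries it lets the λ_2-weighted background term repel the
front from an η-window distance and is not recommended.

**Initialisation and stopping.** φ starts as the signed Euclidean distance
to the seed strokes dilated by one voxel (a 1-voxel stroke's SDF ridge
would be smoothed away by the μ-term within a few steps, before the data
force can grow it). Evolution stops when the fraction of voxels whose sign
changed across a 10-iteration window falls below 1e-4 (never before
iteration 30, so a small initial front cannot trip the test), or at
max_iters = 300.

**Narrow band.** Updates are restricted to |φ| < 6 voxels. When the zero
level comes within 2 voxels of the band edge, φ is redistanced (EDT of the
current sign mask) and the band rebuilt; without redistancing the stale
frozen distances outside the band would stall the front at the old band
edge. In the evolution loop the fitting functions are refreshed each step
on the band (plus a margin), on a stride-2 coarse lattice with trilinear
interpolation — the local term is K_η-smoothed, hence band-limited at scale
η = 3, and stride 2 is comfortably below Nyquist for it (stride 3 was
measured to cost ~0.02 DSC and rejected). The evolution loop truncates the
η kernel at radius ceil(2η) (87% of the 3-D Gaussian mass before
renormalisation) to bound the cost of the nonlocal term. The public
operations (`fitting_functions`, `local_feature_means`, `data_force`,
`total_energy`) use exact full-support evaluation; they are the surfaces
the brute-force oracle tests check.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| sigma | 0.5 | voxels | feature kernel scale; raise (0.5–5) for heavier noise |
| eta | 3.0 | voxels | fitting/locality scale; raise (3–30) for milder inhomogeneity |
| lambda1, lambda2 | 1.0, 2.0 | – | phase data weights; lambda2 > lambda1 biases conservatively against the object |
| omega | 0.4 | – | seed (0) ↔ local (1) blend; use small ω when seeds are trustworthy |
| mu | 1.0 | – | distance-regularisation weight |
| nu | 0.0 | – | surface smoothness weight |
| dt | 0.1 | – | time step (μ·6·dt < 1 for the sweep) |
| eps | 1.0 | voxels | Heaviside/Dirac mollifier width |
| seed_cap | 2000 | voxels | per-class seed subsample bound |
| band_width | 6.0 | voxels | active-band half width |
| force_softness, force_gain | 0.25, 10 | nats, – | force saturation (above) |

The RSF baseline shares the mollifier, sweep, band, stopping rule and force
saturation, and differs only in its data term, the kernel-smoothed squared
residuals to the local phase intensity means f_1, f_2 (σ default 3.0,
expanded algebraically into separable convolutions).

## Synthetic phantoms

The generator reproduces the degradation axes used for synthetic MR
evaluations: objects (sphere, two blobs, a thickened sinusoidal
"folded sheet" as a high-curvature stand-in, a low-contrast blob) rasterised
at contrast 200/0; optional Gaussian blurring of the binary edge emulating
partial voluming; a multiplicative bias field, exp of a sum of three broad
random Gaussians, rescaled by root-finding so its peak-to-peak variation
over the foreground is exactly the requested fraction of its mean there
(e.g. 40% INU); i.i.d. Gaussian noise of requested STD, clamped at zero.
The ground truth is the exact rasterised geometry, identical across all
degradation settings. Seed strokes are straight axis-aligned runs placed
uniformly at random strictly inside the eroded target (mutually
non-adjacent, so n strokes form n components), reproducible per RNG seed.
The clean phantom defaults to a sharp (two-valued) edge.

What the phantoms do not emulate: anatomy (no tissue textures, no
multi-class background, no slice artefacts), spatially varying noise, and
BrainWeb's specific INU field shapes — passing these tests shows correct
mechanics and robustness trends, not clinical performance.

## Evaluation

Dice overlap 2|A∩B|/(|A|+|B|) and the exact symmetric Hausdorff distance
between boundary voxels (6-connectivity surface; coordinates scaled by the
voxel spacing; 100th percentile, not HD95). For closed solids the
boundary-set and full-set Hausdorff distances coincide.

## Known limitations

* On an ideal sharp-edged two-phase phantom at the default operating point
  (ω = 0.4, λ2 = 2) the blended density model's own decision surface sits
  about a quarter voxel inside the true boundary: boundary voxels' VSIQR/WIV
  spike matches neither phase mean, and the λ2-weighted outside term wins
  the blend at the outermost shell. The seed term alone (ω = 0) classifies
  such a phantom exactly; with noise present the WIV-adaptive variances are
  well calibrated and the deficit disappears. Expect Dice ≈ 0.95–0.97 on
  clean sharp spheres and ≈ 0.97–0.98 on biased/noisy ones at defaults.
* On single-object two-phase geometry the RSF baseline is correctly
  specified and is as good as or better than the robust-feature model; the
  latter's advantages (seed anchoring, robustness to initialisation and to
  heterogeneous backgrounds) show on complex scenes, of which the phantom
  suite only probes the initialisation-robustness part.
* One contour, one object class; no shape priors; no multimodal fusion.
* Determinism: all randomness flows through explicit RNG seeds; repeated
  runs are bit-identical on the same machine.
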