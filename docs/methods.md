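# Methods

`dtithresh` quantifies how the FA threshold used in atlas-based white-matter
segmentation changes regional volumes, diffusion scalars and their
inter-subject variability, in the regime of the neonatal brain where many
tracts have FA close to the candidate thresholds. This note records the
models, the defaults and the reasoning behind the open design choices.

## Signal model and tensor estimation

Diffusion is modelled per voxel as a symmetric positive-semidefinite 3×3
tensor D (mm²/s). The simulated signal follows the single-shell
monoexponential model

    S_i = S0 · exp(−b · g_iᵀ D g_i),

with b = 1000 s/mm², 25 unit gradient directions and 3 B0 images. The
direction set was produced once by minimising an antipodally symmetric
Coulomb energy on the sphere (electrostatic repulsion; minimum pairwise
angular separation ≈ 28°) and is shipped verbatim in
`dtithresh.acquisition`.

Noise is Rician: the stored value is |S + n₁ + i·n₂| with n₁, n₂ ~
N(0, σ²) and σ = S0/SNR, matching magnitude reconstruction of MR images.
`snr = inf` is an exact noise-free sentinel, which makes closed-form
oracles possible (a noise-free simulate → fit round trip recovers the
tensor to ≈ 1e-17 mm²/s, i.e. machine precision of the linear solve).

Fitting is ordinary (unweighted) log-linear least squares on
ln(S_i/S0), with S0 the mean of the B0 volumes. Weighted or nonlinear
estimators reduce noise bias but introduce estimator-specific behaviour;
OLS is the reproducible baseline and its defects are part of what the
study measures. Voxels with S0 ≤ 0 or any S_i ≤ 0 are marked invalid and
excluded through a propagated validity mask — clamping before the log
would instead produce near-zero tensors that silently pass FA thresholds.

Eigenvalues are sorted descending. Scalars use the standard definitions:
FA = √(3/2)·‖λ − λ̄‖/‖λ‖, trace = λ₁+λ₂+λ₃, AD = λ₁, RD = (λ₂+λ₃)/2.
Negative eigenvalues (possible in noisy fits) are kept for trace/AD/RD —
clamping would bias exactly the high-trace CSF voxels the trace cutoff
must catch — and clamped to zero for FA only, keeping FA in [0, 1]. The
clamp count is reported on the scalar maps. An all-zero voxel has FA 0 by
definition.

## The synthetic cohort

The phantom supplies what the analysis actually consumes — co-registered
labels plus realistic scalar contrast — with no anatomy. Geometry is
abstract: on the default 48³ grid (1.25 mm voxels) twelve bilateral WM
regions are rectangular blocks (1728 voxels each) mirrored left/right
inside a grey-matter interior, a 2-voxel CSF rim and a background margin.
Blocks are separated by 1-voxel GM gaps so every region has a
partial-volume interface. Equal block sizes were chosen so each region
supports a stable interior calibration measurement (960 interior voxels
per side); real atlas regions vary greatly in size, which this phantom
deliberately does not reproduce.

Regions span the neonatal maturity range, from an anterior-corona-radiata-
like region at FA 0.15 — sitting on the lowest threshold — to a
posterior-limb-like region at FA 0.50, with axial diffusivities of
1.4–1.95e-3 mm²/s (highest in the callosal regions). Within a pure region
the noise-free tensor is axially symmetric (λ₂ = λ₃): given a target FA f
and AD λ₁, the radial/axial ratio x = λ⊥/λ∥ solves
f = (1 − x)/√(1 + 2x²), inverted in closed form as
x = (1 − f·√(3 − 2f²))/(1 − 2f²) (linearised at the removable singularity
f = 1/√2). Unreachable FA/AD pairs raise a parameterisation error.

Orientation follows one of three modes. `uniform-axis` regions share one
deterministic axis; `smoothly-varying` regions rotate the axis by 90°
across the region; `crossing` regions mix two orthogonal fibre
populations voxel-wise at a fixed fraction (0.25–0.30 for the corona
radiata subdivisions), with the constituent anisotropy solved numerically
so the mixture's FA still equals the region target and the mixture
rescaled so its largest eigenvalue equals the AD target. Crossing-fibre
geometry is thereby a labelled property of the ground truth, not an
accident of noise.

Compartments: CSF is isotropic at 3.0e-3 mm²/s per axis (trace 9e-3
mm²/s, above the 0.006 exclusion cutoff); GM has per-voxel FA drawn
uniformly in [0.02, 0.12] with random axes and trace fixed at 3.3e-3
mm²/s. Voxels within one voxel of a compartment border get a 50/50
mixture of their own tensor and the mean neighbouring-compartment tensor —
a one-voxel partial-volume shell that reproduces the boundary-voxel
failure mode threshold choice is meant to manage. The compartment
contrast guarantees (CSF trace > 0.006, GM FA < 0.15) hold by
construction for pure-compartment voxels; partial-volume voxels are
intermediate by design (WM/GM edges reach FA ≈ 0.3).

Between-subject variability is a per-region FA offset ~ N(0, sd) with
sd = 0.02–0.025, shared by left/right homologues so hemispheric means
stay correlated within a subject. There is no additional within-region
ground-truth FA spread: interior noise-free FA is exactly the subject
target, and all within-region dispersion in fitted maps comes from
measurement noise, boundaries and crossing mixtures. This is a deliberate
free choice — it keeps the snr = ∞ calibration exact (interior regional
FA matches the target to < 1e-3 by construction) at the cost of a lighter
true-FA tail than real tissue.

Default cohort conditions: 8 subjects, SNR 20, S0 = 1000. Seeding uses
`numpy.random.SeedSequence(seed).spawn`, one child stream per subject, so
identical (config, seed) gives bit-identical cohorts.

## Masking cascade and regional metrics

Per subject and region: the base mask is the atlas label intersected with
trace ≤ 0.006 mm²/s (CSF is excluded by a strict `>` on trace, so a voxel
exactly at the cutoff is retained) and with the validity mask. Each FA
condition then keeps base voxels with FA strictly greater than the
cutoff; the conditions base, FA>0.15, FA>0.20, FA>0.25 are nested by
construction, and voxel counts are non-increasing while within-mask mean
FA is non-decreasing in the cutoff. Cells (region × condition × subject)
with fewer than 10 voxels are flagged excluded and carry counts but no
means. Exclusion is per cell: a region excluded at FA>0.25 in one subject
still contributes at the other cutoffs — listwise deletion is not
applied, and cohort tables report per-condition n for each region.

`percent_volume` is 100 · n(condition)/n(base), with the trace-masked
base as denominator; the raw-atlas-label denominator is carried as a
diagnostic column. Regional means are unweighted voxel averages.

## Cohort statistics

Across subjects, each (region, condition, measure) cell gets the sample
mean, SD (n−1), CV = SD/mean (defined for positive means; it is
scale-invariant) and a Student-t 95 % CI (t chosen over the normal: the
difference is negligible at n = 45 and matters at phantom cohort sizes).
Cells with one contributing subject report the mean only.

Condition effects are tested region by region (left and right separately)
with the Kruskal–Wallis rank test across all four conditions. H uses the
tie-corrected form — ties are real here because excluded cells shrink
groups — and the primary p comes from the chi-square(k−1) upper tail.
When the pooled sample is small (total n ≤ 30) a seeded Monte-Carlo
permutation p (10⁴ resamples, add-one estimator) is reported alongside;
permutations are vectorised and reuse the single tie-correction constant
of the pooled multiset. Adjacent-condition contrasts (base vs 0.15, 0.15
vs 0.20, 0.20 vs 0.25) use the same statistic on two groups, which is
equivalent to a rank-sum test.

The family-wise cutoff is Bonferroni: alpha/m with alpha = 0.05 and
m = 12 regions by default (0.05/12 = 0.00417 to 3 s.f.). The working
cutoff is the exact fraction, not the rounded presentation value, because
the rounding direction matters at the boundary; significance uses a
strict `<`. Whether left and right should count separately (m = 24) is a
config knob (`family_size`), defaulting to the 12-region family.

## Numerical choices and degenerate inputs

- Thresholds: ties resolved exactly as stated (trace at cutoff retained;
  FA at cutoff excluded).
- A region absent from the label volume yields an empty mask and a
  warning, not an error; an empty base mask flags the region
  unanalyzable for that subject.
- Fully tied samples give H = 0, p = 1 (the tie correction degenerates).
- Non-PSD ground-truth tensors abort simulation naming the voxel;
  rank-deficient gradient schemes abort fitting.
- Grids are validated before analysis; shape/affine mismatches are hard
  errors naming the offending pair, with no partial outputs.

## What passing tests do and do not show

The phantom emulates compartment contrast, partial-volume boundaries,
crossing fibres, Rician noise and between-subject FA variation. It does
not emulate anatomy, registration error, motion, eddy currents,
multi-repetition averaging, spatially correlated noise, or heterogeneous
region sizes. Two consequences observed at the default conditions are
worth stating plainly:

1. Rician noise plus eigenvalue ordering inflates fitted FA at low FA:
   at SNR 20 the inflation is ≈ +0.036 at target FA 0.15, ≈ +0.010 at
   0.42, reproduced independently by a from-scratch single-voxel
   Monte-Carlo. Regional FA recovery at SNR 20 is therefore accurate to
   ≈ 0.03 only for regions with target FA ≳ 0.18; the lowest-FA regions
   carry a larger, physics-driven bias.
2. The same noise gives the lowest-FA region a heavy fitted-FA tail
   (P(FA > 0.25) ≈ 0.10 at target 0.15), so with ~1700-voxel regions the
   10-voxel rule never triggers end-to-end. The rule's semantics are
   exercised on constructed scalar maps with narrower spread, where a
   50-voxel FA ≈ 0.15 region is identifiable at FA>0.15 but not at
   FA>0.25. In real neonatal data the analogous regime arises because
   repetition averaging and interpolation smooth the per-voxel FA
   distribution — features outside this phantom's scope.

## Problem sizes used

Default study: 8 subjects on a 48³ grid (≈ 110k voxels, 28 DWI volumes),
which runs the full generate → fit → segment → statistics chain in well
under a minute on one CPU. Unit and property tests use 24³ grids with a
three-region template. Statistic oracles enumerate exact permutation
distributions for pooled samples up to n = 8 and use 10⁴–2·10⁴ Monte-
Carlo resamples elsewhere.
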