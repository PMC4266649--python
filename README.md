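# dtithresh

Threshold sensitivity of atlas-based DTI white-matter segmentation,
exercised end-to-end on synthetic neonatal-like cohorts.

## The problem

Atlas-based analysis of neonatal diffusion tensor imaging selects each
white-matter region from a registered parcellation, removes CSF with a
trace cutoff, and then keeps only voxels above an FA threshold. Adult
pipelines typically use FA > 0.25 — but neonatal tracts are only partly
myelinated, and many sit at FA 0.15–0.25, right on top of the candidate
thresholds. The choice of threshold then changes the measured regional
volume, the regional FA/AD/RD means, and how variable those measurements
are across subjects, differently for immature and mature tracts.

`dtithresh` implements that analysis as a reusable pipeline for
researchers studying segmentation parameters in developing brains:

- a **synthetic phantom** — seeded cohorts with 12 bilateral WM regions
  spanning FA 0.15–0.5, grey matter (FA < 0.15), CSF
  (trace > 0.006 mm²/s), partial-volume boundary voxels, crossing-fibre
  regions, and Rician-noise DWI (25 directions + 3 B0 at b = 1000 s/mm²);
- a **tensor model** — log-linear least-squares fit of
  ln(S/S₀) = −b·gᵀDg, eigendecomposition, and the standard scalars
  FA = √(3/2)·‖λ−λ̄‖/‖λ‖, trace = λ₁+λ₂+λ₃, AD = λ₁, RD = (λ₂+λ₃)/2;
- the **masking cascade** — atlas label ∩ trace ≤ 0.006 mm²/s, then
  FA > {0.15, 0.20, 0.25}, with cells under 10 voxels excluded;
- **regional metrics** — voxel counts, percent of trace-masked base
  volume, mean FA/AD/RD per subject × region × condition;
- **cohort statistics** — mean, SD, CV = SD/mean, Student-t 95 % CI, and
  region-wise Kruskal–Wallis comparison of the four conditions
  (tie-corrected H, chi-square p, seeded permutation p for small n) at a
  Bonferroni-corrected alpha (0.05/12 ≈ 0.00417).

Real data enters at the analysis stage: pre-computed, co-registered FA /
trace / AD / RD maps plus an integer label atlas (NIfTI), or raw DWI
with FSL-style `bvec`/`bval` files. Registration itself is out of scope.

## Worked example

```python
from dtithresh import CohortConfig, ThresholdConfig, generate_cohort
from dtithresh.pipeline import StatsConfig, _fit_subjects, analyze_cohort

cohort = generate_cohort(CohortConfig(n_subjects=8, seed=7))
subjects = _fit_subjects(cohort, cohort.scheme)          # DWI -> tensors -> scalars
res = analyze_cohort(subjects, cohort.region_table,
                     ThresholdConfig(), StatsConfig(seed=7))

pv = res["moments"].query("measure == 'percent_volume'")
for cond in ("base", "FA>0.15", "FA>0.2", "FA>0.25"):
    sub = pv[pv["condition"] == cond]
    print(f"{cond:8s} volume {sub['mean'].mean():5.1f} %   CV {sub['cv'].mean():.3f}")
```

prints

```
base     volume 100.0 %   CV 0.000
FA>0.15  volume  83.5 %   CV 0.044
FA>0.2   volume  62.4 %   CV 0.114
FA>0.25  volume  41.2 %   CV 0.225
```

Raising the FA cutoff discards progressively more of each region's
trace-masked base volume (100 % → 41 % on average) while the
coefficient of variation of the retained fraction across the 8 subjects
grows five-fold — higher thresholds select smaller *and* less consistent
regions. The region-wise tests show the same asymmetry the volume numbers
hint at: the high-FA internal-capsule-like region's mean FA barely
responds to the threshold (H = 9.3, p = 0.025, not significant at the
corrected alpha 0.00417), while the lowest-FA corona-radiata-like region
is strongly threshold-dependent (H = 29.1, p ≈ 2e-6).

The same study runs from the shell:

```bash
dtithresh analyze --out results/ --seed 7 --n-subjects 8
dtithresh phantom --out cohort/ --seed 7          # export NIfTI + bvec/bval
dtithresh analyze --scalars maps/ --labels atlas.nii.gz \
    --fa-cutoffs 0.15,0.20,0.25 --trace-cutoff 0.006 --min-voxels 10 \
    --out results/                                 # real-data mode
```

Every run writes `table.csv` (subject × region × condition cells),
`moments.csv` (cohort statistics), `comparisons.csv` (Kruskal–Wallis
results with pairwise adjacent contrasts), a Markdown report, and a
manifest with the seed, the config echo and SHA-256 hashes of every
artifact; identical config + seed reproduces the tables byte for byte.

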