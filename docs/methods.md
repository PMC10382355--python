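# Methods

## Model and procedure

`hrscan` operationalizes two hypotheses about radioresistant tumors:
(1) recurrence originates from a *high-risk subvolume* (HRS) — a subset of
tumor voxels with a distinct biological/physiological signature visible in
quantitative imaging — and (2) a larger HRS translates into higher
radiation resistance. Under these hypotheses, if a region of imaging
parameter space corresponds to the resistant phenotype, then the fraction
of each tumor's voxels falling in that region should increase from
radiosensitive to radioresistant tumors. The pipeline therefore searches
parameter space for the cluster whose per-tumor fractional occupancy best
separates radiosensitivity classes.

### Parameter space

Voxels are points in a 1–5 dimensional space spanned by ADC and the first
two uncentered principal-component projections of dynamic FMISO-PET SUV
curves and DCE-MRI relative-enhancement curves. PCA is *uncentered*
(right singular vectors of the raw voxel×time matrix): uptake and
enhancement curves are non-negative and their overall level carries
signal, so subtracting the temporal mean would discard information. The
basis is computed once over the pooled tumor voxels of the whole analysis
cohort, not per animal — projections must be comparable across tumors for
the cluster search to be meaningful. Muscle voxels do not enter the PCA
training matrix. Component signs are fixed so each component's mean
projection over the cohort is non-negative (the decomposition is otherwise
sign-ambiguous).

Voxels are pooled over tumors and z-normalized per dimension (population
SD; at ~10⁴ voxels the sample/population distinction is negligible). The
normalization constants are part of the fitted model: extended-cohort
evaluation reuses them so that the learned center stays comparable.

### Radiosensitivity classes and cluster size

Classes derive from published TCD50 (dose controlling 50% of tumors)
95% confidence intervals: lines whose closed CIs intersect are merged,
transitively, and the connected components — ordered by mean TCD50 —
are labelled H (most sensitive), M, L. Closed-interval overlap is used
because published CIs are rounded; a touching endpoint should merge.
CAL-33 is excluded by default: its wide reported CI spans two classes,
so no reliable class assignment is possible.

Each class maps to an HRS voxel-fraction prior: 0% (H), 7.5% (M),
15.0% (L). The scanned cluster size is
`N_HRS = round(Σ_t fraction(class(t)) · n_voxels(t))` — the unique size
for which the expected per-class fractions match the priors when the
size hypothesis holds. The rule is also exposed per class
(`class_voxel_budgets`) as integer voxel budgets.

### Scan

`N_it = 5000` candidate centers are drawn uniformly from the pooled
voxels, by default *without* replacement (duplicate centers waste
iterations; a `with_replacement` flag reproduces the literal
random-sampling protocol). For each candidate the `N_HRS` nearest voxels
(Euclidean, center included) form the cluster; per-tumor fractions are
scored by `S = (S_HM + S_ML)/2` with Cohen's d
`S_ij = (μ_j − μ_i)/σ_ij` and the (n−1)-weighted pooled SD. The best
cluster is the score argmax; ties resolve to the earliest iteration, so a
scan is a pure function of (cohort, seed). The fitted model records the
de-normalized center, the per-dimension min–max interval of member
voxels, both pairwise Wilcoxon rank-sum p-values and, as the headline p,
their maximum (the most conservative choice; the bootstrap CI of the
center is computed separately and answers a different question than the
member interval).

Nearest-neighbour queries are exact. A k-d-tree path exists
(`knn_cluster(tree=...)`, contract-identical to the brute-force sort,
ties broken by ascending voxel index), but the scan's default is a
vectorized brute-force pass with precomputed squared norms: with
`N_HRS` in the thousands, large-k tree queries are slower than one
GEMV + argpartition over ~10⁵ voxels.

### Statistical tests

Rank-sum p-values are exact permutation enumerations (two-sided by
symmetric deviation of the Mann–Whitney U from its null mean — under
ties the U null can be asymmetric, and deviation counting is the
convention that remains well defined) when both groups have ≤ 10
observations; otherwise the normal approximation with tie correction is
used. Model comparison across dimensionalities applies the same test to
the two bootstrap score samples.

### Robustness

Bootstrap cohorts resample *animals* (tumors) with replacement, never
voxels — voxel resampling would break within-tumor spatial dependence.
Each of `N_bs = 50` replicates recomputes the z-normalization and
`N_HRS` before rescanning, so the percentile CIs (order statistics, no
interpolation) reflect the full pipeline's variability. Replicates
missing two tumors of any class are redrawn (logged; hard error after
100 attempts). Extended-cohort evaluation freezes the trained
normalization and center and only re-identifies the member set as the
evaluation cohort's nearest voxels to the frozen center, with the size
rescaled by the class-fraction rule on that cohort; evaluating on the
training cohort is a fixed point. A `rescan` is deliberately not
performed — the flag-free frozen-center rule is the minimal reading of
"model verification on an extended cohort".

### Classical features

The baseline comparators are whole-tumor statistics: mean/min/max plus
"peak"/"valley" — the mean over a 7-voxel neighbourhood centred on the
in-mask extremum (the extremum voxel plus its six face-connected in-mask
neighbours, completed at mask borders with the nearest in-mask voxels by
grid distance, ties by row-major index). The 7-voxel region is the
natural 3-D reading (center + 6 face neighbours) of a noise-robust
extremum surrogate. Their stratification uses exactly the same score and
tests as the cluster fractions; a feature decreasing from H to L yields
a negative score by the sign convention of `S_ij`.

## Synthetic cohorts

No public archive exists for the kind of co-registered multi-parametric
animal data this pipeline targets, so validation uses synthetic cohorts
that encode the size hypothesis directly.

Defaults (all overridable via `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| tumors per class | 18 H / 12 M / 12 L | echoes the 42-animal training cohort design |
| voxels per tumor | uniform 500–3000 | small-animal tumor at PET grid resolution |
| background | Gaussian per dim; ADC 1050 ± 230 ×10⁻⁶ mm²/s, FMISO_c1 1.2 ± 0.45, FMISO_c2 0.35 ± 0.18, DCE_c1 0.9 ± 0.4, DCE_c2 0.2 ± 0.12 | bulk-tumor parameter cloud |
| per-tumor jitter | 0.3 × SD | between-animal variation of the background mean |
| niche center | ADC 420, FMISO_c1 2.0, FMISO_c2 0.75 | low-ADC/high-uptake resistant phenotype; DCE dims carry no niche contrast |
| niche SD | ADC 35, FMISO_c1 0.07, FMISO_c2 0.035 | ~0.15 pooled-SD per dim |
| niche fraction | 0.15 L / 0.075 M / 0 H | the size hypothesis, planted exactly (floor(frac·n) voxels) |
| raw-signal noise | 1% (DWI), 2% (PET, DCE) | additive Gaussian relative to each modality's scale |

The niche is deliberately *compact* (~0.15 pooled-SD per separated
dimension): the planted-recovery experiments ask whether the scan
localizes the niche center to within 0.5 z-units, and that question is
only well posed when the niche's own extent is small on that scale —
the best-scoring center is itself a niche voxel and scatters like the
niche spread. Niche voxels are spatially contiguous (nearest lattice
voxels to a random seed voxel inside a digital-ball tumor), so
image-space features remain plausible.

Raw-signal synthesis inverts the extraction model: mono-exponential
diffusion decay; PET curves spanned by two fixed orthonormal temporal
shapes (saturating-exponential accumulation, gamma-variate perfusion) on
the 65-frame protocol grid; DCE enhancement on 150 frames with an
exactly flat 11-frame pre-injection baseline. The planted PET/DCE
coefficients are re-expressed in the cohort's own uncentered principal
basis (an orthogonal 2×2 change of components that leaves every curve
unchanged) before emission, so at zero noise the extraction pipeline
returns exactly the stored per-voxel parameters; the rotation preserves
niche geometry and fractions, and the rotated niche center is reported
as ground truth. Clamping of negative samples applies only to
noise-induced negatives.

**What the generator does not emulate:** anatomically realistic tumor
shapes, partial-volume and registration errors, Poisson PET noise,
arterial-input-function variability, and — most importantly — overlap
between niche and background phenotypes. Real-data stratification scores
are O(1–3); the synthetic niche is cleanly separated, so scores are an
order of magnitude larger. Passing the synthetic suites demonstrates
algorithmic correctness (localization, calibration, determinism), not
clinical-grade performance on real images.

## Numerical choices

* ADC fits: vectorized damped Gauss–Newton on `S0·exp(−b·k)` with
  log-linear initialization and backtracking line search; negative
  fitted ADC clamped to 0 and flagged; non-positive b=0 signals flagged
  NaN and excluded from parameter-space construction (counts logged).
  ADC is carried in 10⁻⁶ mm²/s.
* Distance ties in KNN: ascending global voxel index (stable and
  reproducible); best-score ties: earliest iteration.
* Zero pooled SD in Cohen's d: 0 for equal means, flagged signed
  infinity otherwise; a scan in which no candidate attains a finite
  score raises.
* Percentile CIs use `closest_observation` so the bounds are order
  statistics of the replicate values.
* All seeds feed `numpy.random.default_rng`; per-replicate scan seeds
  are drawn below 2³¹ from the master generator.

## Validation problem sizes

The heavy validation suites run at the following sizes, chosen as a
balance of statistical resolution and desk-scale runtime: planted-niche
recovery uses the full default cohort (42 tumors, ~7×10⁴ voxels) with
`N_it = 5000` over 20 seeds plus 20 matched no-niche cohorts; bootstrap
validation runs one 50-replicate full-pipeline bootstrap on a
13-tumor cohort plus a coverage experiment of 20 independent
10-tumor cohorts with 20 replicates each; noisy ADC recovery uses 10⁴
voxels. The null-calibration check compares the scan's significant-p
rate on exchangeable no-niche cohorts against a label-permutation
reference over 24 replicates.

## Known limitations

* The pipeline assumes co-registered inputs on a common grid;
  registration and reconstruction are upstream.
* Clusters are defined in parameter space only; no spatial-connectivity
  constraint is imposed in image space.
* With a single cell line in class M, "class spread" within M is
  between-animal spread only; Cohen's d remains defined (n ≥ 2 tumors)
  but class-level generalization is limited by design.
* The exact rank-sum enumeration is O(C(n, k)); it is restricted to
  groups of ≤ 10.
* The headline p (max of pairwise tests) is conservative; both pairwise
  values are always reported.
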