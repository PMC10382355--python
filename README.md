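# hrscan

Identification of **high-risk subvolumes (HRS)** — compact voxel clusters in
multi-parametric PET/MRI parameter space whose per-tumor fractional size
stratifies tumors by radiation resistance.

## The problem

Head-and-neck tumors that recur after radiotherapy are thought to harbour
resistant niches: small, biologically distinct subvolumes (hypoxic, highly
cellular) that survive a standard dose. If such niches can be localized on
pre-treatment imaging, dose painting could escalate dose exactly there.
`hrscan` implements a data- and hypothesis-driven pipeline that searches
quantitative imaging parameter space for such niches in a cohort of tumors
with known, cell-line-specific radiosensitivity.

Each tumor voxel is described by up to five quantitative parameters:

* **ADC** — apparent diffusion coefficient from a mono-exponential fit
  `S(b) = S0 · exp(−b · ADC)` over nine b-values (0–800 s/mm²),
* **FMISO_c1, FMISO_c2** — projection coefficients of dynamic
  [18F]-FMISO PET SUV curves (65 frames) onto the first two *uncentered*
  principal components,
* **DCE_c1, DCE_c2** — the same for DCE-MRI relative-enhancement curves
  ΔS = (S_t − S0)/S0 (150 frames, 11 pre-injection baseline frames).

## The method

Tumor voxels of the cohort are pooled and z-normalized per dimension. A
randomized scan repeats, `N_it = 5000` times:

1. pick a voxel as cluster center `X_cluster`;
2. take its `N_HRS` nearest neighbours (Euclidean distance in z-space);
3. compute each tumor's cluster fraction
   `f_cluster(t) = |cluster ∩ voxels(t)| / n_voxels(t)`;
4. score class separation with Cohen's d:
   `S_ij = (μ_j − μ_i) / σ_ij`, σ_ij the pooled SD with (n−1) weights, and
   `S = (S_HM + S_ML) / 2` over radiosensitivity classes H/M/L.

Classes derive from TCD50 95% confidence intervals: cell lines with
overlapping CIs are merged (transitively); the three resulting classes map
to HRS voxel-fraction priors of 0% (H), 7.5% (M) and 15.0% (L), which fix
`N_HRS = round(Σ_t fraction(class(t)) · n_voxels(t))`. The best cluster per
dimensionality is reported with its de-normalized center, per-dimension
member interval, Wilcoxon rank-sum p-values, and bootstrap 95% CIs
(`N_bs = 50` cohorts resampled at the animal level, full pipeline rerun per
replicate). Classical whole-tumor features (SUV_mean/max/peak,
TMR_max/peak, ADC_min/valley/mean/max) provide the baseline comparison.

Because the animal imaging data this methodology was developed on is not
publicly archived, the package ships a first-class synthetic cohort
generator (`hrscan.synthetic`) that plants a resistant niche occupying
15%/7.5%/0% of voxels per class, optionally down to raw diffusion/dynamic
signals so the whole extraction pipeline is exercised end to end.

## Worked example

```python
from hrscan import (ScanConfig, SimulationConfig, simulate_parameter_cohort,
                    scan, bootstrap_scan)

cohort = simulate_parameter_cohort(seed=1)          # 42 tumors, 5-D voxels
dims = ["ADC", "FMISO_c1", "FMISO_c2"]
model = scan(cohort.select(dims), ScanConfig(dims=dims, n_it=5000, seed=7))
print(f"S_HRS = {model.score:.2f}, p = {model.p_value:.2g}, "
      f"N_HRS = {model.n_hrs}, ADC center = {model.center_raw[0]:.0f}")
```

prints (numbers from this exact invocation):

```
S_HRS = 182.92, p = 3.7e-05, N_HRS = 4212, ADC center = 477
```

The score is huge compared to real-data values (the synthetic niche is
cleanly separated by construction); the recovered ADC center of
477 × 10⁻⁶ mm²/s lies inside the planted niche (centered at 420 with
SD 35, i.e. well within 0.5 z-units of it in the joint 3-D space), and
p is the conservative maximum of the H–M and M–L rank-sum tests. `bootstrap_scan`
adds percentile CIs; `HRSScanner` exposes the same scan as a
scikit-learn-style estimator with `fit`/`transform`.

The same workflow is available from the shell:

```bash
hrscan simulate --out synth/ --seed 1 --raw
hrscan scan --maps synth/ --cohort synth/cohort.csv \
       --dims ADC,FMISO_c1,FMISO_c2 --n-it 5000 --seed 7 --out model.json
hrscan bootstrap --maps synth/ --cohort synth/cohort.csv --n-bs 50 \
       --seed 7 --out boot.json
hrscan classical --maps synth/ --cohort synth/cohort.csv --out features.csv
```

## Documentation

`docs/methods.md` describes the model, its assumptions, all tunable
parameters with defaults and units, what the synthetic generator does and
does not emulate, and the package's numerical choices and limitations.
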