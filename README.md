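# delfitf

Mutation- and tumor-independent estimation of circulating tumor fraction
from low-coverage whole-genome cfDNA sequencing.

## The problem

Monitoring cancer treatment through plasma usually requires knowing a
tumor-specific mutation in advance (ddPCR, targeted panels). But tumor-derived
cfDNA also differs *globally* from healthy cfDNA: its fragments are shorter,
their genome-wide coverage reflects tumor copy-number changes, and their
positional pattern mirrors tumor chromatin. `delfitf` turns those fragmentome
signals into a single quantitative score — a predicted mutant allele frequency
(MAF, in percent) — without needing any prior tumor genotyping. It is aimed at
computational genomics groups working on liquid-biopsy treatment monitoring.

## The method

Per sample, deduplicated fragment intervals (BED, hg19 autosomes) are reduced
to a 16-dimensional feature vector:

1. **Fragmentation profile.** Fragments are assigned by midpoint to 26,236
   non-overlapping 100-kb bins (504 five-Mb groups of 50 contiguous bins;
   regions of low mappability, centromeres and telomeres excluded). Counts of
   short (100–150 bp) and long (151–220 bp) fragments are GC-corrected per
   sample by loess residualisation (span 0.75, 2 robustness iterations):
   `corrected = raw − smooth(GC) + median(raw)`. The per-group ratio
   `s(g)/l(g)` forms a 504-point profile; its top two principal components
   (PCA refit inside every cross-validation fold) are features `pc1, pc2`.
2. **Arm-level aneuploidy.** For each of the 39 scoreable autosome arms the
   fraction of corrected counts is standardised against a non-cancer reference
   panel, `z_a = (f_a − μ_a)/σ_a`. The two largest |z| are features. The
   plasma-aneuploidy score takes each chromosome's max-|z| arm, keeps the top
   five chromosomes, maps |z| to two-sided p-values under a t distribution with
   3 df, and sums `−ln p` (PA-score).
3. **Fragment-length mixture.** A 12-component normal mixture (35 free
   parameters) is fitted once by EM to pooled panel fragment lengths
   (50–400 bp); per sample, only the component weights are re-estimated
   (a convex EM), and the first 11 mean-sorted weights are features.

A random-forest regressor (1000 trees, a third of the features per split,
minimum leaf 2) maps the features to the ddPCR MAF of a known driver variant.
The score — **DELFI-TF** — is the out-of-fold prediction from
leave-one-patient-out cross-validation, so no patient's labels ever influence
their own score; a locked model can also be applied to unlabeled cohorts.
For longitudinal monitoring, the **DELFI-TF slope** is the least-squares slope
of a patient's scores (percentage points/day) against days since the first
post-treatment draw, within defined progression windows, dichotomised at the
cohort median.

Because the cohorts the method was developed on are controlled-access, the
package ships a synthetic-cohort simulator with known ground-truth tumor
fractions (see `docs/methods.md`) so that the whole pipeline is verifiable.

## Worked example

```python
import numpy as np
import delfitf as d

tiling = d.mini_tiling(n_chroms=6)          # small synthetic tiling for the demo
config = d.SimulationConfig(seed=7, n_patients=10, draws_per_patient=4,
                            coverage=500_000, n_panel=20, n_altered_arms=4)
cohort = d.simulate_cohort(config, tiling)
panel = d.build_healthy_panel(cohort.panel_counts, tiling)
features, profiles = d.featurize_cohort(cohort.feature_inputs(), tiling, panel)
scores = d.lopo_cv(features, profiles, panel, seed=7)

detectable = features["detectable"].to_numpy(bool)
r = np.corrcoef(scores["delfi_tf"][detectable],
                features["maf_label"][detectable])[0, 1]
print(scores.head(4).round(2).to_string(index=False))
print(f"Pearson r (DELFI-TF vs ddPCR MAF, detectable): {r:.3f}")
```

prints

```
sample_id patient_id fold  delfi_tf
  P000_T0       P000 P000     27.19
  P000_T1       P000 P000      1.50
  P000_T2       P000 P000      3.60
  P000_T3       P000 P000     17.53
Pearson r (DELFI-TF vs ddPCR MAF, detectable): 0.962
```

Patient `P000` shows the canonical treatment arc: a high baseline score
(27.2%), a sharp drop after therapy starts (1.5%), then regrowth toward
progression (17.5%). Out-of-fold scores track the simulated ddPCR labels with
r = 0.96 even on this deliberately small cohort. Continuing with the slope
statistic:

```python
slopes = d.slope_table(
    scores.merge(features[["sample_id", "date"]], on="sample_id"),
    cohort.clinical, analysis="PFS")
print(slopes[slopes.eligible].round(4).head(3).to_string(index=False))
```

```
patient_id analysis   slope  n_points  eligible above_median reason
      P000      PFS  0.1432         3      True         True
      P001      PFS -0.0004         3      True        False
      P002      PFS  0.2311         3      True         True
```

Positive slopes (score rising after treatment start) flag patients heading to
progression; the `above_median` dichotomy is the grouping used for survival
comparisons.

The same pipeline is available from the shell:

```bash
delfitf simulate --mini --seed 7 --out-dir cohort/
delfitf build-panel --mini --cohort-dir cohort/ --out panel.json
delfitf featurize --mini --panel panel.json --cohort-dir cohort/ --out-prefix cohort
delfitf cv --features cohort.features.tsv --profiles cohort.profiles.tsv \
           --panel panel.json --seed 7 --out scores.tsv
```

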