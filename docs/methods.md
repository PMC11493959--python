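# Methods notes

This note records how the estimator is defined, the choices made where the
design was genuinely open, and what the synthetic cohort does and does not
establish.

## Coordinate system

All genomic coordinates are 0-based, half-open (BED convention). The
canonical hg19 tiling is constructed deterministically at run time from
packaged constants (autosome lengths, centromere gaps, a 10-kb telomere pad
at each chromosome end): 26,236 adjacent 100-kb bins arranged into 504
five-Mb groups of 50 contiguous single-arm bins over the 39 scoreable arms
(the acrocentric short arms 13p, 14p, 15p, 21p and 22p are heterochromatic
rDNA and never tiled). Bins-per-arm are apportioned by largest remainder of
each arm's capacity so the totals hold exactly; the exclusion list exported
by `hg19_exclusions()` is the complement of the tiled bins (~257 Mb of gaps,
arm-end padding and untiled remainders). Note the "arms with 5-Mb groups"
construction fixes an interpretation: each 5-Mb group is exactly 50
contiguous 100-kb bins on one arm, and leftover bins that cannot complete a
group belong to no group.

Per-bin GC fractions are a deterministic *synthetic* track (a smooth
isochore-like positional wave plus fixed-seed bin noise, clipped to
[0.30, 0.62]); computing real GC from a genome FASTA is out of scope, and
the GC-correction machinery only needs a plausible covariate. Analyses of
real data should substitute a measured GC track via the `gc_source`
argument or the tiling file.

## Fragment reduction

A fragment contributes to the unique bin containing its midpoint
`floor((start+end)/2)` — an explicit convention for boundary-straddling
fragments. Length classes are inclusive: short 100–150 bp, long 151–220 bp;
lengths in [50, 400] bp of bin-assigned fragments are retained (as an
integer-bp histogram) for mixture modelling. The 50–400 window is a fixed
choice covering mono- and di-nucleosomal cfDNA while excluding adapter
artefacts and very long genomic contamination. Input BEDs are assumed
aligned and deduplicated upstream (e.g.
`samtools sort -n in.bam | bedtools bamtobed -bedpe | cut -f1,2,6 > frags.bed`).

## GC correction

Counts (short and long separately) are residualised against GC with a
locally weighted regression (span 0.75, 2 robustness iterations, `delta` =
1% of the GC range for speed): `corrected = raw − fitted + median(raw)`,
floored at 0. A constant GC vector degenerates to subtracting the mean;
all-zero counts pass through unchanged. The correction is additive around
the per-sample median, so rescaling all counts rescales the profile
ratios' numerator and denominator together and the short/long profile is
scale-invariant.

## Features

* **Profile (504 values).** Group ratio = Σshort/Σlong of corrected counts
  over the group's 50 bins. A zero long-count group is missing (imputed
  from the panel median); a sample with >5% missing groups is rejected.
* **Arm z-scores (39).** Arm count fraction standardised by panel mean/sd
  (sd across ≥20 non-cancer samples, ddof=1). Ties in |z| break by arm
  label order.
* **PA-score.** Per chromosome take the max-|z| arm, rank chromosomes,
  keep 5, convert by two-sided p under t(3) — the heavy-tailed reference
  keeps single extreme arms from saturating the score — floored at 1e-300
  to avoid log(0), and sum −ln p. Two-sidedness makes PA = 0 exactly when
  all z = 0. Requires ≥5 chromosomes; the 2-chromosome mini tiling cannot
  produce a PA-score by construction (use `mini_tiling(n_chroms>=5)`).
* **Length mixture (11 weights).** A 12-component normal mixture is fitted
  once to pooled panel lengths by EM on the integer-bp histogram
  (convergence: relative log-likelihood change < 1e-6, max 500 iterations;
  sd floor 0.5 bp). Two deterministic initialisations are tried — means
  evenly spaced over [50, 400] and means at evenly spaced data quantiles —
  and components that collapse onto one another are merged and restarted
  where the data most exceed the model; the best-likelihood fit wins. This
  rescue step matters: a single even-spacing start can stall in local
  optima (verified against simulated ground truth), and a point-mass input
  would otherwise split its weight across duplicate components. Per
  sample, weights are re-estimated with components frozen (convex; stop
  when the weight vector moves < 1e-10). Freezing the components is what
  makes the per-sample weights comparable across samples. Features are the
  first 11 mean-sorted weights; the 12th is determined by the simplex
  constraint, and dropping the largest-mean (least tumor-informative)
  component is this package's convention.

## Model

Random-forest regression (scikit-learn), defaults: 1000 trees, 1/3 of
features per split, min leaf 2, fixed seed, single-threaded — all
overridable. Profile PCA (column-centered, unscaled, top-2 right singular
vectors, sign fixed by largest-|loading| entry) is refit inside every
cross-validation fold to avoid leaking held-out profiles into the feature
basis; panel statistics and mixture components come from non-cancer
samples outside the labeled cohort and are never refit. Undetectable-ddPCR
samples train with label 0 by default (`include_undetectable=False` drops
them). Predictions are clipped to [0, 100]%. Training rows are
canonically ordered (stable sort by sample id) before fitting so the fit
depends on fold membership, not sample arrival order — bootstrap draws in
forests are positional. Grouped importances are impurity-based (the
forest's native attribute), summed over {PA + two z features}, {11
weights}, {2 PCs}.

## Longitudinal slope

Days are whole-day differences of ISO dates. T1 is the earliest draw
strictly after the recorded treatment start. PFS analysis includes draws
in [T1, progression]; OS in [T1, progression + 60 d]. Eligibility: ≥3
draws before progression (all post-T1 draws count, T1 included) and ≥1
draw within 120 d before progression (PFS) or 120 d before to 60 d after
(OS). The slope is the OLS coefficient in percentage points per day;
fewer than two included points leaves it undefined. Dichotomy at the
median of eligible slopes; a slope exactly at the median is "below"
(deterministic and conservative — below-median is the favourable group).

## Synthetic cohort

The simulator generates bin-level counts, not reads: the method consumes
only bin counts and length histograms, and this keeps the cost independent
of sequencing depth (fragment-level BED emission exists for I/O tests).
Two archetypes are mixed per sample at the true tumor fraction θ:

* healthy — smooth per-group ratio baseline; lengths
  0.80·N(167,10) + 0.15·N(320,30) + 0.05·N(480,40);
* tumor — phase-shifted ratio curve, per-patient arm copy events
  (multiplicative 2^±u on `n_altered_arms` arms, u ~ U(0.2, 1.0), fixed
  across a patient's draws); lengths
  0.40·N(145,12) + 0.45·N(167,10) + 0.15·N(320,30).

Counts are Poisson around the θ-mixed rates with per-sample lognormal
jitter at the arm (sd 0.01) and 5-Mb-group (sd 0.01) level — emulating the
biological/technical variance that dominates panel spread in real cohorts —
plus a per-sample ±1.5 bp shift of the length modes. Labels are ddPCR-like:
mutant droplets ~ Binomial(10,000, θ·s) with per-patient clonality
s ~ Beta(50, 2.5), reported as percent and zeroed below 10 droplets
(detection floor ≈ 0.1% MAF, spanning the 0.1–40% dynamic range the score
is meant to cover). Trajectories decay exponentially from baseline
(θ0 ~ U(0.005, 0.45); rate 0.06/day × U(0.5, 1.5)) to a nadir at
U(40, 110) days, then regrow at 0.02/day × U(0.5, 1.5), capped at 0.5;
draws default to every 56 days × 4, progression at U(150, 215) days, and
15% of patients never progress. Default coverage is 8,000,000 fragments
per sample: count simulation cost is coverage-independent, and at this
depth panel variance is dominated by the biological jitter term rather
than Poisson noise, as in real data. All randomness descends from one
mandatory seed through spawned generator sub-streams (per panel sample,
per patient), so cohorts are bit-reproducible.

What the simulator does **not** emulate: mappability/sequencing-error
structure, GC bias coupled to a real genome, sub-clonal copy-number
heterogeneity, batch effects, or the empirical clinical distributions of
any real cohort. Passing tests therefore demonstrate that the pipeline
recovers known signal under this generative model — internal validity —
not clinical performance on patient data.

## maxMAF

For targeted-panel validation cohorts: a variant is a somatic hotspot when
its exact nucleotide change recurs in ≥20 catalogued cancer cases
(recurrence counts are an input column; no live catalogue lookups);
non-hotspots with MAF > 40% are putative germline; both are filtered and
maxMAF is the maximum over surviving hotspots (undefined, flagged, when
none survive). Hotspots above 40% MAF are retained — the germline rule is
defined only for non-hotspots — but flagged for review.

## Known limitations

* The hg19 GC track is synthetic; arm boundaries and gap coordinates are
  the standard annotations, but the exclusion list beyond gaps is chosen
  to satisfy the bin/group counts, not a mappability screen.
* The per-sample weight re-fit treats the truncated [50, 400] window as
  the full support of the mixture; components with substantial mass
  outside the window (the di/tri-nucleosomal tails) absorb truncation
  bias consistently across samples, which is harmless for features but
  makes the weights biased as density estimates.
* The forest cannot extrapolate beyond the training label range; scores
  saturate near the maximum MAF seen in training.
* Slope analysis assumes exact calendar dates and a recorded progression
  date; interval-censored progression is not modelled, and survival
  estimation itself (Kaplan–Meier/Cox) is deliberately out of scope.
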