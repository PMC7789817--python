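# Methods

This note records the models, statistics and numerical choices behind
`episig`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Value scales

Methylation is carried on two scales. The **beta value**
β = M/(M + U + offset) (methylated and unmethylated intensities M, U;
offset default 100, the array convention — setting it to 0 gives the
plain intensity ratio) is bounded in [0, 1] and is used for effect sizes,
visualization and classification features. The **M value**
log2(β/(1−β)) is unbounded and closer to homoscedastic, and is the
regression scale. Betas are clipped to [1e-6, 1−1e-6] before the logit
so M values stay finite; the transform pair is an exact identity inside
the clip bounds.

## QC rules

* Probe filtering removes, with one primary reason each: sex-chromosome
  probes, SNP-overlapping probes, cross-reactive probes, and probes with
  detection p > 0.01 in *any* retained sample (the conservative "any"
  rule keeps the probe set identical across samples). The filter is
  idempotent.
* Samples are excluded when strictly more than 5% of probes fail
  detection (a sample at exactly 5% is retained).
* Sex is predicted from median log2 total intensity on chrY minus chrX;
  the decision threshold is −2 (males, with single copies of both, sit
  near 0; females have Y probes at background, near −4). Predicted sex
  discordant with the sample sheet flags the sample.
* The genome-wide beta density must be bimodal: the fraction of betas in
  (0.3, 0.7) must stay below 0.35. This mid-range-mass statistic was
  chosen over a formal dip test for transparency — it needs no critical
  tables and its failure mode is easy to inspect.
* Matched controls: greedy nearest-age matching within exact (sex,
  batch) strata (falling back to sex-only, then to the whole pool, when
  a stratum is too small), 4 controls per case without replacement; ties
  in age distance break by pool order for determinism. After each
  matching pass a PCA over the matched set flags samples beyond 3 SD on
  PC1 or PC2; flagged controls are banned and matching repeats, up to 10
  iterations.

## Cell-type deconvolution

Blood composition is a confounder for any blood epi-signature, so each
sample's proportions over six leukocyte types are estimated by
constrained least squares of its betas (at the reference's
discriminating probes) on the reference profiles: minimise
‖Rᵀw − β‖² subject to w ≥ 0 and Σw ≤ 1 (SLSQP on the quadratic
objective; the feasible set is the simplex with slack, so remainder mass
is allowed). A rank-deficient reference is rejected. The estimated
proportions enter the differential design matrix with one cell type
dropped (the proportions nearly sum to one and would be collinear with
the intercept).

## Differential methylation

Per-probe ordinary least squares of M values on
[intercept, case indicator, covariates] is computed for all probes in
one matrix product (identical residual df everywhere). Residual
variances are shrunk with the standard empirical-Bayes scaled
inverse-chi-square prior fitted by method of moments on log s²: with
e = log s² − ψ(d/2) + log(d/2), the prior df solve
ψ′(d₀/2) = var(e) − ψ′(d/2) by Newton iteration and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Posterior variances are
s̃² = (d₀s₀² + d·s²)/(d₀ + d) and moderated t uses d₀ + d degrees of
freedom. Degenerate case: when the variances carry no excess spread the
prior df are infinite and the posterior is taken as the common observed
variance, so moderated and ordinary t coincide exactly.

Two-sided p-values are BH-corrected (single shared implementation, used
by every module). Signature probes require both |Δβ| > 0.10 (computed on
the beta scale, group mean difference) and q < 0.01, both strict
inequalities; the effect-size guard exists to drop probes whose
statistical significance comes from tiny variances rather than a usable
methylation difference.

## DMR calling

Moderated t statistics are kernel-smoothed per chromosome with Gaussian
weights w_ij = exp(−(p_i−p_j)²/2σ²), σ = λ/C with λ = 1000 bp and C = 2
(the bandwidth that matches the 1 kb chaining rule); the smoothed
statistic z_i = Σw_ij t_j / √(Σw_ij²) is standard normal under the null.
The computation is exact (dense, row-chunked), so an isolated probe
keeps z = t. Probes significant after BH on the smoothed p (q < 0.05)
chain into regions while consecutive candidates are ≤ 1 kb apart;
regions need ≥ 3 probes and |mean regional Δβ| > 0.10. The regional
statistic is a **signed Stouffer** combination over member probes,
z_region = Σ Φ⁻¹(1 − q_i/2)·sign(t_i)/√n, whose two-sided normal p is
BH-corrected across regions and thresholded at FDR < 0.01. The signed
(rather than squared) combination was chosen so that a region of
incoherent directions cannot reach significance. Region bounds are
reported at the first/last member-probe positions, 1-based inclusive in
memory and 0-based half-open in BED output.

## MVP classifier

Feature probes are those (within an optional shared-platform mask) with
|mean(case) − mean(control)| ≥ 0.10 on betas. A linear SVM is trained
one-vs-rest per class; the cost C is picked from {0.01, 0.1, 1, 10} by
stratified 10-fold cross-validated accuracy with ties broken toward the
smaller (more regularized) C. Scores come from Platt sigmoids
P = 1/(1 + exp(A·f + B)) fitted by regularized maximum likelihood on
*cross-validated* decision values (resubstitution decision values would
make the sigmoid overconfident). One-vs-rest with per-class sigmoids is
this package's multiclass definition; the predicted phenotype is the
argmax class, and a score above 0.5 for the syndrome class is emitted as
a flag rather than enforced as a hard rule. Samples missing up to 10% of
feature probes are imputed with training means (with a warning); more
missingness is an error.

Validation harnesses: leave-2-out enumerates all C(11,2) = 55 held-out
case pairs, re-selects features on the 9 remaining cases per fold,
embeds everything by classical (Torgerson) MDS on Euclidean distances
and assigns held-out samples to the nearer group centroid; Ward
clustering and MDS are also exposed directly. Classical MDS is exact for
data of intrinsic rank ≤ k and deterministic up to sign (fixed by a
largest-coordinate convention).

## CNV from intensities

Total intensities (meth + unmeth) over query and control samples are
quantile normalized (columns mapped onto the cross-column mean of sorted
values; ties receive the average target at their tied ranks), divided by
per-probe control medians and log10 transformed. Each sample's track is
median-filter smoothed (window 5) and recursively segmented with a
circular-binary-segmentation statistic: the maximal standardized
|mean(arc) − mean(rest)| over contiguous arcs, scanned on a geometric
grid of arc widths (ratio 1.2 — the grid makes the permutation null
tractable and is part of the statistic's definition, applied identically
to observed and permuted data). The null re-shuffles the raw segment
values and re-applies the median filter each time, so the filter-induced
autocorrelation cannot inflate the test; a split is accepted at
permutation p < 0.01 (10,000 permutations by default; desk-scale runs in
this repository use 500 with the same alpha). Breakpoints are then
locally refined (±3 probes) against the raw values to undo the filter's
edge smear. Neighbouring segments with mean difference < 0.05 are joined
(probe-count-weighted, iterated to a fixed point).

Deletions are segments at mean log10 ratio ≤ −0.1 with ≥ 5 probes; the
−0.1 threshold stands in for the published "visual comparison" and sits
above the theoretical heterozygous signal (log10 0.5 ≈ −0.30) to
tolerate array compression. Symmetrically to the minimum-size rule, an
interruption shorter than 5 probes between two qualifying deletion
segments is absorbed into one call. A 20% mosaic loss (mean copy number
1.8, expected ratio −0.046) sits above the threshold and is deliberately
not callable at defaults.

**Critical region.** The epi-signature critical region is the
intersection of all signature-positive deletion intervals minus the
union of the signature-negative ones, on closed 1-based intervals where
touching endpoints count as overlap. Boundary convention: a region
trimmed by a deletion starting at coordinate c is reported as ending at
c itself (the breakpoint probe), which is how the cohort's published
coordinates are expressed; with the packaged 16-interval table this
yields chr22:49,238,268-50,248,907 exactly. Interval lengths in Mb are
(end − start)/10⁶ rounded half-up, matching the published table's
printed values.

## Metabolomics

The plate model covers Biolog PM-M1..M4 (energy sources) and PM-M5..M8
(metabolic effectors), 96 wells each, plus the 8 analyzed tryptophan-
plate contents — 776 analyzed wells per cell line; kinetic series are 96
points at 15-minute intervals over 24 h. Endpoint relative absorbance
(A590 − A750) is normalized by subtracting the mean of the triplicate
blank-plate readings, floored at 1e-3 (guaranteeing finite logs) and
log10 transformed. The endpoint is the tested quantity; slope (least
squares, OD/hour), endpoint and trapezoidal AUC are computed for every
kinetic series and reported. Wells are compared case vs control with a
two-sided Mann-Whitney test — exact enumeration for combined n ≤ 12
without ties, normal approximation with tie and continuity correction
otherwise — and BH-corrected across all analyzed wells; summaries count
significant wells by direction, plate and the PM-M6..M8 block (288
wells).

## Synthetic-data generator

The generator is the package's test bed and defines its study
conditions. Defaults mirror the modelled study: 11 cases vs a 4x control
panel, 20,000 probes over three chromosomes, 1,000 signature probes at a
planted Δβ of 0.15 with 80% hypermethylated; plate runs use 11 case vs
50 control lines.

* Each sample's baseline beta profile is a Dirichlet-weighted mixture of
  six cell-type reference profiles (concentration 60 around realistic
  blood means, neutrophil-dominated); 600 discriminating probes carry
  strong between-type contrast (≈0.9 in the owning type vs ≈0.1
  elsewhere) so deconvolution has signal. A `case_cell_shift` option
  moves the case Dirichlet mass toward the dominant type to build
  composition-confounded nulls (the shift of 0.5 used in the harness
  moves the mean dominant proportion from ≈0.55 to ≈0.70).
* Signal probes get mid-range, cell-type-invariant baselines
  (hyper: U(0.25, 0.45); hypo: U(0.55, 0.75)) so the planted contrast
  survives the (0,1) bounds; a Δβ that would leave (0,1) raises.
* Noise is Gaussian on the M scale with per-probe sd
  noise_sd/(ln2·μ(1−μ)) capped at 8·noise_sd, calibrating the beta-scale
  spread to noise_sd (default 0.05) mid-range while keeping
  extreme-methylation probes tight, as on real arrays.
* Intensities satisfy β = M/(M+U+offset) exactly; totals are lognormal
  around 10,000 with a wide per-probe brightness factor (lognormal,
  σ = 0.5) reproducing real probe-to-probe spread — quantile-normalized
  CNV detection depends on that spread. Males halve X and Y totals;
  females have Y at 5% background.
* Planted deletions multiply both intensity channels inside the interval
  by a factor (0.5 = heterozygous, 0.9 = 20% mosaic) with optional
  multiplicative lognormal measurement noise; betas are untouched, since
  copy number scales total signal, not the methylated fraction.
* Plate kinetics are scaled logistics in time (amplitude per well fixed
  across lines, per-line lognormal variation, additive Gaussian noise);
  affected wells in case lines lose `effect_size` OD of amplitude.
  Blanks are media-only baselines in triplicate.

What the generator does **not** emulate: probe-type (I/II) chemistry and
dye bias, background correction, array batch effects beyond a batch
label, SNP-driven outlier betas, LD-like correlation between nearby
probes' noise, or real compound-specific plate kinetics. Passing
recovery tests therefore demonstrate the pipeline's correctness under
its stated statistical model, not performance on raw IDAT-level
artefacts, which are out of scope (normalized matrices are the expected
input).

## Problem sizes and determinism

Tests and the acceptance script run the differential recovery at the
full 20,000-probe / 11-vs-44 design, the classifier harness at 5,000
probes with three 300-probe disjoint signatures, CNV at 12,000 probes
over two chromosomes with 500 permutations, and the metabolome null at
the full 776-well panel — sizes chosen to keep a complete run at a few
minutes on one CPU while leaving every threshold at its analysis
default. Every stochastic step takes an explicit seed; generators are
pure functions of their seeds, and the acceptance script derives all of
its sub-seeds from the single `--seed` argument.

## Known limitations

* The regional Stouffer definition and the DMR kernel scaling are stated
  choices; other kernel-smoothing region callers differ in both and will
  not match region-for-region on real data.
* The CNV permutation test assumes exchangeable probe noise within a
  segment; wave artefacts or GC trends on real arrays would need an
  additional correction layer.
* The Platt sigmoid is fitted per class one-vs-rest; pairwise-coupled
  multiclass probabilities (as in some SVM libraries) will differ
  slightly in multi-syndrome settings.
* Greedy age matching is order-dependent by design (deterministic); an
  optimal-assignment matcher would trade determinism for slightly better
  aggregate age balance.
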