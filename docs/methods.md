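# Methods

## Analysis model

The unit of analysis is the metagenomic species pangenome (MSP): a
cluster of co-abundant genes from one microbial species. Gene counts are
depth-standardized by rarefaction — exact multivariate-hypergeometric
subsampling per sample, i.e. a uniform draw of mapped reads without
replacement — and converted to frequencies FPKM-style (divide by gene
length in bp, rescale the sample to sum 1). Because the final rescaling
makes the transform invariant to the per-sample total, the order of the
two normalizations is immaterial; we divide by length first. Genes with
zero counts everywhere are retained so catalogue joins never change
dimension.

MSP abundance is the arithmetic mean frequency of the MSP's
best-ranked core genes, capped at 50 (`min(50, |signature|)` when a
synthetic catalogue has fewer). Richness counts MSP with abundance
strictly above 0; rarefaction upstream makes a nonzero detection cutoff
unnecessary, but the threshold is an argument. Taxonomy is a
strict-majority vote: species level if one reference species accounts
for more than half of *all* member genes (no-hit genes stay in the
denominator — the conservative reading) at ≥95 % identity and ≥90 %
gene-length coverage; otherwise the deepest rank from genus up to
superkingdom with a strict gene majority; exact 50/50 ties assign
nothing at that rank. Taxon aggregation sums member-MSP abundances and
pools unannotated MSP under "unclassified", so per-sample totals are
conserved identically.

Engraftment of a mouse is its Spearman correlation (Pearson on
midranks) to each fresh-transplant control mouse at the same day, over
a fixed MSP universe: every MSP detected in at least one sample of the
dataset, zeros retained. A dataset-wide universe keeps all pairs on one
dimension; per-pair double-zero removal would make correlations
incomparable across pairs. The ANOVA response is the per-mouse mean of
the correlations to the control group (one value per subject per day,
as a repeated-measures model needs); raw correlation means are
reported, no Fisher z-transform.

## Mixed ANOVA

The response table is a balanced split-plot design: diluent (3) × week
(2) between subjects, day (3) within, n = 4 mice per cell. Sums of
squares follow the classical decomposition; subjects within cells are
the error stratum for between effects, subject × day within cells for
within effects. Control mice are excluded — they define the response,
not a diluent level. Generalized eta squared uses the Olejnik–Algina
form with all factors manipulated: ges = SS_effect / (SS_effect +
SS_err_between + SS_err_within). Effects are Bonferroni-adjusted over
the family of 7.

Sphericity of the day covariance (pooled within cells, df = subjects −
cells) is tested with Mauchly's W, using Box's chi-square approximation
with the second-order correction term. When Mauchly rejects at α = 0.05
(and k > 2), the four day-involving effects' p-values are recomputed on
Greenhouse–Geisser shrunken degrees of freedom; ε comes from the
double-centered pooled covariance, clamped to [1/(k−1), 1], and equals
1 exactly for k = 2. Both corrected and uncorrected p-values are kept
in the effect table. Note the correction is guaranteed conservative
only for F ≥ 1; for F < 1 shrinking both dfs can lower p slightly,
which never affects a conclusion.

Assumption checks mirror common practice: Brown–Forsythe
(median-centered) Levene at each day, Box's M over the six cell
covariances, boxplot-rule extreme-outlier flags (3 × IQR) per cell.
Simple main effects are one-way F tests of diluent within each day ×
week stratum, Bonferroni over the strata family; post-hoc pairwise
comparisons are pooled-variance two-sample t-tests, Bonferroni over
comparisons × strata (the family choices are documented here because
the convention is genuinely open; per-family-of-strata was chosen).

## Differential screen

Each experimental group's 12 samples (4 mice × 3 days pooled — mice are
the independent units but days are pooled deliberately, accepting the
within-mouse pseudo-replication of the "all time samples" comparison)
are tested against the 12 control samples per MSP with a two-sided
Wilcoxon rank-sum test. With both sides ≤ 12 the p-value is exact: the
permutation distribution of the midrank sum is enumerated by a
subset-sum dynamic program, which handles ties without approximation
(complete separation at 12 vs 12 gives p = 2/C(24,12) ≈ 7.4e−7). Larger
samples use the normal approximation with tie-corrected variance and a
0.5 continuity correction. The tested universe is MSP detected in the
two groups or in the donor inoculum. Fold change is log2 of mean ratios
with a scale-adaptive pseudocount δ = half the smallest nonzero
abundance of the compared sub-table, so extinctions give finite
log2FC; the base is configurable. q-values are Benjamini–Hochberg
step-up within one comparison's MSP family; classes are extinguishing
(q < 0.05, log2FC ≤ −2) and proliferating (q < 0.05, log2FC ≥ +2). The
impacted fraction is the percentage of tested MSP in either class.

## Synthetic study generator

The generator emulates a gnotobiotic-colonization experiment: one donor
inoculum, 7 groups (fresh-NaCl control plus {NaCl, MD, TR} × {W1, W7}),
4 mice per group, days D2/D4/D15.

**Community.** A default catalogue of 400 MSP over 15 gut families
(91 *Lachnospiraceae*, 60 *Ruminococcaceae*, 45 *Bacteroidaceae*, 25
*Enterobacteriaceae*, …), 60–200 genes per MSP, gene lengths log-normal
(μ = 6.8, σ = 0.4; median ≈ 900 bp), signatures = the first 50 genes.
Donor MSP abundances are log-normal (σ = 1.5, a realistic gut
heavy-tail) normalized to sum 1; every member gene carries its MSP's
abundance (shared coverage) times a small per-gene jitter (σ = 0.1).

**Mice.** Per mouse and MSP, multiplicative log-normal effects drawn
once per mouse (σ = 0.30) persist across days, giving the
within-subject correlation a repeated-measures model needs; day drift
(σ = 0.15) is redrawn per sample. A phylum-level humanization shift
(Firmicutes ×0.4, Actinobacteria ×0.3, Bacteroidetes ×2.5,
Proteobacteria ×2.0) applies to every mouse group including the
controls — mirroring the standard humanized-mouse outcome — never to
the inoculum. Reads are multinomial over genes with probability ∝
abundance × gene length, total exactly `read_depth`; column sums are
conserved by construction. Randomness is keyed hierarchically: the
master seed plus CRC-labelled (group, mouse, day) streams, so any
subset of mice regenerates identically regardless of iteration order.

**Degradation.** A scenario's θ ∈ [0, 1] scales three channels:
per-MSP extinction probability θ·extinction_base (×family_bias, default
3, for *Lachnospiraceae*/*Ruminococcaceae*, clipped to 1), log-scale
abundance noise θ·σ_noise (default σ_noise = 1.2), and bloom folds
fold^θ. Extinctions are drawn per mouse by default; the
`consistent_extinctions` mode instead plants one extinct set per group
with its size fixed at the expected count — the configuration used for
planted-truth recovery, where effects must be consistent across mice.
Bloomer selectors accept explicit MSP ids, `family:<name>`,
`random:<k>`, and `rare:<k>` (sampled below the median donor
abundance). Large planted blooms use `rare:` because blooming a
dominant MSP redistributes so much relative abundance that every other
MSP appears depleted — a closure artifact, not a detection. The fresh
control keeps θ = 0.05 (mild remodeling only).

**Calibration.** `calibrate_engraftment` bisects θ against the target
mean experimental-to-control correlation. The objective simulates a
control + one-group study with fixed per-iterate seeds (two replicate
studies averaged, to shrink the Monte Carlo error of the objective
below the 0.01 tolerance) and measures through the full pipeline,
including rarefaction. The response is monotone non-increasing in θ
(tested on a replicated grid), so bisection converges in ~7 iterations.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run at desk scale
chosen as this package's own study conditions: 400 MSP, 200 k reads per
sample, rarefaction to 150 k for calibrated-recovery checks; 100 MSP /
60 k reads for the 100-replicate ordering check; response tables drawn
directly from iid noise for the 500-replicate null-calibration check.
Rarefaction column sums are exact, FPKM columns sum to 1 within 1e−9,
aggregation conserves totals within 1e−12. BH restores input order
after the step-up pass; all-equal p-values stay equal. Degenerate
inputs raise explicit errors rather than returning NaN: constant
vectors in Spearman, zero pooled variance in post-hocs, samples below
rarefaction depth (named), signature genes missing from the frequency
table (listed).

## What the generator does not emulate

No read-level error model, FASTQ, or mapping ambiguity (the pipeline
starts at gene counts); no strain-level variation within an MSP; no
compositional interaction between diluent chemistry and specific taxa
beyond the family-bias channel; day drift is exchangeable rather than
autocorrelated, so engraftment kinetics (day-ordered trends) are not
modeled. Passing recovery tests therefore demonstrates that the
pipeline measures what it claims under a realistic abundance and
sampling model — not that real frozen transplants behave like the
simulator.
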