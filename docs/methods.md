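# Methods

`pigbiome` implements the longitudinal 16S rRNA-gene analysis used to
compare post-weaning-diarrhea (PWD) prophylaxis diets in piglets: a control
("white") diet, a conventional in-feed antibiotic ("traditional") diet, and
an essential-oil supplemented ("oil") diet, with rectal samples at days 1,
12, 26 (weaning) and 58. This note records the models, conventions and
design choices behind each stage, and what the synthetic data generator
does and does not emulate.

## Read quality control

Joined single-end reads are filtered with three rules applied in order:

1. **Run rule / truncation.** A run of more than `max_bad_run` (default 3)
   consecutive low-quality calls truncates the read immediately before the
   run starts. *Low quality* means Phred <= `quality_threshold` (default
   19): the threshold value itself counts as low, the convention of the
   amplicon toolchains whose parameterization these defaults mirror.
2. **Fraction rule.** Retained length / original length must be >=
   `min_fraction` (default 0.75).
3. **N rule.** The retained portion must contain no uncalled base.

Whether the original analyses truncated reads or only tested the longest
high-quality stretch is not decidable from toolchain descriptions alone;
truncation is the default and a `longest_run` mode (no truncation, the
fraction being the longest high-quality stretch over read length) is
implemented and unit-tested. Failure accounting assigns each discarded
read to its first failing rule, so the counts partition the input exactly.

## OTU-table processing

- **Rare-OTU filter:** keep taxa with total count >= 10 that are present in
  >= 2 samples. Study reports phrase this rule in several near-equivalent
  ways; this conjunction is the standard reading and both thresholds are
  configurable.
- **CSS normalization:** per sample, counts are divided by the cumulative
  sum of counts up to the sample's median positive count (type-1 lower
  empirical quantile; ties included), times a scale constant of 1000. The
  quantile is fixed rather than chosen adaptively per dataset, keeping the
  operation deterministic; it is configurable.
- **Aggregation** sums values over identical lineage prefixes
  (domain..genus); lineage labels such as "uncultured" are kept as real
  labels, so two "uncultured bacterium" genera under different families
  remain distinct taxa.
- **Rarefaction** subsamples reads without replacement (multivariate
  hypergeometric) per depth, or accumulates distinct taxa over random
  sample orderings.

## Core microbiome

A taxon (genus rank by default, on the rank-aggregated filtered raw table)
is *core* for a period when present in >= 90% of the period's pooled
samples (pre = T0+T1, post = T2+T3). The prevalence comparison is done in
exact rational arithmetic, so 9 of 10 samples passes a 0.9 threshold with
no floating-point edge cases. Core sets are compared on full six-rank
lineages. Whether prevalence should be computed on raw or normalized
tables is a free choice (prevalence is scale-invariant per sample; the
choice only matters through filtering), and the filtered raw table is the
default.

## Alpha and beta diversity

Eight per-sample indices are reported: observed richness, bias-corrected
Chao1, ACE (rare-taxon cutoff 10), Fisher's alpha (root of
S = a·ln(1 + N/a)), Shannon entropy in **bits** (log base 2), Simpson
1 − Σp², Pielou's J = H / log2(S_obs), and Simpson evenness
(1/Σp²)/S_obs. The base-2 convention is pinned by the published summary
cells, where J equals shannon/log2(richness) to within rounding in every
cell. Richness estimators require raw integer counts (their formulas use
frequencies of frequencies); Shannon/Simpson-family indices are computed
from CSS-normalized values, which enter only through proportions. ACE and
Fisher's alpha are undefined for degenerate vectors (e.g. all rare taxa
singletons) and reported as NaN there.

**Baseline adjustment** subtracts each treatment group's mean day-1 value
from that group's whole series, making group means exactly zero at T0 and
removing litter/initial-condition confounding from between-group contrasts;
within-group differences between later timepoints are unchanged.

Beta diversity is Bray-Curtis on normalized values. NMDS minimizes Kruskal
stress-1 by majorization (SMACOF, non-metric) from a classical-scaling
start, making the embedding deterministic given a seed. PERMANOVA uses the
standard pseudo-F on squared distances with p = (#{F* >= F} + 1)/(B + 1)
at B = 999 permutations; permutations are free by default (matching the
published analysis, which reports no repeated-measures restriction), with
an optional `strata` argument to restrict permutations within pigs.

## Repeated-measures model

For a per-sample response y (alpha index, normalized count, or F:B ratio):

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, sigma2_pig),
    corr(e_ij, e_i'j) = rho^|t_ij - t_i'j|,  Var(e) = sigma2_e

with fixed effects of treatment and timepoint (the F:B model uses the
pre/post period, treatment, and their interaction), a random intercept per
pig, and stationary AR(1) residual correlation on the **timepoint order**
(lags 1,2,3 — the uneven day spacing 1/12/26/58 is deliberately ignored;
the correlation is per-step). Estimation is REML: the residual scale is
profiled out and the profiled criterion is minimized over
(rho, gamma = sigma2_pig/sigma2_e) with Nelder-Mead on transformed
coordinates (atanh for rho, log for gamma); fixed effects follow by
generalized least squares, and pigs sharing a timepoint pattern are
stacked so each likelihood evaluation costs a single 4x4 inverse plus
BLAS products. |rho| >= 0.99 raises a boundary flag on the fit.

Each fixed term gets a Wald F with containment denominator degrees of
freedom `n_obs − n_pigs − rank(X) + 1` — a single df for all terms (46 at
the study scale with the interaction model). This single-df containment
convention reproduces the published term p-values from their F statistics
to the fourth decimal, so it is what the original analysis used; note it
is anti-conservative for between-pig contrasts (the treatment term's
effective replication is 17 pigs), and simulation at study scale puts the
treatment term's type-I error near 0.065 for Gaussian responses at
nominal 0.05. Pinning `fix_rho=0, fix_gamma=0` reduces the fit exactly to
ordinary least squares.

**Per-OTU tests** fit this model to every taxon's normalized counts
(counts, not logs, as in the published analysis) and flag taxa with
treatment-term p < 0.05, with no multiplicity correction — again matching
the published cutoff. Taxa entirely zero in some treatment-by-timepoint
cell, or constant, are skipped and logged.

## F:B ratio and bootstrap

The Firmicutes:Bacteroidetes ratio is computed per sample from normalized
counts summed at phylum rank; samples with a zero Bacteroidetes sum have
an undefined ratio and are excluded with a warning. The ratio model is the
interaction model above.

The bootstrap draws, per replicate, samples with replacement **within each
treatment x timepoint cell**, placing each drawn sample onto one of the
cell's original (pig, timepoint) design slots. This keeps the
repeated-measures design intact in every replicate (duplicate draws can
never create a singular AR(1) block) while resampling the observed
responses — the only reading of "resample the data and recompute each
sample's ratio" under which the replicate model remains estimable. A
pig-level cluster bootstrap (`unit="pig"`, resampling whole pigs within
treatment) is provided as the variant that propagates between-pig
variance. The replicate refit uses the interaction model by default
(matching the reported bootstrapped interaction term), with a flag for the
additive model.

Summaries: per-term medians of the replicate F statistics and p-values,
and per treatment x period cell the observed median ratio with Q1/Q3 of
the bootstrapped per-sample ratio distribution (all replicate samples in
the cell pooled). The pooled-sample reading of the quartiles is forced by
the published intervals, which are far wider than any plausible sampling
uncertainty of a cell median and match within-cell sample spread; under
it, the interquartile band covers a known simulated effect in ~80% of
study-scale datasets, whereas quartiles of replicate cell medians would
cover it in well under half (a within-cell sample bootstrap cannot see the
pig-level variance of a cell median).

## Growth and mortality

Average daily gain uses a 26-day pre-weaning span (day 1 to 26) and a
32-day post-weaning span (day 26 to 58); these divisors reproduce every
published sequenced-subset ADG cell from the published weights. The
whole-trial "overall" ADG is **not** derivable from group-mean weights
when survivor composition changes between weighings, and is reported as
missing. Group differences — including mortality, as per-animal 0/1 death
indicators over the initial group size — are tested by one-way ANOVA (the
published convention; a chi-square alternative is provided). Degenerate
ANOVA inputs (no spread at all) return F = 0, p = 1.

## Synthetic data generator

Counts are logistic-normal multinomial: per-taxon latent log-abundance =
baseline + treatment effect + timepoint effect + per-pig effect
(N(0, sigma_pig²), drawn per taxon) + stationary AR(1) noise across the
pig's timepoints (marginal sd sigma_noise, per-step correlation rho); a
softmax maps latents to a composition, and counts are multinomial at a
log-normal library size. Additive log-scale effects are exactly the
structure the repeated-measures model assumes, which keeps parameter
recovery well-posed — a Dirichlet-multinomial would not give that.

Defaults are the emulated study's conditions: 17 pigs (5/6/6 per arm), 4
timepoints, 68 samples; the taxon panel is the 46 distinct published core
lineages with baselines log(average counts), giving a realistic
rank-abundance shape; timepoint effects encode each taxon's published
pre-to-post shift; treatment effects are a modest Firmicutes enrichment
(oil 1.4x, traditional 1.15x, white 1x) reproducing the observed F:B
ordering. The study reports no variance components, so sigma_pig = 0.3,
sigma_noise = 0.6 (log scale) and rho = 0.4 are free choices in the range
typical of log-scale 16S variation; library sizes are log-normal around
85,000 reads (the per-sample average depth after filtering), sigma 0.4.
`random_taxon_panel` provides larger generic panels (log-normal
rank-abundance, phyla rotating through the five major gut phyla) for
calibration studies.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomic mis-assignment, zero-inflation beyond multinomial sampling,
litter structure, and real tables' long tail of thousands of rare OTUs
(the default panel is 46 abundant taxa, so simulated core sets are much
denser than real ones). Passing tests therefore demonstrate correctness of
the statistical machinery under the assumed dependence structure, not
robustness to those artifacts.

Read generation builds reads per QC outcome class with unambiguous
quality layouts (e.g. a run of max_bad_run+1 Q10 calls halfway through
the read, or just under the fraction boundary), so filter retention can be
checked against the manifest exactly. Growth generation draws per-piglet
weights around group means (published means and group sizes by default),
resampling draws that violate positivity or within-piglet monotonicity,
with Bernoulli mortality; pre-weaning deaths lack both later weights.

## Problem sizes used in checks

The packaged verification studies use: oracle comparisons on ~1000 random
small instances per kernel; PERMANOVA null calibration over 500 simulated
18-sample datasets at 999 permutations; per-OTU null calibration over 6
simulated studies of 300 taxa (1800 tests); REML recovery over 200
simulated 200-pig studies; bootstrap interval behavior over 100
study-scale (17-pig) datasets at 200 replicates (the production default
is 1000); and QC accounting on 1000 generated reads.

## Known limitations

- The single containment df is the published convention but is liberal for
  between-pig terms at 17 pigs (see above); per-OTU null rejection on
  count responses runs near 6-7% at nominal 5%.
- Fixed-effect tests use plug-in variance parameters (no Kenward-Roger
  small-sample correction).
- CSS uses a fixed median quantile rather than the reference method's
  adaptive quantile selection.
- AR(1) ignores the uneven day spacing; with 4 timepoints the data cannot
  distinguish per-step from per-day decay anyway.
- The sample-level bootstrap underestimates cell-median uncertainty in the
  presence of pig-level correlation; the pig-level variant addresses this
  at the cost of only 5-6 resampling units per arm.
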