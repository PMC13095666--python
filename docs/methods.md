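# Methods

## Guide assignment

Guide reads arrive as (cell barcode, guide id, MAPQ, read id, optional UMI)
records, exported upstream from alignment of guide-transcript reads against
the guide library. Reads with MAPQ < 30 are discarded (inclusive threshold).
Counting deduplicates either by unique read id (default) or by unique
(cell, guide, UMI) triple; UMI collapse guards against PCR jackpots after
targeted guide-transcript amplification, but read-id counting is the default
because the assignment rule is defined over separate barcoded reads. A cell
is **assigned** the most abundant guide when it has ≥ 2 deduplicated reads
and the top guide holds strictly more than 2/3 of them; cells with enough
reads but no dominant guide are **ambiguous** (a tie can never satisfy the
strict inequality, so no tie-breaking is needed); cells below the read floor
— or absent from the read table — are **unassigned**. Assignment is
invariant to read order and monotone: adding reads for a cell's assigned
guide never changes the call.

## Heteroplasmy from linked SNVs

The model system is a heteroplasmic mouse mtDNA (16,299 bp, 1-based circular
coordinates) carrying two haplotypes distinguished by seven SNVs: the focal
pathogenic m.5024C>T together with m.13715C>T on one haplotype (*cis*), and
m.1781C>T, m.1866A>G, m.3009G>T, m.3823T>C, m.13614C>T marking the other
(*trans*). Because the seven sites are in perfect linkage, the read depth at
each site is an independent observation of the same underlying fraction, and
counts can be pooled:

    h = Σ_s f_s / Σ_s (ref_s + alt_s),   f_s = alt_s (cis) or ref_s (trans)

Reads carrying neither the reference nor the alternate base at a site are
excluded from both numerator and denominator. Pooled h equals the
depth-weighted mean of per-site oriented fractions, and relabeling which
haplotype is focal maps h to exactly 1 − h.

Orientations can be supplied or inferred: for each non-focal site, the
Pearson correlation between its per-cell allele fraction and the focal
site's is computed over cells with depth ≥ 5 at both sites; r ≥ +0.3 marks
the site cis, r ≤ −0.3 trans, and anything else (or fewer than 10 qualifying
cells) leaves the site unknown and excluded from pooling. These thresholds
are implementation choices — linkage in the source system is essentially
perfect, so any reasonable cutoff recovers it; they exist to fail safely on
noisy or unlinked sites.

Cells are filtered at combined depth ≥ 20 (inclusive) before variance
analyses; the accuracy simulation below quantifies what that threshold buys.
Long-read tables (read × position × allele) are summarized as pairwise
haplotype concordance — the fraction of reads covering both positions whose
oriented alleles agree — which is 100% under perfect linkage and
q·q′ + (1−q)(1−q′) under independence.

## mtDNA copy number

Relative copy number is the mean deduplicated mtDNA coverage:
total aligned mitochondrial bases / genome length. It is deliberately *not*
normalized to total ATAC signal: nuclear read counts rise through S/G2 as
nuclear DNA replicates, so normalization would erase exactly the cell-cycle
trends in mtDNA content that the readout should expose (a normalized column
is emitted alongside when nuclear fragment counts are available). Group
comparisons use pairwise two-sided Welch t-tests on log10 coverage with
Bonferroni correction; zero coverages are floored at half the smallest
nonzero value before the log (an implementation choice, logged at runtime).
Welch is used throughout where a t-test family is unspecified, since equal
group variances cannot be assumed under depletion.

## The read-depth bottleneck null

For observed heteroplasmy ĥ = Binomial(n, h)/n with h drawn from the cell
population, the law of total variance gives

    Var(ĥ) = Var(h) + (E[h](1 − E[h]) − Var(h)) · E[1/n]

so reduced depth inflates variance mechanically. The null distribution for a
perturbed group's variance is built by depth-matched binomial resampling:
per simulation, draw n_kd control cells without replacement; per cell, draw
a depth with replacement from the perturbed group's depths; draw an
alternate count Binomial(depth, control h); record the sample variance
(n − 1 denominator, used throughout) of the simulated fractions. After 5,000
simulations the observed variance is scored with a two-sided add-one
empirical p:

    p = min(1, 2·min((1 + #{null ≤ obs})/(S+1), (1 + #{null ≥ obs})/(S+1)))

The add-one form keeps p strictly positive and honest at finite S; its cap
at 1 matches the convention of reporting saturated adjusted p-values as 1.
Holm correction is applied across perturbed groups, with the number of tests
equal to the number of non-reference groups compared (a runtime parameter).
The observed group variance is computed on unfiltered cells by default,
matching the all-depth analysis where bottleneck effects are strongest; a
depth filter can be applied on both sides.

One property of this construction worth knowing: the null treats the
control group's *observed* heteroplasmies as the true population, so it
carries the control group's own measurement noise, q·E[1/n_control], as a
small upward bias. With deep control coverage (the regime of non-depleted
cells here) this bias is negligible relative to the null's spread; it would
matter if the control group itself were shallowly sequenced.

## Calling-accuracy simulation

To quantify depth effects on single-cell calling, cells receive a true
heteroplasmy from Normal(μ = 0.582, σ = 0.113) clipped to [0, 1] — clipping
moves negligible mass at these parameters — and a finite pool of N = 1,750
molecules with round(h·N) mutant copies (the measured copy number of
unperturbed cells). Sampling n molecules without replacement
(hypergeometric) models the partition of molecules into reads; sample sizes
5/20/50/100 across 2,000 cells show R² of sampled-on-true regression rising
steeply with n. A matched-population mode instead draws each cell's depth
from a supplied empirical distribution. The bottleneck *null* above uses
binomial sampling (reads resample molecules effectively with replacement),
while the accuracy simulation subsamples a finite pool without replacement;
the two regimes model different physical processes and both are kept.

## Depth-variance quantile model

Cells are sorted by combined depth and split into contiguous equal-count
bins (non-depleted population: 100 bins; depleted groups: 15), remainders
going one extra cell to the lowest-depth bins (the assignment rule for
non-divisible counts is an implementation choice). Per bin, mean depth and
the sample variance of h are computed, and the 5th and 95th percentile
curves are fit as

    Variance = β₀ + β₁ / depth

by minimizing the pinball loss ρ_τ(u) = u(τ − 1{u<0}). The fit is solved as
a linear program (exact optimum; recovers zero-residual designs with loss 0,
where iteratively reweighted solvers stall). The intercept is kept because
biological variance does not vanish at infinite depth; only the
depth-dependent component scales as 1/depth. Uncertainty bands come from
resampling bins with replacement (200 iterations), refitting, and taking
pointwise 2.5/97.5 percentiles over a depth grid; degenerate replicates
(all bin depths equal) are redrawn up to 10 times.

## Supporting statistics

Brown–Forsythe variance test: each value is transformed to |x − group
median| and a one-way ANOVA F is computed on the transformed values (W = F);
if every transformed value is zero, W = 0 and p = 1. Holm and
Benjamini–Hochberg adjustments wrap statsmodels; Welch t, Mann–Whitney,
Wilcoxon, chi-squared and ANOVA come from scipy. Where a figure-legend
convention names a signed-rank test for unpaired group comparisons, the
independent-sample rank-sum test is used, with an explicit `paired=True`
mode for genuinely paired designs.

## Transcriptomic response

Expression input is assumed log-normalized. Each gene is regressed on
per-cell mtDNA copy number (OLS, linear scale by default with a log10
option); the residuals are the CN-adjusted expression. The top 2,000
residual-variance genes (ties broken by gene id for determinism) feed a PCA
on centered, unit-scaled residuals — scaling prevents a few high-variance
genes from dominating; zero-variance genes are dropped with a warning. Each
component's sign is fixed so its largest-magnitude loading is positive. PC1
scores are compared per group against the non-targeting reference by
two-sided rank-sum tests with BH correction; cell-cycle phase composition
(G1/S/G2M) per group versus all other cells by 2×3 chi-squared (no
continuity correction, low-expected-count rows flagged); and coverage trends
across phases by one-way ANOVA, with equal-width pseudotime bins over
[0, 2π) for the continuous view.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with one seed
fanned out through named substreams so stages regenerate independently:

* true heteroplasmy ~ Normal(0.582, 0.113) clipped to [0, 1], identical in
  expectation across groups — perturbations deplete copy number, not
  heteroplasmy;
* true copy number = 1,750 × per-gene depletion factor (defaults: Tfam 0.2,
  Polg 0.3, Opa1 0.4; all other genes 1.0) × lognormal noise (σ = 0.25),
  rising linearly through cell-cycle pseudotime (relaxed replication);
* per-base coverage = copy number × (60/1750) × lognormal dispersion
  (σ = 0.6), so undepleted cells average ~60× per-base coverage with a heavy
  low-coverage tail; combined panel depth ~ Poisson(7 × per-base coverage),
  i.e. ~420× for undepleted cells — summing seven sites multiplies per-base
  depth by the panel size, which is what makes pooled calling precise while
  depleted cells drop into the bottlenecked regime;
* per-site alternate counts ~ Binomial(site depth, h) at cis sites and
  Binomial(site depth, 1 − h) at trans sites, with fixed multinomial site
  weights;
* guide reads per cell ~ Poisson(mean × (1 − ambient)) of the true guide
  plus Poisson(mean × ambient) uniformly random ambient reads; MAPQ drawn
  from a supplied distribution (default: 10% below the 30 threshold);
* expression: gamma-Poisson (negative-binomial) counts, log1p-normalized,
  with a stress-response gene module scaled by (1 − depletion factor) and a
  second module tracking coverage;
* an optional per-gene heteroplasmy-s.d. inflation map injects genuine
  variance changes for power studies.

What the generator does **not** emulate: doublets and empty droplets,
ambient mtDNA contamination between cells, NUMT misalignment, strand
asymmetries or site-specific base-calling error, chimeric long reads, or
realistic transcriptome structure beyond two gene modules. Tests passing on
these cohorts therefore validate the estimators and their calibration under
the stated sampling models, not robustness to those artifacts — which
upstream QC is expected to handle.

## Problem sizes and numerical choices

The test suite and acceptance script use cohorts of 1,250–6,000 cells, 100
replicate cohorts for the calibration/power rates, and 5,000 null
simulations per test — sizes at which every Monte-Carlo tolerance used is
several standard errors wide while the whole suite runs in minutes on one
CPU. The quantile LP uses scipy's HiGHS solver (deterministic); bootstrap
and simulation reproducibility are exact under a fixed seed; TSV outputs are
written at full double precision so reruns are byte-identical.

## Known limitations

* The bottleneck null conditions on observed control heteroplasmies and
  observed depths; it does not propagate uncertainty in either, and carries
  the control-noise bias noted above.
* Beta-binomial overdispersion (e.g. from intra-cell mtDNA clustering) is
  not modeled; a cell whose reads are not independent draws will look
  overdispersed relative to the binomial null.
* Orientation inference assumes a two-haplotype system; recombinant or
  third-haplotype structures yield intermediate correlations and are
  excluded rather than modeled.
* Copy-number estimates are relative; absolute calibration requires an
  external standard.
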