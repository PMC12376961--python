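# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package. Everything quantitative stated here is computed
by the test suite, the `analysis/` drivers or `scripts/acceptance.py`.

## Data model

The pipeline's currency is a diploid bi-allelic dosage matrix
(individuals × loci, values 0/1/2 counting copies of the per-locus reference
allele) with a missing-data mask, plus per-individual metadata
(collection, river, calendar year, role). Individuals are never dropped for
missingness; masked cells simply contribute nothing to any estimator.
Polarity is fixed per dataset: merging or comparing files reconciles allele
symbols explicitly, and strand-ambiguous pairs (A/T, C/G) typed with
reversed symbols are flagged rather than guessed, because a silent strand
flip would corrupt admixture polarity. The two-row "structure" text dialect
stores only per-call allele symbols, so the polarity of a locus monomorphic
in a file is unrecoverable from that file alone; readers document this and
the round-trip tests assert exactness at the file level.

## Locus filtering

MAF filtering keeps loci with minor-allele frequency above the threshold
(default 0.05) in *every* collection named by the caller, computed on
non-missing calls. LD pruning uses the genotype (composite) correlation
r² because phase is unknown, with missing cells mean-imputed for the
correlation only; pruning is greedy keep-first over the input order, which
makes it deterministic and idempotent. Default r² cut-off 0.8.

## Admixture model

Two-source supervised mixture: individual *i* has coefficient *q_i*; each of
its two allele copies at a locus is of hatchery origin with probability
*q_i* independently, and carries the reference allele with probability
*p*<sub>H</sub> (hatchery cluster) or *p*<sub>W</sub> (wild cluster). Loci
are treated as unlinked. The EM estimator maximises the joint likelihood
over all *q* and both frequency vectors; reference individuals are pinned
hard at *q* = 0 / *q* = 1 and anchor the labels (the model is unidentifiable
up to label swap without an anchor). Cluster frequencies are clipped to
[10⁻⁶, 1−10⁻⁶]. Convergence is declared when the largest per-iteration
change in any *q* falls below 10⁻⁵ (≤ 300 iterations). Restarts (default 5,
mirroring the replicate-runs-for-consistency practice) jitter the frequency
initialisation; the best likelihood is kept and the fit is flagged
non-converged if restarts disagree in any *q* by more than 0.01.

This EM point estimator stands in for an MCMC clustering with a
correlated-allele-frequency prior: in the supervised K = 2 setting the
likelihood is well identified, and a deterministic optimiser is faster and
directly testable against a dense grid search of the same likelihood (the
tests do exactly that). Consequences of the simplification: no posterior
uncertainty from the frequency prior, slightly less shrinkage of extreme
*q*.

Confidence intervals for *q* are nonparametric bootstrap over loci
(default 200 replicates, percentile, level 0.90) with cluster frequencies
frozen at the fitted values; the interval is widened if necessary to contain
the point estimate (resampling loci can shift the whole distribution at
small panels). The hybrid index *h* used by the cline analysis is the same
per-individual maximiser with both frequency vectors frozen at supplied
parental tables, so *h* ≡ *q* under pinned frequencies — asserted in tests.

Analyses run **per river** with shared reference panels. Pooling rivers in
one K = 2 run lets between-river drift leak into the wild–hatchery axis and
biases *q* in opposite directions in the two rivers; we observed this
directly on the synthetic two-river data.

## Hybrid classes and thresholds

The five classes are simulated by explicit gamete sampling: pure classes are
Hardy–Weinberg draws from their source frequencies, an F1 receives one
gamete from each source, and each backcross receives one gamete from a
freshly simulated F1 parent (one of its two alleles per locus at random)
plus one pure gamete. Simulating the F1 parent explicitly preserves the
between-individual variance of backcross ancestry that frequency-pool
crossing would understate.

Calibrated thresholds follow the printed rule: the upper boundary of each of
the first three classes is the minimum simulated *q* of the next-higher
class minus 0.01 (so a simulated backcross-to-wild minimum of 0.13 puts the
WILD boundary at 0.12, and an F1 minimum of 0.35 puts the low-admixture
boundary at 0.34); the HAT lower boundary is the 5th percentile of simulated
HAT *q*. Boundary points between the high-admixture and HAT intervals
belong to HAT (intervals: [0, b₀], (b₀, b₁], (b₁, b₂], (b₂, b₃), [b₃, 1]).
Calibration fails loudly when the simulated class distributions overlap so
much that boundaries invert or leave no WILD interval — which is the normal
outcome for small panels at source divergence as low as F<sub>ST</sub> 0.026.
The intended workflow, reproduced in `analysis/03`, is to calibrate on a
dense panel (or fall back to the published default thresholds
0.12/0.34/0.60/0.84) and classify smaller-panel fish with the same criteria.
The coarse screen (*q* < 0.20 "pure wild", *q* > 0.80 hatchery) exists only
to pick WILD-proxy reference fish when no explicit wild reference is
available.

## Temporal selection scan

Per locus, allele counts at sampled generations are modelled by a
hidden-Markov Wright–Fisher chain with 2N<sub>e</sub>+1 states. Transitions
are binomial draws of 2N<sub>e</sub> copies at the post-selection frequency
*p*\* = *p*(1+*s*)/(1+*ps*) — genic (multiplicative, dominance-free)
selection with fitness 1+*s* per copy of the reference allele, the
dominance-free default since the parameterisation of the original temporal
test is not recoverable. Emissions are binomial in the sample size. The
initial state distribution is the posterior of a uniform prior over states
given the first sample; the first sample is conditioned on, not scored,
which avoids penalising the unknown starting state and calibrates the null
(checked by simulation: type-I error 0.02–0.09 at nominal 0.05 over 500
drift-only loci). The forward pass is scaled; it equals brute-force path
enumeration for N<sub>e</sub> ≤ 3 to 10⁻¹⁰, and satisfies the
polarity-flip identity s′ = −s/(1+s) numerically.

*ŝ* comes from a grid (−0.5 … 0.5, step 0.01) refined by bounded scalar
minimisation in the bracketing cell; the LRT 2(ℓ̂ − ℓ₀) is referred to χ²₁.
Calendar years map to generation indices by rounding at 3.5 years per
generation, and collections landing on one index are pooled. Scans restrict
to fish classified wild, low- or medium-admixed, run per river and per
N<sub>e</sub> ∈ {100, 200} (constant within a scenario), and BH-adjust
p-values within each scenario; outliers are adjusted p < 0.05. Series fixed
for one allele in every sample are flagged unidentifiable with p = 1.

Power at these settings is genuinely modest: post-FDR recall of five
*s* = 0.25 loci among 288 is high (4–5/5 in our scenario tests) only when
the selected loci are moderately differentiated between the sources so that
the selection response is sustained across the sampled generations; loci
nearly fixed in the hatchery strain are purged largely during the stocking
phase itself (multi-locus selection against intact hatchery genotypes), and
weakly differentiated loci barely move. This mirrors the sparse post-FDR
outlier counts the method produces on real monitoring data.

## Genomic clines

Per locus the three genotype categories are regressed on *h* by multinomial
logit (linear predictor per non-reference category; batched Newton with a
10⁻⁶ ridge so separated fits stay finite — identical machinery in observed
fits and null refits, so the calibration absorbs it). The neutral model
gives category probabilities ((1−*m*)², 2*m*(1−*m*), *m*²) with
*m* = *h p*<sub>H</sub> + (1−*h*) *p*<sub>W</sub>; the statistic is the
deviance 2(ℓ_fit − ℓ_neutral) (not necessarily positive — the two models
are not nested) and the direction statistic is the mean observed-minus-
expected dosage of the **hatchery-associated** allele, so its sign is
invariant to which allele the file happens to count. The null distribution
per locus comes from 2000 simulated admixed individuals (each resamples an
observed *h*, then draws each allele copy from the ancestry-specific
parental frequency) refit in observed-cohort-sized subsamples (default
999 refits, warm-started from the pooled fit). p-values are two-sided
permutation ranks; verdicts after BH: "reduced" (significant, hatchery
allele under-represented), "increased", else "neutral".

Cline tests run on an informative-locus panel — the union of the top 5%
between-reference discriminators, per-locus θ > 0.03 between references,
and any externally supplied outlier list — and per river. Two consequences
worth knowing: (i) with 999 refits the two-sided permutation floor is
p = 0.002, so FDR-adjusted significance requires either multiple true
signals or a panel not much larger than a few hundred loci — testing the
informative panel, as the pipeline does, is what makes small signal sets
detectable; (ii) on cohorts produced by many generations of genuine
Wright–Fisher drift the neutral permutation model is misspecified
(drift-deviated neutral loci get flagged), so verdict counts on real or
realistically simulated cohorts overstate locus-specific selection; the
simulation-truth driver reports this precision honestly.

The linear-in-*h* logit cannot represent the neutral quadratic exactly near
*h* = 0/1; over the *h* range the data cover, the replicate-mean gap between
fitted and neutral curves is < 0.1 at n = 200 (model-class bias ≈ 0.04 in
the dense-data limit). Inference rests on the simulation-calibrated
deviance, not on curve agreement.

## Synthetic data generator

Source pools: ancestral frequencies uniform on [0.05, 0.95]; each pool draws
per-locus frequencies from a Balding–Nichols Beta with divergence parameter
equal to the target F<sub>ST</sub> (default 0.026; realised multi-locus θ
between 500-fish samples verified within ±0.01). Each river is a discrete-
generation Wright–Fisher population of N<sub>e</sub> diploids at unlinked
loci: per generation, a scheduled fraction of the parent pool is replaced by
fresh pure-hatchery individuals, parents are drawn proportionally to
multiplicative genic fitness over the selected loci, and offspring receive
one gamete per parent. True ancestry is pedigree-expected (mean of parental
ancestries; stocked fish = 1) — adequate for scoring *q* recovery and cheap,
but without the locus-level ancestry variance of real genomes. No linkage,
no overlapping generations, no within-river structure, no migration between
rivers.

The default two-river preset: 288 loci, N<sub>e</sub> = 200, stocking 0.3
per generation for six generations then zero, thirteen generations total,
five loci with *s* = 0.25 against the hatchery-associated allele, cohorts of
40 sampled at generations 6, 8, 10 and 13 (years anchored at 2001, 3.5
y/generation), plus 50-fish wild and hatchery reference cohorts. Locus 0 is
six6-like: frequency 0.92 in the hatchery pool versus 0.15 in the wild —
dominant in the hatchery strain yet polymorphic enough that a 50-fish
hatchery reference sample passes the pipeline's own MAF > 0.05 screen.
Because multi-locus selection purges intact hatchery genotypes fastest
during the stocking phase, the six6-like locus reliably ranks among the
largest post-stocking hatchery-allele declines but is not always strictly
the largest of the five.

What passing on this generator does and does not show: it validates the
estimators under the stated statistical structure (unlinked loci,
well-defined source pools, missing-at-random calls); it does not emulate
linkage to causal variants, genotyping artefacts, family structure within
collections, or ongoing gene flow between rivers — all present in real
monitoring data.

## Problem sizes and numerical choices

Acceptance-level checks run at the study's own scales: 3656 loci for the
hybrid-class calibration experiment, 500 drift-only loci for LRT
calibration, 300 loci / 200 fish / 999 null refits for cline specificity,
and the full −0.5…0.5 s-grid. Unit tests use smaller replicates of the same
structures. Tie-breaking is deterministic everywhere (stable sorts, greedy
keep-first pruning, fixed per-stage seed offsets from one global seed), and
rerunning the pipeline with one seed reproduces byte-identical tables.

θ bootstrap CIs resample individuals within populations (default 1000
replicates in the API, 0.95 level; the percentile interval is widened to
contain the point estimate, which individual-resampling can otherwise
exceed at small n). The source material is ambiguous between 90% and 95%
intervals for this statistic; the level is a parameter. Negative per-locus
θ values are reported as computed; the multi-locus estimator is the ratio
of summed variance components, untruncated. Expected heterozygosity uses
Nei's per-locus correction n/(n−1) on allele copies, then averages over
defined loci. Hatchery strains, when two are present, are pooled by default
(their mutual differentiation in the motivating system is below the
wild–hatchery signal); a flag separates them.
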