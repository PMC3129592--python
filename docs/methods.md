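# Methods

This note documents the statistical procedures implemented in
`tissueatlas`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical edge cases.

## Detection calls (`tissueatlas.detection`)

Short-oligo arrays pair each perfect-match (PM) probe with a mismatch (MM)
probe that estimates cross-hybridization background. A probe set with k
pairs is called by the discrimination scores
`R_i = (PM_i − MM_i) / (PM_i + MM_i)` and a one-sided Wilcoxon signed-rank
test of H₀: median R = τ_det against H₁: median R > τ_det. For up to 25
pairs the p-value uses the exact sign-flip null distribution, computed by
dynamic programming over doubled midranks, so ties and zeros are handled
without approximation; beyond 25 pairs a continuity-corrected normal
approximation is used. Defaults τ_det = 0.015, α₁ = 0.04, α₂ = 0.06 are
the classic present/marginal/absent parameterization for this array type;
all three are config-exposed. At least 6 pairs are required for the test
to be able to reach conventional significance.

Replicate calls collapse to a per-(tissue, sex) consensus by the "present
in at least `min_present` replicates" rule (default 3). Marginal calls do
not count as present. The rule needs head-room: passing exactly
`min_present` replicates would turn "at least 3 of 4" into "all of 3", so
that is rejected as a caller error. Gene-level detection is the logical OR
over a gene's probes — a gene is detected if any probe detects it — and a
gene is *tissue-specific* when its consensus detection is true in exactly
one (tissue, sex) cell.

Under a silent probe set (PM = MM + symmetric noise) the test is
conservative by construction (the true median R is 0, below τ_det), so the
present rate at α = 0.05 stays below nominal; the test suite measures it
at well under 7% over 5,000 simulated sets.

## Sex bias and gonad enrichment (`tissueatlas.differential`)

Each gene gets a two-group comparison on log2 intensities (female vs male
within a tissue, or gonad vs carcass within a sex). With two groups this
is equivalent to a one-way ANOVA, so a single moderated t-test covers both
framings. Because per-gene variances from ~4 replicates per group are
unstable, they are shrunk by empirical Bayes: s² is modelled as
s₀²·F(d, d₀), i.e. a scaled inverse-chi-square prior (s₀², d₀) on the true
variance, and the posterior variance

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)

feeds a moderated t with d₀ + d degrees of freedom. The hyperparameters
are fitted by a method-of-moments match on the log scale (digamma /
trigamma moments of log s², with a Newton inversion of the trigamma
function). The log-scale match was preferred over matching raw first and
second moments of s² because the raw-moment solution only exists for
d₀ > 4 and is erratic at small replicate counts, while the log-scale match
is defined whenever the empirical spread of log s² exceeds its theoretical
sampling spread; when it does not, d₀ = ∞ (complete shrinkage to the
prior) is the natural limit. Setting d₀ = 0 recovers the ordinary
equal-variance t exactly, which the tests verify to 10⁻¹⁰.

Degenerate genes: with zero residual variance and no prior, the test
statistic has no finite form. A zero-variance gene with a non-zero effect
is assigned the limiting p = 0 (t = ±∞); a gene with zero variance *and*
zero effect carries no information and is flagged (p = NaN, `degenerate`).
This limit is what makes noise-free simulations classify exactly.

Classification applies two rules jointly: Benjamini–Hochberg q < 0.05
*and* a fold rule on the model's effect estimate M (|M| ≥ 1, i.e. 2-fold,
for sex bias; M > 2 strictly for gonad enrichment). The fold rule is
applied to M, not the raw ratio of means, and both thresholds are
config-exposed — in particular the gonad "M > 2" cut is kept distinct from
the 2-fold sex-bias cut and can be switched if a 2-fold reading is wanted.
BH q-values come from the standard step-up formula
(`statsmodels.stats.multitest` behind a validating wrapper).

Probes are collapsed to genes by taking, per (tissue, sex), the probe with
the highest mean intensity, preserving replicate structure. Restricting
the fit to consensus-detected genes is the caller's responsibility (the
CLI applies the filter when a detection table is available; the default
analysis filters to genes detected in at least one sex).

## Tissue specificity (`tissueatlas.specificity`)

The tau statistic of a non-negative per-tissue profile x over N tissues is

    τ = Σᵢ (1 − xᵢ / x_max) / (N − 1),

0 for a flat profile, 1 for single-tissue expression, scale-invariant, and
monotone under concentration of expression into the peak tissue. Profiles
are per-tissue mean log2 intensities floored at 0, with sexes combined as
the unweighted mean of per-sex means and probes collapsed by the
per-tissue maximum; log-scale profiles are the convention in the tau
literature, and flooring enforces the non-negativity the formula needs.
When a detection table is supplied, undetected tissues contribute 0
(silent) rather than their measured background mean
(`tau_detection_filter`). Breadth classes use strict thresholds:
housekeeping τ < 0.15, narrow τ > 0.85. An all-zero profile has no defined
tau and is an error (skipped, in table form).

Top-decile enrichment is a df = 1 chi-square of the observed count of a
gene set inside the top 10% of an intensity ranking against the decile
proportion, without continuity correction.

## A/S selection estimation (`tissueatlas.selection`)

Site counting follows unweighted Nei–Gojobori (1986): at each codon
position the synonymous site fraction is the share of the three possible
single-base changes that preserve the amino acid, so each position
contributes exactly one site and each codon three. Changes creating a stop
codon count as non-synonymous; a terminal stop codon is excluded from
counting; internal stops and ambiguous bases are errors. SNPs are
classified by mutating the codon and comparing translations.

A gene set's A/S pools counts — A = Σ nonsyn SNPs / Σ nonsyn sites,
S likewise, ratio = A/S — rather than averaging per-gene ratios, because
pooling is robust to genes with zero synonymous SNPs and reproduces the
printed genome-wide A ÷ S arithmetic exactly. The ratio is reported as
undefined (None), never as a number, when the set has no synonymous SNPs
or sites. The 95% CI is a percentile bootstrap that resamples *genes* with
replacement (each carrying its SNPs and sites), since genes are the
exchangeable unit of a tissue-class gene set; replicates with an undefined
ratio are dropped from the percentiles and their fraction reported.
Multi-allelic VCF rows contribute one SNP per alternate allele.

SNPs travel in CDS space (VCF CHROM = gene id, POS = 1-based position in
the CDS, forward strand), which preserves the computation while avoiding a
genome + annotation liftover; internally coordinates are 0-based
half-open, converted only at I/O boundaries. SNP density is
1000·n_snps/n_nucleotides. Two gene sets are contrasted by a df = 1
chi-square on their {syn, nonsyn} SNP counts (no continuity correction).

## Chromosome-arm tests (`tissueatlas.genome`)

A gene set's arm counts over {X, 2R, 2L, 3R, 3L} are tested against
expected counts proportional to the background (all genes of the reference
universe; configurable between "all annotated" and "same detection filter
as the set"). Standardized residuals (O − E)/√E give direction per arm.
When any expected count falls below 1 the χ² approximation is replaced by
a seeded Monte-Carlo multinomial p-value (10,000 draws, `(r+1)/(B+1)`
estimator). Genes with unknown arms are dropped and tallied. Null
calibration is verified by simulation: uniform draws from the background
reject at 0.05 ± 0.02.

## Cross-species conservation (`tissueatlas.crossspecies`)

Because the two species' array platforms have incomparable absolute
intensities, profiles are compared as relative abundance (RA): each gene's
linear-scale tissue vector divided by its sum, so rows sum to 1. RA is
defined here as proportion-of-row-total; max-normalization is available as
a config alternative for sensitivity analysis. Pearson correlation is
unchanged by the per-gene rescaling, so clustering on RA equals clustering
on linear profiles; what RA changes is the Euclidean tissue distances used
for the dendrograms.

Co-expression modules: average-linkage agglomeration on d = 1 − r. The
selection thresholds (mean pairwise correlation > 0.8, size > 50, both
strict) leave the cut procedure open; the implementation scans the merge
tree and emits the *maximal* subtrees whose mean pairwise correlation
exceeds the floor, then reports those above the size threshold. Maximality
makes the reported clusters disjoint by construction. Mean pairwise
correlations are maintained incrementally over the merge sequence
(O(n²) total), and constant profiles — for which Pearson is undefined —
are excluded and tallied.

Module conservation: with N one-to-one orthologue pairs present in both
analyses as the universe, a cluster pair with mapped sizes m, n and
overlap k gets the upper-tail hypergeometric p = Σ_{i≥k} C(m,i)C(N−m,n−i)/C(N,n),
BH-corrected across all cluster pairs, with significance bands at the
corrected 0.05 and 0.01 levels. The universe defaults to pairs whose genes
entered both clustering analyses, and the exact tail is verified in tests
against full enumeration (N ≤ 30) and a permutation oracle.

Tissue dendrograms use Euclidean distance and average linkage, with items
sorted lexicographically before linkage so equal-distance merges resolve
deterministically. Branch support resamples feature columns (genes) with
replacement, rebuilds the tree, and scores each internal branch by the
fraction of replicate trees containing the same unrooted leaf bipartition
(topology only; branch lengths ignored). Splits that are trivial as
unrooted bipartitions get support 1. Newick output renders supports as
percent internal-node labels.

Gene families over the five-species panel (Anopheles Ag, Drosophila Dm,
Tribolium Tc, Apis Am, Caenorhabditis Ce) are labelled by the deepest
outgroup present — Metazoa if a Ce member exists, else Hymenoptera (Am),
else Coleoptera (Tc), else Diptera — and as single-copy iff exactly one Ag
member. The family map is an *input* (orthology inference is out of
scope). The narrow-family report cross-tabulates (a) members of expanded
families with τ = 1 by peak tissue and (b) single-copy one-to-one families
whose two orthologues are both narrow (τ > 0.85) and share a peak tissue.

## Synthetic data (`tissueatlas.simulate`)

The atlas generator emulates the study design: 7 tissues (head, midgut,
salivary gland, Malpighian tubules, carcass, gonad, accessory gland), male
and female samples with the gonad implicitly sex-resolved (ovary/testis)
and the accessory gland male-only, 4 biological replicates, 11 PM/MM pairs
per probe set. Baseline log2 expression is drawn from N(6, 1.5) — a
lognormal intensity scale — truncated to [3.5, 9] so that expressed genes
sit inside the detected dynamic range (below ~3 the PM excess over MM for
the weakest probe pairs drops under the detection threshold, which would
blur the planted truth). Planted roles: dimorphic genes get a +2 log2
effect in one sex of one tissue; narrow genes are expressed in exactly one
(tissue, sex) cell and silent (log2 = 0) elsewhere; housekeeping genes are
flat; the remainder get a moderate single-tissue peak (Δ log2 ∈ [2, 4]),
giving intermediate tau. Gaussian noise of SD `noise_sd` (default 0.25,
log2 scale) is added per replicate. PM = background + linear signal and
MM = background, each with multiplicative lognormal noise tied to
`noise_sd` and per-pair affinity factors in [0.5, 1.5]. The truth table
records each gene's role and its *noiseless* tau computed from the
deterministic mean profile, so recovery checks compare against exactly
what was planted. At `noise_sd = 0` every downstream classification
(detection, tissue-specific set, tau, sex bias) recovers the truth
exactly; note that narrow single-sex genes are then genuinely sex-biased
in their tissue and are counted as such.

The ortholog generator plants conserved co-expression clusters: each
cluster has a center profile with a dominant peak tissue, members (in both
species) add iid noise whose variance is set from the target within-cluster
correlation r via Var(e) = Var(center)·(1 − r)/r, and values are clipped
so the planted peak stays the argmax. Non-cluster pairs are either
conserved (shared center) or diverged (independent centers) according to
`diverged_fraction`. Families carry planted outgroup memberships and
Anopheles copy numbers; duplicated copies get single-tissue profiles.

The SNP generator writes CDSs of uniform random sense codons (100–500
codons) plus a terminal stop, then turns each possible synonymous
single-base change into a SNP with probability μ_S/3 and each
non-synonymous change with probability μ_S·(target A/S)/3, so expected
counts are μ_S per synonymous site and μ_S·target per non-synonymous site
(default μ_S = 0.007, on the order of the observed coding SNP density).
Pooled A/S estimation then recovers the regime targets {0.5, 1.0, 2.0}
within ±0.1 at 500 genes.

What the generators do *not* emulate: probe sequence biases and spatial
array artifacts, bloodmeal time-course dynamics (time points are pooled
into a single tissue sample), non-uniform codon usage, linkage between
SNPs, allele frequencies, and realistic correlation structure between
tissues beyond the planted blocks. Passing tests therefore demonstrate
that the *machinery* is correct and calibrated under controlled
conditions, not that any particular biological dataset would yield the
same numbers.

## Problem sizes and determinism

Default verification sizes were chosen to make the suites sharp but quick:
1,000–2,000 genes for sex-bias recovery and null calibration, 5,000 probe
sets for detection calibration, 500 genes × B = 1,000 bootstrap replicates
per A/S run with coverage measured over repeated seeded runs, 240 genes in
three 60-gene blocks for cluster recovery, 50,000-gene backgrounds with
1,000-gene sets for the arm tests, and B = 200 for dendrogram support
(scaled down from the 10,000 used at publication scale, which is the
library default). Every stochastic operation takes an explicit seed; the
CLI default seed is 1729 and is logged on every run. Identical seeds give
byte-identical generator output files.

## Known limitations

- The detection test is a reconstruction of the standard PM/MM call; the
  exact parameterization used for the original arrays is not published, so
  τ_det/α₁/α₂ are conventions, not recovered constants.
- The moderated-model hyperparameter fit assumes a common variance prior
  across all genes of a tissue; strong variance heterogeneity (e.g. mixed
  probe quality) is absorbed, not modelled.
- Bootstrap percentile CIs undercover slightly at small gene counts; the
  coverage suite quantifies this (≥ 90% empirical coverage at 500 genes).
- The cluster-cut rule (maximal subtrees above a mean-correlation floor)
  is one defensible reading of "average similarity > 0.8 with > 50 genes";
  alternative cuts change cluster counts, as adjusting the thresholds does.
- `arm_distribution` treats genes as exchangeable; gene clustering along
  chromosomes (tandem arrays) would inflate the test's significance on
  real data.
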