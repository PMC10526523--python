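# Methods

## The analysis model

The pipeline treats the X chromosome of a female breast tumour as
described by four coupled measurements: allele-specific copy number
(major/minor integer copies per segment), promoter methylation
(beta-values in [0, 1]), log2 expression, and the RNA read support of
somatic mutations.  Its central interpretive assumption is that **the
inactive X is proxied by the minor allele** — a tumour that has deleted
its Xi shows minor copy number 0 over most of chrX — and **Xa
amplification by the major allele** (major copy number 2–3 over a large
block).  Nothing in an allele-specific segmentation labels which
haplotype is inactive; this proxy is the simplest assignment consistent
with the methylation and XIST behaviour of the deletion group (both drop
when the methylated Xi is lost), and it is deliberately the only place
where Xi/Xa identity is inferred.

### Promoter methylation

A gene's promoter methylation is the mean beta of probes within 200 bp of
its TSS, else within 1500 bp, else undefined — the TSS200/TSS1500
convention of methylation arrays.  Distance is strand-agnostic; a probe
may serve every gene whose window covers it (overlapping promoters are
rare and deduplication would need an arbitrary owner rule).  Missing
betas propagate: a gene–sample entry is missing only when all assigned
probes are missing, and means never impute.  Per-sample XCI level is the
unweighted mean over chrX genes with data.

### Clustering cascade

Samples are clustered on fixed 1 Mb chrX bins rather than raw segments so
the dissimilarity is computed in a fixed-dimensional space.  Bin value =
length-weighted mean copy number of the chosen allele over overlapping
segments; bins with no coverage take the sample's length-weighted modal
copy number (ties to the smaller value) and are flagged, so missing
telomeric segments do not masquerade as events.  Dissimilarity is the
Gower coefficient for numeric data — the mean over columns of
|xᵢ − xⱼ| / range(column), skipping zero-range columns and pairwise-missing
entries — and clustering is Ward linkage on that dissimilarity
(`scipy.cluster.hierarchy.linkage(method="ward")` on the condensed
matrix, the ward.D2-style form; scipy's merge order is deterministic, so
no additional tie-break rule is needed).  The tree is cut at k = 2 for
the copy-number tiers and k = 3 for methylation.

Cluster naming is data-driven: at tier 1 the cluster with the larger mean
fraction of bins below copy number 0.5 is Xi-large-deletion; at tier 2
(run only within Xi-unaltered samples) the cluster with the larger mean
fraction of bins above 1.5 is Xa-large-amplification; at tier 3 (run only
within Xa-unaltered samples with methylation data) clusters are ranked by
centroid mean beta — highest = high, lowest = low, middle = unaltered.  A
tie on the labelling statistic names the larger cluster unaltered
(conservative).  If every sample is identical the tier degenerates to a
single unaltered group with a warning.  `selected_unaltered` marks
samples unaltered at all three tiers; they are the contrast group for
every signature.

### RMAF

RMAF = alt / (alt + ref) is undefined below a default coverage floor of
8 reads: below that depth a binomial read count cannot usefully separate
hemizygous (p = 1) from bi-allelic (p = 0.5) expression given the 0.75 /
0.25 class boundaries (at depth 8, P(RMAF < 0.75 | p = 1) is 0 but
P(RMAF ≥ 0.75 | p = 0.5) ≈ 0.14; at depth 20 the three classes are each
recovered with probability ≥ 0.95).  Both boundary values belong to the
outer classes, exactly as the class inequalities state.  Multiple
mutations of one gene in one sample are averaged for the per-sample
gene-level RMAF (symmetric and order-free).  Records lacking usable
counts pass through unclassified.

### Differential expression and signatures

Per-gene OLS of log2 expression on [intercept, group, subtype dummies]
(treatment coding, most frequent subtype as reference; rank-deficient
designs are rejected naming the collinear columns).  Variance moderation
follows the standard empirical-Bayes formulation: a scaled
inverse-chi-square prior (d0, s0²) is fitted to the gene variances by
method of moments on log variances using digamma/trigamma identities
(trigamma inverted by Newton iteration); the posterior variance is
(d0·s0² + df·s²)/(d0 + df) and the moderated t has d0 + df degrees of
freedom.  When the log-variances are under-dispersed relative to the
chi-square sampling noise the prior degenerates (d0 = ∞, every posterior
variance = s0²); the exactly-zero-spread input is treated as noise-free
and pools to the common value.  Setting d0 = 0 reproduces the ordinary t
exactly.  This moderation stage is implemented here rather than delegated
because it is the one bespoke-numerics step of the DE analysis; BH FDR,
the hypergeometric test and the rank/chi-square/t tests wrap statsmodels
and scipy.  FDR is corrected within the tested (chrX) gene set.

Signatures keep genes at FDR ≤ 0.05 with a strictly signed logFC (0 is
excluded both ways), weighted sign(logFC).  The per-sample score rescales
each gene to [−1, 1] via its 2.5% / 97.5% quantiles with clipping
(robust to outliers, bounded output) and averages with the ±1 weights;
constant genes contribute 0.  Overlap percentages between signatures are
reported round-half-up to the nearest integer.

### Survival

Kaplan–Meier, two-group log-rank, and Cox proportional hazards (Efron tie
handling, via lifelines) with administrative censoring at a configurable
horizon: 20 years for signature evaluation, 5 for subtype comparisons.
The Cox covariate question — continuous score or median-split factor — is
left open by convention, so both hazard ratios are always reported.
Median-split ties go to the low group.  Monotone likelihood is flagged
with an unbounded confidence interval rather than an error.

## The synthetic-cohort generator

`synthdata.generate_cohort` draws, per sample: a molecular subtype
(LumA/LumB/Her2/Basal at 0.54/0.20/0.08/0.18), TP53 status (mutation
probability 0.12/0.30/0.70/0.80 by subtype), then an Xi-large deletion
with probability 0.51 (TP53-mutant) or 0.18 (wild type), else an Xa-large
amplification with probability 0.68 / 0.41, else a methylation group
(high 54/280, low 25/280).  These rates are the cohort-level cross-tab
rates the generator emulates.  All remaining parameters are generator
choices — the underlying studies publish no effect sizes, depths or noise
levels — fixed once and listed here:

- **chrX geometry**: 100 abstract 1 Mb bins; PAR1 = first 3 bins, PAR2 =
  last 3 (1-based inclusive segment coordinates, BED half-open peaks).
- **Copy number**: deletion = minor 0 over a contiguous Uniform(0.7, 1.0)
  fraction of bins; amplification = major 2–3 over a similar block, with
  the level stepping between 2 and 3 in 5–20-bin chunks (real
  amplifications are stepwise; a single cohort-wide level would make the
  amplified group two artificial point clouds).  All samples get
  Poisson(0.5) focal events of 1–3 bins.
- **Methylation**: promoter beta ~ Beta(m·c, (1−m)·c), c = 40, with
  probe-level noise (sd 0.03) and 2% missingness.  Means: XCI-subject
  0.47 (0.36 inside open chromatin), escapee 0.10, pulled to 0.15 in
  Xi-deleted and methylation-low samples and 0.80 in methylation-high
  samples; per-gene baseline jitter sd 0.03.  PAR genes always escape;
  15% of other X genes escape.
- **Expression**: per-gene baseline N(8, 1.5²) log2 units, noise sd 0.5;
  deleted bins −1.0, amplified bins +0.8, methylation-high −0.8 and
  -low +0.6 on XCI-subject genes; XIST −2.0 in Xi-deleted and −1.0 in
  TP53-mutant samples.
- **Mutations**: Poisson(3) X-linked mutations per sample, classes
  Missense/Nonsense/Splice_Site/Silent at 0.6/0.1/0.1/0.2, depth
  Poisson(40), alt ~ Binomial(depth, p) with true p ∈ {1, 0.5, 0} at
  frequencies 0.8/0.1/0.1 in Xi-deleted and 0.4/0.25/0.35 in other
  samples (planting the ~2x expressed fraction).  TP53-mutant samples
  carry one TP53 mutation with p = 0.95 under any large CN aberration
  (LOH) and 0.5 otherwise.
- **Survival**: hazard = 0.05 · exp(log 3 · aggressiveness) per year,
  exponential by default (Weibull via config) — the simplest model
  satisfying proportional hazards, so Cox recovery is well-posed.
  Aggressiveness = 1.0·XiDel + 0.7·XaAmp + 0.5·methHigh + 0.4·methLow +
  0.2·TP53mut.  Censoring: administrative at 25 years plus, for a 0.3
  fraction of samples, an independent Uniform(0, 25) drop-out.

One `numpy` Generator seeded from the config drives everything; the same
(config, seed) produces byte-identical files.

**What the generator does not emulate**: autosome-wide copy number,
subclonal mixtures and purity, probe cross-reactivity and normalisation
artefacts, expression count noise (values are Gaussian on the log scale),
linkage between neighbouring genes beyond shared bins, and any realistic
correlation structure between subtype and expression baseline.  Passing
tests therefore demonstrate that the pipeline recovers structure of this
planted form at these effect sizes — not that it would recover weaker or
confounded structure in real tumours.

## Numerical and design notes

- Problem sizes: cohort recovery studies run at n = 200–400 samples, the
  default simulated cohort at n = 1000 (the scale of the cohorts being
  emulated), Cox recovery at 100 replicates of n = 1000, null
  calibrations at 200 replicates.
- The four signature scores are evaluated on the full cohort.  Because
  every aberration class raises the planted hazard while deletion and
  amplification shift expression in opposite directions, the
  amplification ("up") signature can show an inverted per-unit hazard
  ratio on fully synthetic cohorts: the most aggressive (Xi-deleted)
  samples sit at the low end of its score.  This confounding is a
  property of evaluating any single-direction score on a cohort with
  several planted aberration classes, and is reported as computed.
- Percentage rounding is round-half-up everywhere (`floor(x + 0.5)`), the
  convention most printed cohort tables follow; Python's banker's
  rounding would send exact .5 cases down half the time.
- Degenerate inputs are first-class: identical samples collapse a
  clustering tier to "unaltered" with a warning; empty signatures warn
  and propagate; constant scores, event-free cohorts and all-zero
  contingency margins raise informative errors.
- Known limitations: the cascade's k is fixed (2/2/3) rather than chosen
  by a stability criterion; the minor-allele Xi proxy cannot distinguish
  which parental X was silenced; RMAF classification ignores mapping bias
  and purity; survival models carry no clinical covariates beyond the
  score (by design — the evaluation isolates the signature).
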