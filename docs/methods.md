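# Methods

This note documents the models, defaults and numerical choices behind
`aberex`, and what the synthetic-data experiments do and do not demonstrate.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GFF3/GTF (1-based, fully
closed) is converted only at the I/O boundary. Exons identical in
coordinates across transcripts of one gene are merged into a single
canonical exon carrying the union of transcript ids. Genes whose spans
overlap on the same chromosome *and strand* are aggregated into one counting
group (underscore-joined id) before flattening, mirroring the behaviour of
standard exon-bin preprocessing for differential exon usage; cross-strand
overlap does not aggregate, because splice-side assignment is
strand-specific. The biotype attribute key is configurable (`gene_type` /
`gene_biotype` dialects both occur in the wild).

## Novel-region derivation

A junction end is *canonical* when it coincides with a same-strand exon
boundary of the matching splice side (acceptor = exon start on the plus
strand, exon end on the minus strand; donor mirrored). Junctions are kept
when the strand is defined, the aligner did not mark them annotated, at
least `min_samples` (default 2) samples support them with
`min_unique_reads` (default 3) uniquely-mapped reads — `SJ.out.tab` files
contain alignment noise and no noise filter is inherent to the format — and
at least one end is non-canonical.

Each non-canonical end is assigned to the nearest canonical exon whose
matching boundary lies within `max_distance` (default 500 nt; cryptic
SF3B1-class acceptors sit tens of nt from the canonical site, and an
unbounded search would capture deep-intronic noise). A site on the intronic
side of the boundary yields an *extension* region; a site strictly inside
the exon yields a *shortening*. A site beyond the exon's far end fits
neither geometry and yields nothing for that exon. An end that exactly
matches any canonical boundary of its side emits nothing (it must not be
re-assigned to a neighbouring exon of, say, an overlapping gene). Ties at
equal distance prefer an exon of a gene that already owns the junction's
canonical other end, then the lexicographically smallest gene id. Regions
identical in coordinates and class from different junctions are merged with
support summed.

## Flattening

Portion boundaries are the sorted union of all canonical-exon and
novel-region endpoints of a group; every covered cell between consecutive
boundaries becomes one bin. A bin inside a novel region and outside every
canonical exon is labelled `novel_acceptor`/`novel_donor`; a bin overlapping
any canonical exon is `canonical` even if a novel region also covers it
(novelty is reserved for sequence absent from the canonical annotation —
this is why only extensions, not shortenings, produce novel bins;
shortenings still create the bin boundaries that let the usage test see
them). Unit and acceptance tests check the flattening against a per-base
brute-force labeller on random instances.

## Counting

Only primary alignments count (FLAG 0x100/0x800 excluded); duplicates count
by default. A fragment (mates merged by query name) adds 1 to every portion
one of its aligned blocks overlaps by ≥ 1 base — sibling bins must compete
for boundary-spanning reads for the usage design to work — and at most 1 to
a gene (union of its exons). Reads spanning two genes count toward both by
default (`multigene=False` disables). Counting is unstranded.

## Differential gene expression

Per-gene NB log-link GLM of counts on condition plus categorical covariates,
with `log(size factor)` offsets. Size factors are median-of-ratios (per
sample, the median of count / geometric row mean over rows with no zero;
an all-positive-row-free matrix falls back to positive-subset medians with a
warning). Dispersions: per-row method-of-moments on normalized counts,
`alpha_raw = (var - mu * mean(1/sf)) / mu^2`; a least-squares fit of the
trend `alpha(mu) = a0 + a1/mu` on rows with `mu >= 1` and positive raw
estimates (one 3-sigma trimming pass); the working value is the geometric
mean of raw and trend (trend alone when the raw moment is non-positive),
floored at 1e-8 and capped at 10. The Wald statistic is the condition
coefficient over its standard error with a two-sided normal reference
(large-sample); BH adjustment runs over tested (non-all-zero) genes only.
Shrunk fold changes are the posterior mode under a zero-centred normal prior
on the condition coefficient whose scale is the MAD of the MLE estimates —
this captures the ranking intent of heavier shrinkage machinery with a
simple, testable estimator.

Null simulations at n = 8+8 put the empirical type-I error at nominal 0.05
slightly low (≈ 0.035–0.042 across seeds; ≈ 0.055 if the generator's true
dispersion trend is supplied), i.e. the moment-based dispersion estimate
makes the test mildly conservative at small n. The DEU test below is
calibrated more tightly because its dispersions pool more structure.

## Differential exon usage

For each portion the response is the stacked two-row profile per sample —
this bin's count and the sum of the group's other bins — with offset
`log(group total)`, and design {intercept, condition, bin, bin×condition}.
The interaction estimate / ln 2 is the usage log2 fold change (under this
model it coincides with the log odds-ratio of the bin's usage between
conditions). Fitting uses a small IRLS NB-GLM in which the dispersion varies
with the fitted mean: the bin rows use the bin-level trend, the sibling-sum
rows a second trend estimated on the sum profiles. This matters: a sum of k
bins has effective dispersion ≈ alpha/k, and borrowing the bin-level value
for the sum row overestimates its variance enough to push type-I error to
0.016–0.029; with the dual trend the null simulation sits at ≈ 0.044–0.054
(n ≈ 2400 bins, n = 8+8). Each row class's trend is rescaled per portion by
its shrunk-to-trend ratio (clipped to [0.25, 4]) to retain row-specific
dispersion scatter. Groups with a single bin or a zero group total in any
sample are reported untested (NA), and NAs are excluded from the BH
denominator.

Both tests default to "test level = first condition level encountered", so
fold changes are mutant-over-wildtype when mutant samples come first.

## Enrichment

Genes with mean normalized count ≥ 1 (reduces rank ties among low-coverage
genes) are ranked by Wald statistic, ties broken by gene id. The enrichment
score is the weighted Kolmogorov–Smirnov running sum with hit increments
proportional to |stat| (weight exponent 1) and uniform miss decrements;
the vectorized permutation evaluates the walk only at hit positions, where
its extrema lie. Significance uses gene-label permutations preserving set
size: `p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #same-sign perms)`,
`NES = ES / mean |same-sign ES_perm|`, BH across sets. Default
`n_perm = 10,000` (100,000 is available by flag but unnecessary at toy
scale). ENTREZ→ENSEMBL style id translation is a static two-column mapping;
unmapped members are dropped from their sets.

## Clinical statistics

PFS is the interval from treatment to metastasis or disease-specific death,
whichever is earliest; loss to follow-up, death from another cause and death
of unknown cause censor at the last known time. Stratification at 60 months:
event before the cutoff → early; at risk at the cutoff (with or without a
later event) → late; censored before the cutoff → unclassifiable. The three
strata partition every valid observation.

Kaplan–Meier estimation (product-limit, Greenwood variance, log-log CI,
median = smallest t with S(t) ≤ 0.5, median CI from the CI curves crossing
0.5) is delegated to lifelines. The r×c Fisher test enumerates every
non-negative integer table with the observed margins recursively in log
space; the two-sided p sums the probabilities of tables no more probable
than the observed one, with a 1e-7 relative tolerance for floating-point
ties (all-zero rows/columns are dropped first; a single-row/column table has
p = 1). Rows recorded as "Data not reported" are excluded before testing —
with them included the reference 3×2 metastatic-location table would not
reproduce its published p = 0.510. Continuous variables use the pooled-
variance Student t (Welch by flag), also computable from summary statistics.
Wilcoxon rank-sum is exact for combined n ≤ 20 without ties, otherwise the
tie-corrected normal approximation.

qPCR: ΔCt = mean Ct(reference) − mean Ct(target), so a target amplifying
later than the reference (lower expression) gives a negative ΔCt — the sign
convention is chosen to match the negative group means the validation data
report; ΔΔCt subtracts the control sample's ΔCt and the fold change is
2^ΔΔCt. IRS: staining-intensity class (0–3) × stained-cell-percentage class
(0 % → 0, < 10 % → 1, 10–50 % → 2, 51–80 % → 3, > 80 % → 4), range 0–12.

## Synthetic-data generator

Each sub-generator draws from its own seed-derived stream
(`default_rng([seed, stream])`), so a fixed seed reproduces every artifact
byte-for-byte and the truth tables make sensitivity/FDR of every detector
computable without re-deriving labels.

* **Annotation** — multi-exon genes (4–8 exons of 100–300 nt, introns
  300–1200 nt) alternating strands on one synthetic chromosome; ~10%
  pseudogene biotypes to exercise the exclusion rules; one same-strand
  overlapping gene pair to exercise aggregate grouping.
* **Junctions** — every sample sees all canonical junctions (NB support,
  mean 30 reads); mutant samples additionally see novel acceptor junctions
  offset Uniform{10..30} nt upstream of selected canonical exon starts
  (strand-respective; the characteristic cryptic 3′ splice-site range for
  this mutation class), NB support with mean 20; a few undefined-strand
  noise junctions per sample exercise the filters.
* **Bin counts** — group depth log-normal (median 1000, floored at 500);
  novel bins carry a baseline usage fraction Uniform(0.01, 0.04) of the
  gene's output — cryptic sites carry a small share of output in baseline
  samples — multiplied by 2^2 in mutants and renormalized; canonical bins
  share the remainder via a Dirichlet draw; NB noise on the trend
  α(μ) = 0.02 + 2/μ with library-size (Uniform 0.7–1.3) and alternating
  batch multipliers. Planting necessarily depresses sibling fractions by the
  renormalization (≈ −log2(1 + 3u)); with the default small u this stays
  well below the 0.5 significance threshold.
* **Gene counts** — 2000 genes, log-normal baseline means (median ≈ 100),
  10% DE with log2FC = ±Normal(1, 0.25), batch shifts 2^Normal(0, 0.3) on
  30% of genes, same NB trend.
* **Cohort** — 146 patients; a third early-onset (metastasis time from a
  Weibull with median ≈ 40 months truncated below the 60-month cutoff), the
  rest late (median ≈ 130 months, truncated above the cutoff; 40%
  eventually metastatic, the remainder followed without an event); uniform
  censoring applied to 30% of patients when the censor draw precedes the
  latent time. LTD ~ Normal(17.7, 2.8) mm early vs Normal(14.7, 3.7) late;
  ΔCt ~ Normal(−5.38, 0.25) vs Normal(−4.14, 1.13) with triplicate Ct
  replicates (0.1 cycle noise) around a ~20-cycle reference; IRS ~ clipped
  Normal(1.34, 0.82) vs Normal(2.64, 2.14). Group-specific location/scale
  parameters follow the stratified-cohort summaries of the clinical domain
  this package models.
* **Reads** — an optional toy SAM writer places single-end reads in exon
  bodies (with a fraction duplicated as secondary alignments) to exercise
  the counting module without binary fixtures.

What the generator does *not* emulate: real exon/intron length and GC
structure, sequence content, alignment artefacts, isoform-level correlation
between bins, overdispersed junction-support noise correlated with
expression, non-uniform censoring, or cohort heterogeneity beyond a single
batch factor. Passing the recovery experiments therefore demonstrates the
*algorithmic* correctness and statistical calibration of the chain on data
matching the model's assumptions, not performance on real tumors.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale sizes chosen to make
Monte-Carlo bands tight enough to be informative: ≥ 2000 rows for null
calibration (99% binomial band ±0.013 at α = 0.05), 120 genes (~30 planted
events) for recovery, 2000 genes for power. All stochastic steps take
explicit seeds; reruns are bit-identical on the same software stack.

## Known limitations

* The Wald tests use the large-sample normal reference; at n = 8+8 the DGE
  test runs mildly conservative (see above). No outlier handling (Cook's
  distance) or independent filtering is applied.
* The exact Fisher enumeration is exponential in table size; it is intended
  for the small contingency tables of clinical comparison (a 3×2 table
  with n = 27 enumerates instantly, large tables should use asymptotic
  tests instead).
* Junction support is simulated as `SJ.out.tab` summaries; the toy SAM
  writer generates exon-body reads, not junction-spanning reads, so
  counting and junction analysis are exercised by separate fixtures.
* Transcript-model reconstruction, exon skipping, intron retention, novel
  cassette exons, fusion/trans-splicing junctions, Cox regression and CNV
  analysis are out of scope.
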