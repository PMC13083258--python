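# Methods

This note documents the models, conventions and numerical choices behind
`rnuscan`. The package implements a discovery pipeline for recessive
disorders of small non-coding genes — worked out for the U2 snRNA paralog
U2-2, a 191-nt single-exon locus — together with a synthetic cohort
generator that supplies every input the pipeline consumes, so the whole
analysis can be run and validated without access-controlled cohort data.

## Biallelic genotype model

A candidate recessive genotype is either a rare homozygous variant or a
pair of rare heterozygous variants in trans (compound heterozygous). The
pipeline applies three variant-level rules before enumeration:

- **FILTER = PASS.** Non-PASS VCF records produce no calls.
- **Rarity.** Population allele frequency strictly below `max_af`
  (default 0.001). The boundary is exposed (`inclusive=True` keeps
  AF == 0.001) because "below 0.001" and "above 0.001 removed" differ at
  exactly the threshold; the default is the strict predicate. Missing
  frequencies are an error by default; a permissive mode treats them as 0
  with a warning.
- **Coordinates.** All positions are 1-based transcript coordinates.
  Indels are anchored at their most 5' coordinate, and region membership
  (the 5' constrained region n.1–n.67 and the Sm site n.97–n.107) is
  decided on that anchor.

Every unordered pair of rare heterozygotes in a sample is a compound-het
candidate; only trans pairs (and homozygotes) are *confident* biallelic
genotypes. The unordered variant set is the combination key used for
cross-cohort filtering: a case genotype is dropped when the identical
combination occurs as a biallelic genotype in any control source. For the
variant-position distribution analysis a genotype is eligible only when
every allele lies entirely inside the transcript and each variant is an
SNV or an indel with net length change ≤ 2 nt (the net change
|len(ref) − len(alt)| was chosen over allele span; the alternative reading
of "less than 3 nt" is noted here as a deviation risk).

The region constraint used for validation-cohort expansion applies to
compound heterozygotes by default, with homozygotes passing
unconditionally; `include_homozygous=True` subjects them to the same rule,
matching the stricter protocol some validation cohorts used.

## Read-backed phasing

Statistical phasing is taken from `|`-separated genotypes (plus the PS
phase-set tag when present). Read-backed phase for a pair of het sites
follows the read-exclusivity rule: **cis** when ≥ `min_spanning` reads
carry both alternate alleles; **trans** when the alternate alleles occur
only on mutually exclusive reads, each seen at least once, with
≥ `min_spanning` reads traversing both positions; **unknown** otherwise.
Reads are pre-filtered at mapping quality strictly greater than 30.
Paired-end mates sharing a fragment are merged into one observation, so a
fragment whose mates jointly cover both sites spans the pair.

The original rule was applied by eye and tolerates no conflict; the
default `max_conflict_fraction` is therefore 0 (any contradicting spanning
read yields unknown) and can be raised for noisy simulations.
Reconciliation lets read evidence override statistical phase wherever both
are known, counts each disagreement as one phase-switch error, keeps
statistically phased pairs with unknown read phase (flagged unconfirmed),
and conserves the total pair count. Reconciling twice with the same
evidence is a no-op.

## Enrichment statistics

Per-gene enrichment uses a carriers vs non-carriers 2×2 table per gene and
a two-sided Fisher's exact test (point-probability convention: the sum of
hypergeometric probabilities of tables no more probable than the observed
one). Only genes with at least one carrier in either cohort are tested,
and the Bonferroni threshold is α divided by the number of genes actually
tested — 0.05/774 = 6.46 × 10⁻⁵ in the configuration matching the
discovery scan. The odds ratio defaults to the cross-product ad/bc with a
Woolf log-scale normal interval; the conditional-MLE estimator is
available behind a flag because published cohort ORs may reflect either
(and the package does not attempt to match published confidence
intervals, whose estimator is unstated). Tables with a zero cell can be
summarized with the Haldane–Anscombe correction (0.5 added to every cell),
which keeps the OR and its interval finite; phenotype-frequency
comparisons use it with 90% intervals. Benjamini–Hochberg adjustment is
the standard step-up procedure via statsmodels.

## Transmission analysis

A dual-carrier trio has both parents heterozygous for exactly one rare
variant each (parents with two or more rare variants, or homozygous, are
excluded). Outcomes are both / one / neither allele transmitted; under
Mendelian segregation the probabilities are (¼, ½, ¼) in both the
same-variant and different-variant strata, verified in code by exhaustive
enumeration of the four parental gamete combinations. Offspring genotypes
impossible under the parental genotypes (e.g. homozygous for a variant
only one parent carries) are excluded rather than counted as "neither".
The chi-squared goodness-of-fit test is reported per stratum and pooled.
The published trio P value is not reproduced because its underlying
one/neither category counts are not published.

## Phenotype similarity and enrichment

The ontology is any rooted DAG (OBO subset or child–parent TSV). Term
information content is IC(t) = −ln(annotation frequency) over
ancestor-propagated profiles of the reference population, so IC(root) = 0
and descendants are never less informative than ancestors. Profile
similarity is symmetric best-match-average Resnik similarity (the IC of
the most informative common ancestor), and a group's homogeneity statistic
is the mean pairwise similarity over all unordered pairs. The cited
similarity software's exact defaults are not published with formulas, so
this statistic is re-specified here and is a known deviation risk for
numerical comparability.

The Monte Carlo test draws `n_perm` random same-size subsets of the
population as the null. Tail p values use the add-one convention
(1 + #{null ≥ obs})/(n_perm + 1); the two-sided p doubles the smaller tail
and caps at 1, so its floor is 2/(n_perm + 1) — 0.002 at 1,000
permutations. Term enrichment between cohorts is computed on the
non-redundant antichain (terms that are proper ancestors of other
annotated terms are removed), with presence evaluated on propagated
profiles, Fisher tests per term and BH adjustment; terms observed nowhere
or in everyone are untestable and skipped. Phenotype-matrix PCA codes
missing values as absent, drops constant columns and scales the remainder
to unit variance (toggleable).

## Expression ratio biomarker

Abundance is normalized as reads per million unique reads on the gene's
own chromosome (chr11 for U2-2, chr17 for the U2-1 repeat array, whose
counts are accepted pre-summed across copies). The 10⁶ scale factor is a
display choice; the U2-2:U2-1 ratio is scale-free and invariant to
independent library-size changes of the two chromosomes. Rank comparisons
use the Mann–Whitney U test, exact for tie-free pooled samples of combined
size ≤ 20 and the tie-corrected normal approximation otherwise.

The expression-outlier caller included here is a deliberately simple
robust z on ln(RPM + 1) (median/MAD with the 1.4826 consistency constant,
flag at |z| ≥ 3, nothing flagged when the MAD is 0); it is labelled as
such in its output and is **not** the published autoencoder-based method,
whose internals are out of scope. The shared-splicing test consumes
Boolean event × sample outlier matrices from any upstream caller: the
statistic is the number of events flagged in more than one case (counted
once per event however many cases recur), the null re-draws equal-size
control subsets, and the two-sided percentile-bootstrap p (same doubling
and floor conventions as above) is Bonferroni-corrected over the eight
aberrant-splicing event classes.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline targets,
not tuning knobs:

- **Locus and variants.** 191-nt single-exon locus; 40 variants with
  allele frequencies log-uniform on [10⁻⁵, 10⁻²], so the 0.001 rarity
  filter is exercised on both sides (about two-thirds of variants are
  rare); 15% indels; 5% of variants fail FILTER.
- **Genotypes.** Haplotypes carry background variants at their allele
  frequencies plus injected biallelic genotypes: prevalence 0.02 in
  controls, multiplied by the enrichment factor (default 5) in cases; 69%
  of injected biallelics are compound-het (matching the 75:33 confident
  split), the rest homozygous; dual-het cis pairs are injected at
  prevalence 0.02 so the cis:trans mix resembles the observed 114:76.
  The truth ledger is derived from the realized haplotypes, so it agrees
  exactly with the emitted VCF even when background draws create
  unplanned biallelic genotypes.
- **Phasing.** Emitted genotypes are fully `|`-phased; dual-het samples
  have one variant's haplotype assignment flipped with probability 0.08
  (the observed switch-error rate, 15/190) and the corrupted pairs are
  recorded.
- **Reads.** Simulated fragments alternate haplotypes, span both sites
  with probability 1 by default (a short-read fragment essentially always
  traverses two positions of a 191-nt locus; lower it to emulate partial
  coverage) and flip alleles at the configured base-error rate. With
  clean reads and depth ≥ 2 phase classification is deterministic, which
  is what the 100%-recovery acceptance check relies on.
- **Trios.** Parents are clean single-het carriers; offspring genotypes
  come from explicit per-parent Bernoulli gamete draws with success
  probability √p_both, so the default p_both = ¼ reproduces Mendelian
  (¼, ½, ¼) and larger values emulate ascertainment-driven
  over-transmission.
- **Phenotypes.** A generated DAG of 50 terms (1–2 parents each, depth
  ≈ 5) keeps brute-force similarity oracles feasible; cases draw a
  configurable fraction (default 0.8) of their 3–6 terms from a fixed
  8-term leaf cluster, controls draw uniformly.
- **Expression.** U2-2/U2-1 counts are negative-binomial (dispersion 25)
  around means scaled by a shared log-normal latent factor; the latent
  scale is solved by bisection from a closed-form count-correlation
  expression so the sample Pearson correlation matches the 0.83 target.
  Base means (1,514 and 1,456 on chromosome totals of 2 × 10⁶) give
  control RPMs near 760 and a control ratio near 1.04; depleted cases
  have the U2-2 mean multiplied by 0.5. Nine cases vs 300 controls mirror
  the transcriptomic cohort's shape.

Everything is deterministic under the configured seed.

What the generator does **not** emulate: linkage disequilibrium and
population structure, genotyping error, sequence-level reads (FASTQ) and
alignment artefacts, relatedness beyond the explicit trios, real HPO
depth/breadth, and expression batch effects. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated generative model, not robustness to those real-data
complications.

## Problem sizes used in validation

The calibration and recovery suites run at sizes chosen to make Monte
Carlo tolerances meaningful while keeping the default validation runs
quick: the Fisher implementation is checked against integer-arithmetic
enumeration on every non-degenerate 2×2 table with total ≤ 60 (one
representative per symmetry orbit); scan family-wise calibration uses 200
null replicates of a 50-gene cohort (500 cases / 2,000 controls);
transmission type-I uses 2,000 replicate sets of 50 trios; enrichment
recovery uses 3,000 cases / 12,000 controls; depletion recovery uses the
9 vs 300 expression design, estimated from the case:control ratio-of-means
of the ratio biomarker (which cancels the shared latent factor — the same
argument that makes the ratio a better biomarker than raw abundance);
correlation recovery uses 5,000 samples; similarity null uniformity uses
100 replicates at 99 permutations.

## Known limitations

- Printed cohort ORs/CIs and the trio and similarity P values that depend
  on unpublished per-category counts or term profiles are intentionally
  not reproduced; the acceptance layer covers the self-contained printed
  quantities and the property suites instead.
- The exact-test p follows the point-probability convention; software
  using tail-doubling conventions will differ on asymmetric tables.
- Multi-allelic VCF records are handled by simple per-allele splitting;
  no liftover, no structural variants.
- The robust-z outlier caller is a stand-in; its flags should not be
  compared numerically with autoencoder-based callers.
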