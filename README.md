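# rnuscan

Discovery pipeline for recessive disorders of small non-coding genes,
worked out for the U2 snRNA paralog **U2-2** — a 191-nt single-exon locus
whose biallelic variants cause a developmental and epileptic
encephalopathy. The package is aimed at statistical geneticists working in
protected cohort environments (where genotype, trio, phenotype and
transcriptome tables are accessible but raw data cannot leave) and at
anyone who wants to validate this class of analysis end to end on
synthetic data.

It implements, as a tested reusable library with a thin CLI:

- **Biallelic genotype calling** — PASS-filtered VCF ingestion, rarity
  filtering at allele frequency < 0.001, enumeration of homozygous and
  compound-heterozygous (trans) candidates, cross-cohort combination
  filtering, and the 5' constrained-region (n.1–n.67) / Sm-site
  (n.97–n.107) constraint.
- **Read-backed phasing** — cis/trans classification from mutually
  exclusive reads (mapping quality > 30, at least one read traversing both
  sites) reconciled against statistical phasing to detect phase-switch
  errors.
- **Enrichment statistics** — two-sided Fisher's exact tests on
  carriers-vs-non-carriers 2×2 tables per gene with Bonferroni control
  over the tested genes (α/m), cross-product odds ratios with Woolf
  intervals, the Haldane–Anscombe zero-cell correction, and
  Benjamini–Hochberg FDR adjustment.
- **Trio transmission** — dual-carrier trio discovery and a chi-squared
  goodness-of-fit test of both/one/neither allele transmission against the
  Mendelian (¼, ½, ¼) ratios, per stratum and pooled.
- **Phenotype similarity** — information-content-weighted (Resnik,
  best-match-average) profile similarity on an HPO-like DAG with a Monte
  Carlo permutation null, redundancy-aware per-term enrichment, and
  Boolean phenotype-matrix PCA.
- **Expression-ratio biomarker** — chromosome-normalized reads-per-million
  quantification, the U2-2:U2-1 ratio (depressed values mark the recessive
  disorder), Mann–Whitney comparisons, Pearson/OLS fits, a simple robust-z
  outlier stand-in, and a percentile-bootstrap test for splicing-outlier
  events shared across cases.
- **A synthetic cohort generator** with a truth ledger, so every stage
  runs and is validated with no external data (see `docs/methods.md` for
  the generative model and its limits).

## Worked example

Generate a cohort of 1,000 unsolved-NDD cases, 4,000 controls and 50
dual-carrier trios with a five-fold biallelic enrichment in cases, then
run the main stages:

```python
import rnuscan as r

cfg = r.SimulationConfig(seed=42, n_cases=1000, n_controls=4000,
                         n_trios=50, case_enrichment_factor=5.0)
sim = r.simulate_locus_cohort(cfg, out_dir="demo")   # VCF, PED, TSVs, truth.json

calls = sim.to_calls()
rare = {s: r.filter_rare_variants(c.values(), sim.af_table)
        for s, c in calls.items()}
rare = {s: v for s, v in rare.items() if v}

genotypes = r.enumerate_biallelic_genotypes(rare)
confident = [g for g in genotypes if g.is_confident]
n_hom = sum(g.genotype_class == "homozygous" for g in confident)
print(f"confident biallelic genotypes: {len(confident)} "
      f"({n_hom} homozygous, {len(confident) - n_hom} compound het)")

carriers = {g.sample for g in confident}
cases = {s for s, a in sim.assignments.items() if a.group == "unsolved_NDD"}
k_case, k_ctrl = len(carriers & cases), len(carriers - cases)
n_case, n_ctrl = len(cases), len(sim.assignments) - len(cases)
print(f"carriers: {k_case}/{n_case} cases vs {k_ctrl}/{n_ctrl} controls")
res = r.fisher_exact_2x2((k_case, n_case - k_case, k_ctrl, n_ctrl - k_ctrl))
print(f"Fisher OR = {res.odds_ratio:.2f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), p = {res.p:.3g}")

cohort = r.Cohort(variants=sim.variants, calls=calls,
                  assignments=sim.assignments, trios=sim.trios)
trios = r.find_dual_carrier_trios(cohort, rare)
pooled = r.count_transmissions(trios, rare)["pooled"]
test = r.transmission_test(pooled)
print(f"dual-carrier trios: {len(trios)}; "
      f"both/one/neither = {pooled.both}/{pooled.one}/{pooled.neither}")
print(f"chi-squared GOF statistic = {test.statistic:.2f}, "
      f"df = {test.df}, p = {test.p:.3f}")

counts, depleted = r.simulate_expression(r.SimulationConfig(seed=42))
table = r.quantify_expression(counts)
case = table["sample_id"].map(depleted)
p = r.mann_whitney_two_tailed(table.loc[case, "ratio"],
                              table.loc[~case, "ratio"])
print(f"mean U2-2:U2-1 ratio cases {table.loc[case, 'ratio'].mean():.2f} "
      f"vs controls {table.loc[~case, 'ratio'].mean():.2f}; "
      f"Mann-Whitney p = {p:.3g}")
```

Output:

```
confident biallelic genotypes: 188 (58 homozygous, 130 compound het)
carriers: 101/1050 cases vs 84/4100 controls
Fisher OR = 5.09 (95% CI 3.78-6.85), p = 1.16e-25
dual-carrier trios: 50; both/one/neither = 9/28/13
chi-squared GOF statistic = 1.36, df = 2, p = 0.507
mean U2-2:U2-1 ratio cases 0.47 vs controls 1.09; Mann-Whitney p = 6.45e-07
```

Reading the numbers: the carrier odds ratio recovers the injected
five-fold case enrichment and is overwhelmingly significant at this cohort
size; the trio test is null because the generator's default transmission
probability is the Mendelian ¼ (9/50 ≈ 12.5/50 expected); and the
expression ratio separates depleted cases (injected depletion factor 0.5,
observed mean ratio 0.47) from controls (mean 1.09) even with only nine
cases.

The same stages are available from the shell:

```bash
rnuscan simulate --seed 42 --out-dir demo
rnuscan call --vcf demo/cohort.vcf --ped demo/cohort.ped \
    --groups demo/groups.tsv --af demo/af.tsv --out demo/genotypes.tsv
rnuscan transmit --vcf demo/cohort.vcf --ped demo/cohort.ped \
    --groups demo/groups.tsv --af demo/af.tsv --out demo/transmission.json
```

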