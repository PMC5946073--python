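# Methods

This note documents the statistical procedures implemented in `episyn`,
the choices made where the design was genuinely open, and the limits of
what the synthetic-data experiments demonstrate.

## Data model

A study is a subjects × SNPs matrix of minor-allele counts (0/1/2) with a
reserved missing sentinel (never 0, which would silently inflate
reference homozygotes), a case/control phenotype (case = long-lived),
sex, and — for cases — censored follow-up in months from recruitment.
Accepted missing tokens are `NA`, empty, `-9`, `.`. Files are plain TSV
or PLINK `.raw`-style additive recodings (phenotype 1 = control,
2 = case). All SNPs are treated as autosomal-diploid; hemizygous
X-chromosome coding in males is not modelled. Minor-allele recoding at
load time is available (`recode_minor=True`) but off by default so that
write→read round-trips are exact even for columns whose within-sample
frequency drifts above 0.5 after subsetting.

## Marker QC

Order of operations: call rate (< 90% observed → drop; configurable
guard, since modal imputation degrades on highly missing markers), MAF
< 5% over the whole sample (controls-only optional; the original choice
in such studies is usually unstated), Hardy–Weinberg exact test in
**controls only** at p < 0.001 (testing in cases can discard true
association signals), then greedy within-chromosome pruning. The HWE
test is the conditional exact test: given the allele counts, the
two-sided p-value sums the probabilities of all heterozygote counts no
more probable than the observed one (stable recurrence; verified against
a log-gamma enumeration oracle to 1e-12).

Pruning treats r² between unphased SNPs as the squared Pearson
correlation of genotype codes over pairwise-complete subjects (the
standard composite surrogate predating phasing). SNPs are processed in
descending MAF (SNP id as tie-break, so column order cannot change the
retained count); a SNP conflicts with an already-retained tag when
r² ≥ 0.8 or their map distance is < 60 bp. A LOD-based tagging criterion
(as in Haploview-style selection) is deliberately not re-implemented;
only r² and distance are enforced.

## Information-theoretic synergy screen

All entropies are plug-in estimates in bits (base configurable; every
identity used downstream is base-invariant). No small-sample bias
correction is applied by default — screened values are plug-in, matching
how such screens are usually reported — but a Miller–Madow option
exists. Each pair is analysed on its own pairwise-complete subjects
(listwise within the pair, maximising n per pair); `n_used` is recorded
per record, and pairs under 30 complete cases are rejected.

The permutation statistic is Syn itself, one-sided in the synergistic
direction (selection is explicitly about synergy; a redundancy-direction
option would be the mirror image). One shuffled phenotype per replicate
is applied to **all** pairs: this preserves the inter-pair dependence
structure that the Benjamini–Yekutieli step-up (harmonic-sum factor
c(m) = Σ 1/i) is designed to survive, and makes runs reproducible;
per-pair independent streams are available by flag.
p = (b+1)/(n_perm+1). Adaptive early stopping freezes pairs whose
running estimate exceeds 0.2 after 200 replicates (full n_perm is
honoured for pairs still in contention), keeping full panels
desk-tractable; `n_perm=0` skips permutations entirely, which suffices
for ranking because the ranking depends only on Syn.

**Resolution caveat.** With per-pair permutation p-values the smallest
attainable value is 1/(n_perm+1); after BY adjustment over m pairs,
clearing a q < 0.005 threshold requires roughly n_perm > m·c(m)/0.005
(millions of replicates for a thousand-pair panel). Published screens
that report q < 0.005 at p < 1e-4 necessarily derive finer p-values
(e.g. from pooled null distributions). The network-construction stage
therefore takes its thresholds as parameters, and the composition tests
validate the partition bookkeeping (intra-gene / intra-pathway /
inter-pathway counts, residual-LD flags on intra-gene edges) rather than
threshold attainment.

## MDR

Cell labelling: a non-empty cell is high-risk iff its case:control ratio
is ≥ T (the overall ratio), with cells containing cases but no controls
high-risk and ratio-equal-to-T labelled high-risk (the ≥ convention of
the reference MDR implementation). Zero-subject cells are `empty`;
subjects falling into cells empty at labelling time are excluded from
balanced-accuracy evaluation (an "assign low-risk" policy is available).
Brute force over all 2⁹ labelings on random 2-SNP tables confirms the
ratio rule attains maximal training balanced accuracy.

Cross-validation is stratified (case:control ratio preserved per fold)
and seeded; fold winners are selected by **training** balanced accuracy,
with mean **testing** balanced accuracy as the tie-breaker and the
permutation statistic — the classical MDR convention where the selection
metric is not otherwise pinned down. The permutation test reruns the
entire search on each shuffled phenotype and compares the null
distribution of the top model's mean testing BA with the observed value.
Reported models need CVC ≥ 2 and full-data training BA > 0.5. Exhaustive
3-locus search is gated behind candidate lists or panels ≤ 150 SNPs.
Missing genotypes are imputed globally (pre-split) with the per-SNP
modal genotype, ties toward the lower code — the global-replacement
behaviour of the standard MDR data tool.

Interaction dendrograms use average linkage on the distance
max|Syn| − |Syn|, so strongly interacting pairs join first whether the
interaction is synergistic or redundant — matching the convention of MDR
interaction dendrograms, where tightly clustered markers may be linked
by redundancy (negative entropy) as well as synergy.

Carrier distillation: when a model's high-risk cells factor into
per-locus conditions (exact genotype, minor-allele carrier {1,2},
major-allele carrier {0,1}, or any), the compact combination is emitted;
otherwise the explicit cell list is retained (pure-epistasis
checkerboards are the canonical non-factoring case). Odds ratios are
cross-product ratios of the carrier × phenotype 2×2 table with Woolf
log-scale 95% CIs and a logged Haldane 0.5 correction on empty cells.

## Survival follow-up

Time origin is recruitment; zero follow-up times are offset to 0.5
months (logged) since the product-limit estimator is undefined at t = 0
events. Kaplan–Meier estimation and the Mantel–Cox log-rank test are
delegated to lifelines. The Cox fit for the single binary carrier
covariate is a Newton–Raphson partial-likelihood maximisation written
in-package because **Breslow** tie handling is the default here
(month-resolution times produce heavy ties; Efron is available by flag)
and is cross-checked in tests against lifelines on tie-free data and a
golden-section likelihood-search oracle. Convergence tolerance 1e-8,
max 50 iterations; monotone likelihoods (all events in one carrier
group) raise with a diagnostic rather than returning a divergent HR.

Survival screening is sex-stratified (male/female) with per-combination
missing-genotype exclusion (logged), significance flagged at α = 0.05
per test with **no multiplicity correction by default** — matching how
such follow-ups are usually reported — with a warning logged and an
optional BY adjustment across all tests run.

## Synthetic data

The generator fills case/control quotas by rejection from a
superpopulation: genotypes are drawn per SNP from Hardy–Weinberg
proportions at a MAF sampled from uniform(0.10, 0.45) (lower bound of
the law clamped ≥ 0.05), the planted model assigns P(case | genotype) on
the log-odds scale (penetrance tables contribute
logit(table) − logit(base rate), so a lone penetrance effect reproduces
its table exactly), and draws are kept until both quotas are met —
mirroring case–control ascertainment. LD blocks are generated by
conditional copying (copy the previous SNP with probability r, sharing
its MAF), which yields genotypic correlation r within the block and
independence across blocks, keeping the analytic oracles tractable.
Survival for cases is exponential with median 36 months, a
per-combination multiplicative carrier hazard, uniform censoring on
(6, 120) months, and times rounded to whole months (deliberately
producing the tie structure the Breslow handling targets). Sex is 71%
female in cases and 50% in controls; per-cell missingness is 1% by
default. The default test-scale panel is 60 SNPs (20 per pathway, 8 SNPs
per gene) with 400 cases / 300 controls; a full-scale 317/260/481 layout
is available.

`analytic_decomposition` computes the exact population-level I1, I2,
I(joint) and Syn implied by a penetrance table, HWE genotype laws, and
the case-control sampling fraction (the composition plug-in estimates
converge to, not the population prevalence). Plug-in estimates on
simulated studies match it within 0.005 bits at n = 50,000.

**What the generator does not emulate:** haplotype-reference realism
(no coalescent ancestry, no long-range LD decay), population
stratification or relatedness, genotyping batch effects,
covariate-driven survival (age, cohort effects), or X-chromosome
dosage. Passing recovery/calibration tests therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to confounding present in real cohort data.

## Problem sizes used in the evaluation experiments

Chosen as the smallest sizes at which the checked properties are
statistically decisive: null calibration uses 40 seeded screens of 10
SNPs × 300 subjects (200 permutations each) for p-value uniformity, and
40 seeded MDR runs of 20 SNPs × 600 subjects (200 permutations each) for
type-I error; recovery uses 25 replicates of a planted XOR penetrance
pair (0.3/0.7, MAF 0.5) in 30-SNP panels with 1000 cases / 1000
controls; hazard-ratio recovery uses 100 seeded cohorts of ~700 female
cases with a planted carrier HR of 0.7. All randomness in an experiment
derives from a single integer seed.

## Known limitations

- Permutation p-value resolution bounds attainable FDR levels (above).
- The exhaustive screen is candidate-panel scale (≲10⁴ SNPs); no
  genome-wide engine.
- No covariate adjustment anywhere (the MDR and survival stages compare
  raw groups); no model-based MDR variants.
- Balanced-accuracy components with an empty class in a CV test fold
  fall back to 0.5 for that component (rare at the intended sample
  sizes); documented tie-breaks are: lower genotype code for imputation
  modes, first-in-order pair for fold-winner ties, SNP id for QC
  pruning ties.
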