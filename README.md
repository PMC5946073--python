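# episyn

Pathway-based SNP–SNP interaction analysis for case–control longevity
studies: an information-theoretic synergy screen with false-discovery-rate
control, multifactor dimensionality reduction (MDR) with cross-validation
and permutation testing, and survival follow-up of candidate genotype
combinations in the long-lived group.

## Who this is for

Candidate-gene association studies of human longevity (and similar
case–control designs) often genotype on the order of 10²–10³ SNPs grouped
into biological pathways — e.g. insulin/IGF-1 signalling (IIS), DNA damage
signalling and repair, and pro/antioxidant response — comparing long-lived
cases (nonagenarians) against middle-aged controls. Single-SNP tests miss
joint effects; `episyn` implements the standard three-stage epistasis
workflow for panels of this scale, plus a synthetic-data generator that
emulates the study design so every stage can be exercised and calibrated
without access to cohort genotypes.

## The statistics at the core

**Synergy (interaction information).** For SNPs $G_1, G_2$ and phenotype
$Y$ (case/control), with $I(\cdot;Y)$ the plug-in mutual information in
bits,

$$\mathrm{Syn}(G_1, G_2) = I(G_1, G_2; Y) - I(G_1; Y) - I(G_2; Y),$$

where the joint term treats the pair as one 9-level genotype.
$\mathrm{Syn} > 0$ means the pair carries information beyond the additive
single-locus null; $\mathrm{Syn} < 0$ means redundancy (typical of
residual LD). Every in-scope pair receives a one-sided permutation
p-value (shared phenotype-shuffle streams across pairs) and a
Benjamini–Yekutieli adjusted q-value, valid under arbitrary dependence.

**MDR.** A $k$-locus model ($k \in \{2,3\}$) pools its $3^k$ genotype
cells into high-/low-risk classes by comparing each cell's case:control
ratio with the overall ratio $T$; the resulting binary classifier is
scored by balanced accuracy. The search is exhaustive over $k$-subsets
inside a seeded stratified 10-fold cross-validation; models are ranked by
cross-validation consistency (CVC) and mean testing balanced accuracy,
and significance comes from full-search reruns on permuted phenotypes.
High-risk cells are distilled into compact carrier combinations
(e.g. "SNP1 homozygote / SNP2 minor-allele carrier") with logistic odds
ratios.

**Survival follow-up.** Carriers vs noncarriers of candidate combinations
are compared within the case cohort, stratified by sex: Kaplan–Meier
curves, the Mantel–Cox log-rank test, and a Cox proportional-hazards HR
(Newton–Raphson partial likelihood, Breslow tie handling).

Marker QC precedes everything: MAF ≥ 5%, Hardy–Weinberg exact test in
controls at p ≥ 0.001, call-rate filtering, and greedy tag pruning of
within-chromosome pairs with genotypic r² ≥ 0.8 or separation < 60 bp.

## Worked example

```python
import episyn as ep
from episyn.synthetic_data import SimConfig, PenetranceEffect, xor_penetrance

# 500 cases / 400 controls, 60 SNPs in three pathways, with a pure-epistasis
# pair (XOR-like penetrance, MAF 0.5 => no marginal effects) planted at loci 0-1
cfg = SimConfig(
    n_cases=500, n_controls=400,
    effects=(PenetranceEffect(loci=(0, 1), table=xor_penetrance(0.3, 0.7),
                              mafs=(0.5, 0.5)),),
    seed=42,
)
study, ann, truth = ep.simulate_study(cfg)
filtered, report = ep.apply_marker_qc(study, ann)
records = ep.screen_pairs(filtered, ann, n_perm=1000, seed=1)
top = records[0]
print(top.snp1, top.snp2, round(top.syn, 4), top.p_perm)

models = ep.run_mdr(ep.impute_missing(filtered), k=2, n_perm=200, seed=2)
m = models[0]
print(m.loci, m.cvc, round(m.test_ba, 3), round(m.odds_ratio, 2))
```

Output:

```
QC kept 60/60 SNPs
rs000000 rs000001 0.0934 0.000999000999000999
('rs000000', 'rs000001') 10 0.671 4.16
```

The planted pair (`rs000000`/`rs000001`) tops the synergy ranking with
Syn = 0.0934 bits and near-zero marginal terms (I1 = 0.0014,
I2 = 0.0007) — the signature of pure epistasis — at the smallest
attainable permutation p (1/1001). MDR selects the same pair in all 10
folds (CVC 10/10) with mean testing balanced accuracy 0.671 and carrier
odds ratio 4.16 (95% CI 3.14–5.50). Note that an adjusted q-value below
stringent thresholds such as 0.005 needs far more permutations than
1000 once hundreds of pairs are screened; see `docs/methods.md`.

The same pipeline runs from the shell:

```bash
episyn simulate --config sim.yaml --out run/ --seed 42
episyn qc --genotypes run/genotypes.tsv --annotation run/annotation.tsv --out run/
episyn synergy --genotypes run/genotypes_qc.tsv --annotation run/annotation.tsv \
    --perms 10000 --out run/ --seed 1
episyn run --config pipeline.yaml --out run/ --seed 42   # all stages + manifest
```

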