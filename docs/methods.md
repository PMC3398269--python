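# Methods

## Overview

`msrhap` searches a dense panel of biallelic SNPs in a candidate region for
subsets ("haplotype patterns") whose haplotypes are associated with a binary
disease phenotype.  Phase is never observed: all statistics are computed
under the EM-estimated distribution of haplotype pairs given the unphased
genotypes.  Two engines share the search machinery:

* **Case-control** — haplotype frequencies and per-individual phase
  posteriors from the classical EM under Hardy-Weinberg proportions;
  association via weighted haplotype logistic regression on posterior-
  expected dosages with a global likelihood-ratio test (LRT).
* **Nuclear families** — a child-compatibility-restricted EM over the
  parents, followed by a weighted transmission/disequilibrium test (TDT)
  over the enumerated family phase configurations.

The stepwise search starts from all SNP pairs, keeps the `nt` best-scoring
patterns (default 300), extends each by one SNP, and repeats until the mean
of the ten best −log10 p values stops improving by more than 10% per step,
a maximum length is reached, or SNPs run out.  Final p values carry a
Bonferroni factor equal to the number of possible patterns up to the final
length, Σᵢ C(n, i); replicated patterns carry a factor equal to the number
of patterns carried into the replication set.

## EM phasing

For unrelated individuals the E-step weights every haplotype pair (k, l)
compatible with individual *i*'s genotype by (2 − δₖₗ)·pₖ·pₗ, and the
M-step re-estimates pₖ from posterior-expected counts over 2N chromosomes.
Missing alleles are marginalized — every completion of a missing allele is
compatible — so no individual is ever dropped and every test within one
dataset uses the same individuals.  Numerical choices:

* Initialization: uniform over the support (the union of haplotypes
  compatible with at least one individual).  Deterministic; with only
  double heterozygotes the uniform point is a stationary saddle of the EM
  map and the algorithm reports the symmetric frequencies — only data or a
  non-uniform start break that tie (covered by a test).
* Convergence: maximum absolute frequency change < 1e-8 (default), cap 500
  iterations; non-convergence is flagged, not raised.  The observed-data
  log-likelihood trace is retained and asserted non-decreasing in tests.
* Haplotypes whose frequency falls below 1e-10 are pruned from the support
  each M-step for numerical hygiene.

For families, EM runs over the parents with a joint (father-pair,
mother-pair) configuration admitted only if every child's genotype is
Mendelian-compatible with some pair of transmitted haplotypes — a hard
restriction, so with entirely uninformative children the estimator reduces
exactly to the unrelated EM on the parents (tested).  On convergence the
per-family configurations are enumerated with weight proportional to the
product of the four parental haplotype frequencies (with the usual 2-δ
heterozygosity multiplicities), normalized to sum to one within each
family; a flag disables the normalization since either convention is
defensible.  When a child is compatible with more than one transmission
assignment under fixed parental phases, the configuration weight is split
uniformly over the distinct compatible transmitted pairs, matching the
uniform Mendelian transmission prior.  A family with no compatible
configuration raises an error naming the family.

## Case-control association

A pattern's haplotypes are pooled before regression: haplotypes with
estimated frequency below the rare threshold (default 5%) are collapsed
into one synthetic predictor, and that pooled column is itself dropped when
its total mass is still below the threshold (the sparse-data guard).  The
most frequent kept haplotype is the baseline.  If nothing clears the
threshold the pattern is skipped with reason `all_rare`.  For composite
analyses that append rare mutation loci to a pattern, `min_keep_freq`
lowers the keep floor (e.g. to 0.001) while the pooled-column drop rule
keeps the 5% threshold.

The global test is the LRT of intercept + dosage columns (+ covariates)
against intercept (+ covariates), chi-square with df = number of dosage
columns.  Nagelkerke R² is computed against the covariate-free
intercept-only null (its standard definition); AIC/BIC refer to the full
model.  Fits use Newton-Raphson logistic regression (statsmodels); a
pattern is skipped with reason `separation` when the fit fails, does not
converge within 100 iterations, or any |β| exceeds 15 — a pragmatic
quasi-separation rule for low-frequency haplotype columns.  Constant
dosage columns skip with `no_variation`.  Per-haplotype effects use a
one-column model with Wald OR, exp(β ± 1.96·se) CI and normal p.

## Family association

For each weighted configuration, every parent heterozygous for haplotype h
(exactly one copy) contributes the configuration weight to T when it
transmitted h to an affected child and to U otherwise; all affected
children contribute (the classical convention for affected-sib families; a
flag restricts to affected children only vs. all children).  The
per-haplotype statistic is (T−U)²/(T+U) on 1 df; OR = T/U; the 95% CI is
the exact (Clopper-Pearson) binomial interval for T successes of
round(T)+round(U) trials mapped to the odds-ratio scale — the "exact
McNemar" interval on nearest-integer counts.  Note: for T:U = 74.0:38.0
this yields ≈1.31–2.97 rather than the 1.40–2.96 sometimes quoted for the
same counts; the exact inversion variant behind the latter (mid-p or a
different tail convention) is not documented anywhere we could verify, so
the standard Clopper-Pearson inversion is implemented and the discrepancy
is noted rather than reverse-engineered.

The pattern-level family statistic is the Spielman-Ewens multiallelic TDT,
((H−1)/H)·Σ (Tₕ−Uₕ)²/(Tₕ+Uₕ) on H−1 df over haplotypes with informative
transmissions (the biallelic reference does not prescribe a multi-haplotype
combination; `minp` mode — the smallest per-haplotype p times H — is
available as an alternative).  With fewer than two informative haplotypes
the single biallelic test is used.

## The stepwise search

Patterns are identified by their sorted SNP set; candidates reached from
several parent patterns are evaluated once, labelled by the first addition
order.  Skipped patterns carry a p = 1 sentinel and rank strictly last;
ties in p break by lexicographic canonical key, making ranked lists and
TSV outputs byte-reproducible.  The stop quantity is the arithmetic mean of
the ten best −log10 p values; step means quoted as probabilities
(e.g. 3.07e-13 at four loci) are read as 10^(−mean), i.e. geometric means
of p — the only reading consistent with the reported ~4% change between
the four- and five-locus steps.  When the extension step fails the 10%
improvement rule, the *previous* step's list is final, and its p values
receive the search Bonferroni correction with m = final length (the
correction deliberately includes the never-tested single-SNP patterns,
the convention this correction follows).

## tagSNP selection

Pairwise r² = D²/(p_A(1−p_A)p_B(1−p_B)) from EM two-locus haplotype
frequencies (founders only in family mode).  Selection is greedy set
cover under strict r² > threshold (default 0.8): repeatedly take the SNP
covering the most uncovered SNPs, ties to the higher minor-allele
frequency then the lower panel index.  This is a deterministic stand-in
for pairwise taggers used interactively; it serves the method's role
(suppressing near-duplicate SNPs) and is verified against exhaustive
minimum covers on toys, but it is not intended to reproduce any particular
tagger's output SNP-for-SNP.

## Synthetic data

The generators emulate the study design the method targets: a case-control
panel (defaults ~1,000 + 1,000) drawn from an HWE haplotype pool with a
logistic planted effect (affection probability logistic(baseline_logit +
log OR · risk-haplotype copies); baseline logit −1.7 ≈ 15% background
probability, a realistic childhood prevalence for a common inflammatory
skin disease), and nuclear families with two children, ascertained for at
least two affected siblings, with Mendelian transmission and no
recombination across pattern loci (pattern spans are far below the
recombination scale of a ~2 Mb region).  Quotas and ascertainment are met
by batched rejection sampling, so sampled distributions are exact
conditionals.  The scenario generator plants a risk sub-haplotype at chosen
loci and fills the remaining panel with independent noise loci (MAF drawn
once from U(0.2, 0.5)).

What the generator does *not* emulate — and what passing tests therefore
do not establish for real data — includes realistic LD decay between
pattern and background loci (noise loci are independent), population
stratification, genotyping error beyond uniform allele missingness, and
covariate structure.

## Validation problem sizes

The calibration and recovery suites run at desk scale: type-I error of the
global LRT over 1,000 null replicates of 300 + 300 individuals (large
enough for the chi-square asymptotics the LRT relies on); type-I error of
the weighted TDT over 1,000 null replicates of 40 ascertained families
(transmission is independent of affection under the null, so ascertainment
must not inflate the test — asserted); Wald-CI coverage over 200 replicates
at OR 2, 2,000 + 2,000 individuals; and planted-pattern recovery (3-SNP
risk haplotype, frequency 0.15, OR 2.5, 800 + 800) over 20 seeded searches
of a 10-SNP panel with `nt` = 30.  The original study's genotypes are not
public, so validation rests on these property suites plus the in-text
worked values (Bonferroni factor, T:U odds ratios, stop-criterion
arithmetic).

## Known limitations

* Haplotype regression treats posterior dosages as fixed covariates; phase
  uncertainty therefore attenuates effect estimates slightly (visible as
  coverage a little below nominal in high-ambiguity pools).
* The family engine requires complete nuclear families (two genotyped
  parents); half-sib families and deeper pedigrees are out of scope.
* No X-chromosome handling, no recombination within patterns, and no
  permutation-based family-wise error control (replication in an
  independent family set is the intended confirmation route).
* Phenotypes are binary; 0/−9 phenotypes are retained for phasing but
  excluded from association tests.
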