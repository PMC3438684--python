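# Methods

`pleiobayes` detects pleiotropic SNP associations — loci simultaneously
associated with two dichotomous phenotypes — and uses them to build Bayesian
genetic-risk classifiers. This note documents the model, the numerical and
design choices, what the simulator does and does not emulate, and the
problem sizes the tests and the reproduction script run at.

## Model space and scoring

For each SNP `S` and phenotypes `Da`, `Db` (coded 1/2) four relationships
are considered: `M0` (S independent of both), `Ma` and `Mb` (genotype
frequencies depend on one phenotype), and `Mab` (pleiotropic: they depend on
the joint class). Genotypes enter under one of four inheritance codings:

* genotypic — three categories AA / AB / BB;
* dominant — {AA} vs {AB, BB};
* recessive — {AA, AB} vs {BB};
* allelic — each allele is a separate Bernoulli observation.

"A" always denotes the input file's A1 allele; orientation is never flipped.
Missing genotypes are dropped per SNP (complete cases; under the allelic
coding both alleles are dropped).

A model's contingency table has `q` phenotype rows (1, 2, 2, 4 for `M0`,
`Ma`, `Mb`, `Mab`; joint rows in the fixed order (1,1), (1,2), (2,1),
(2,2)) and `c` genotype columns. Its marginal likelihood is a product of
Dirichlet-multinomial row terms with symmetric per-cell pseudo-count
`alpha`:

    ln p(S | D, M) = sum_j [ lnG(c a) - lnG(n_j. + c a)
                             + sum_s ( lnG(n_js + a) - lnG(a) ) ]

This is the probability of the ordered genotype observations (subjects are
distinguishable), which is what a Bayes factor on fixed data requires; the
unit tests verify it against a sequential Pólya-urn recursion and check that
it normalizes over all outcomes.

**Scan prior.** Bayes factors compare each model to the null on the same
coded data with a *common* `alpha = 1` per cell (`SCAN_ALPHA`, a uniform
prior on each row's genotype frequencies). A common pseudo-count makes a
model that merely adds empty phenotype rows score identically to its
reduced form, so Bayes factors measure fit rather than prior sharpness. The
alternative of tying `alpha` to the row count (4/q) makes a model with an
empty row win on skewed counts through the sharper prior alone; with a
constant secondary phenotype that convention retained dozens of spurious
two-category "Mb" SNPs, while under the common prior the pleiotropic and
naive searches agree exactly whenever `Db` carries no information.
Detection power, pleiotropic-upgrade rates and null retention were
empirically indistinguishable between the two conventions. The null model
is always scored under the same inheritance coding as the alternative, so
each factor compares identical data representations.

## Phase I — model search

1. **First pass.** For every SNP, `Ma` and `Mb` under all four codings (8
   models) are scored against matched nulls; the best model is kept when
   `ln BF > 1` (configurable threshold).
2. **Pleiotropy pass.** For each retained SNP the pleiotropic marginal
   likelihood is computed under the first-pass winning coding; the SNP is
   upgraded to `Mab` iff it *strictly* exceeds the first-pass model's
   likelihood (ties keep the simpler model). The evaluation is restricted
   to the winning coding because the first-pass phenotype fixes the data
   representation; re-searching all codings for `Mab` was not adopted.
3. **Ranking.** Retained SNPs are sorted by the ln Bayes factor of their
   assigned model against the null, descending, ties broken by input
   (genomic) order, defining the nested sets `Sigma_r = {S_1, ..., S_r}`.

The naive search is the same machinery restricted to `Ma` x 4 codings with
no pleiotropy pass; it is the single-phenotype baseline.

A scan is skipped with a warning when the target phenotype has fewer than
two subjects in a class; a degenerate secondary phenotype only collapses
`Mb`/`Mab` onto simpler models, which the scoring handles, so the scan
proceeds with a warning.

## Prediction

Classifiers always use the genotypic coding, which subsumes the others.
Each ranked SNP contributes the smoothed conditional probability table

    P(S_i = s | D = d, M_i) = (n_ijs + av) / (n_ij. + 3 av),   av = 4 / q,

and the joint phenotype posterior of a genotype profile is the prior times
the product of CPT entries over the top-r SNPs (naive-Bayes factorization).
Missing genotypes in a profile are skipped, not imputed. The prior over the
four joint classes defaults to uniform — the threshold `T = 1` is the
optimal 0-1-loss rule under balanced priors, and it performs well even on
unbalanced data — with an empirical-prior option.

Prediction statistics are posterior-odds ratios for `Da`:

* *marginal* — genotype only, summing the posterior over the unknown `Db`;
* *conditional* — genotype plus the known `Db` value (the ratio of the
  conditional posteriors `p(Da | Db = db, s)`);
* *naive* — two-class statistic from the naive search and series.

Each has a single-classifier form (posterior at `Sigma_r`) and an ensemble
form: the ratio of the means over `k = 1..r` of the class posteriors at
`Sigma_k` (conditional posteriors for the conditional ensemble). The
decision rule assigns class 2 when the statistic strictly exceeds `T`;
`T = 1` by default, or a Youden-optimal threshold from cross-validation.

## Phase II — cross-validated model-size selection

The discovery set is split into stratified folds (10-fold by default, or
leave-one-out), stratifying on the joint phenotype class. For each fold the
*entire* phase-I search is repeated on the training split and the held-out
subjects are scored at every `r`; the leakage test asserts that altering a
held-out subject cannot change the fold's trained classifier. Out-of-fold
statistics are pooled across folds per `r` (pooling rather than averaging
per-fold AUCs keeps LOOCV well-defined); `r*` is the smallest `r` attaining
the maximal pooled Mann-Whitney AUC. The optional threshold `T*` maximizes
Youden's `J = sensitivity + specificity - 1` over the midpoints between
consecutive distinct pooled statistics (plus one candidate below the
minimum and one above the maximum), smallest threshold on ties. `r_max`
defaults to 200.

## Evaluation

Class 2 is the positive class everywhere. The AUC is the Mann-Whitney
statistic (ties counted 1/2), which equals the trapezoidal area under the
empirical ROC; its confidence interval uses the DeLong placement-value
variance with a normal approximation truncated to [0, 1]. For unbalanced
phenotypes the summary metric is (sensitivity + specificity)/2, the linear
transform (J + 1)/2 of Youden's J. Model-composition curves report, for
each cutoff `r`, the fractions of `Sigma_r` that are correctly modeled
causal SNPs (by type), mis-modeled causal SNPs, and non-causal SNPs, plus
the per-rank causal indicator.

## Simulator

The simulator emulates a two-phenotype case-control GWAS: subjects receive
joint phenotype classes with *exact* per-class counts, then genotypes are
drawn per subject from the 3-category distribution of their class, every
SNP independent (no linkage disequilibrium, no covariates, no quantitative
traits — none of which the method models either). Non-causal SNPs follow
Hardy-Weinberg (HWE) frequencies in every class. A causal SNP keeps HWE in
unaffected classes and tilts affected classes multiplicatively:
`f(g) ∝ f_HWE(g) * w(g)` with `w = OR^{I[carrier]}` (dominant),
`OR^{I[homozygote]}` (recessive) or `sqrt(OR)^{x}` with `x` the
disease-allele count (additive; the homozygote-homozygote odds ratio equals
the full OR). Pleiotropic SNPs multiply both trait weights in the doubly
affected class (effects additive on the log-odds scale). Parameter
recovery is verified at 100,000 subjects per class for all modes and all
four classes of a pleiotropic SNP.

Per-SNP causal parameters are drawn independently: MAF from the pool,
disease allele uniform on {A, B}, OR uniform within the scenario bounds,
mode uniform over dominant/recessive/additive. The default MAF pool is
Uniform(0.05, 0.5) — a flat stand-in for a genotyping-array MAF spectrum
above 0.05; a user-supplied MAF list can be given instead. Because causal
ORs and the decision problem depend only weakly on the exact MAF spectrum,
this substitution mainly affects nothing beyond per-SNP power.

Sixteen scenario presets cover four study designs: six balanced scenarios
crossing discovery size (1,500 / 4,000; the scenario *name* defines the
size) with effect strength (OR 1.10-1.50, 1.25-2.00, 1.75-2.50); six
1,000-subject scenarios with `Da` unbalanced (10% cases; joint counts
450/450/50/50, validation 1800/1800/200/200) and per-trait OR ranges; two
scenarios without pleiotropy (75 `Da`-only + 75 `Db`-only causal SNPs;
discovery size not fixed by the design tables, preset default 4,000); and
two wide-effect scenarios (OR 1.1-2.5 at n = 4,000 and 1,500). Defaults:
a 500,150-SNP assay, 150 causal SNPs (50 pleiotropic / 50 / 50 unless
stated), a balanced 4,000-subject validation set. "Balanced" is implemented
as equal counts in all four joint classes.

## Problem sizes used by the tests and the reproduction script

Full-scale replication (100 replicates x 500,150 SNPs x 16 scenarios) is a
cluster-sized computation. The package's own reproduction runs each
scenario with its causal structure unchanged and the assay reduced so every
replicate costs roughly the same compute, `n_discovery x n_snps ~ 8.6M`
(2,150 SNPs at n = 4,000; 5,650 at n = 1,500; 8,650 at n = 1,000).
`scripts/acceptance.py` averages 20 replicates per scenario; the test suite
uses 4. Reducing the null-SNP count mainly thins the false-positive tail of
the ranking, which nudges selected-model accuracy slightly upward in the
easiest scenarios; the observed shifts are within the published
between-replicate spread.

## Known limitations

* Two dichotomous phenotypes only; no covariates, no continuous traits.
* Conditional independence of SNPs given the phenotype (naive-Bayes); LD
  between SNPs violates this and is not modeled.
* The pleiotropy pass evaluates `Mab` only under the first-pass winning
  coding.
* The uniform-MAF pool is a simplification of real array MAF spectra.
* Posterior odds are decision statistics, not calibrated probabilities.
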