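# pleiobayes

Bayesian detection of **pleiotropic SNP associations** — loci simultaneously
associated with two distinct phenotypes — and pleiotropy-aware **genetic
risk prediction** for case-control GWAS.

Most association scans test one phenotype at a time. When a locus affects
two traits, modeling the joint association both raises detection power and
improves risk prediction, especially when the second phenotype of a new
subject is already known. `pleiobayes` implements a two-phase method for
GWAS data with two dichotomous phenotypes `Da`, `Db` (each coded 1/2):

**Phase I — Bayesian model search.** For each SNP `S`, four models are
compared: the null `M0`, the single-trait models `Ma`, `Mb`, and the
pleiotropic `Mab`, each under four inheritance codings (genotypic, allelic,
dominant, recessive). Marginal likelihoods are Dirichlet-multinomial over
the phenotype-by-genotype contingency table, and models are compared by
Bayes factor against the null,

    BF = p(S | D, M) / p(S | M0),

retaining SNPs with `ln BF > 1` and then testing the pleiotropic model.
Ranked SNPs define nested sets `Σ_r = {S_1, …, S_r}`.

**Prediction.** Each `Σ_r` yields a Bayesian network classifier: with
smoothed conditional probability tables
`P(S_i = s | D = d) = (n_ijs + av)/(n_ij· + 3·av)`, `av = 4/q`, the joint
phenotype posterior is `p(d | s⃗, Σ_r) ∝ P(d) Π_i P(S_i = s_i | d)`.
Posterior-odds statistics `C1` predict `Da` marginally (Db unknown),
conditionally (Db known), or naively (Db ignored throughout), each as a
single classifier or an ensemble over `Σ_1 … Σ_r`; class 2 is assigned when
`C1 > T` (the Bayesian rule uses `T = 1`).

**Phase II — cross-validated feature selection.** Stratified 10-fold (or
leave-one-out) cross-validation repeats the full phase-I search per fold
and picks the SNP count `r*` maximizing the pooled out-of-fold ROC AUC,
optionally with a Youden-optimal decision threshold.

The package also ships the companion **GWAS simulator** (exact phenotype
class counts, Hardy-Weinberg nulls, causal SNPs with assigned
MAF/OR/mode/disease allele, log-odds-additive pleiotropic effects, and the
16 published scenario presets) and PLINK 1 bed/bim/fam input/output.

## Worked example

Simulate a strong-effect balanced scenario (4,000 discovery and 4,000
validation subjects, 150 causal SNPs of which 50 are pleiotropic, OR
1.75–2.5, assay reduced to 2,150 SNPs for desk scale), run both searches,
select the SNP count by 10-fold cross-validation, and classify the
validation set:

```python
import pleiobayes as pb

config = pb.scenario_presets("set1_scenario6").at_scale(2150)
rep = pb.run_replicate(config, seed=7, do_cv=True)

for m in ("naive_single", "marginal_single", "conditional_single"):
    res = rep.methods[m]
    print(f"{m:<22} r*={res.r_star:>3}  accuracy(T=1)={res.accuracy_at_r_star:.3f}  "
          f"peak={res.peak_accuracy:.3f}")
print("retained SNPs:", rep.ranked.t)
top = rep.ranked.assignments[0]
print(f"top SNP: {top.snp_id}  model={top.model.value}  mode={top.mode.value}  "
      f"ln BF={top.ln_bf:.1f}")
```

prints

```
naive_single           r*=107  accuracy(T=1)=0.874  peak=0.875
marginal_single        r*=163  accuracy(T=1)=0.885  peak=0.888
conditional_single     r*=163  accuracy(T=1)=0.899  peak=0.901
retained SNPs: 158
top SNP: snp603  model=Mab  mode=dominant  ln BF=152.8
```

The ordering is the method's central claim: conditioning on the known
second phenotype (0.899) beats marginal pleiotropic prediction (0.885),
which beats the naive single-trait classifier (0.874). The top-ranked SNP
is a true pleiotropic locus assigned `Mab` with overwhelming evidence.

The same pipeline is available from the shell:

```bash
pleiobayes simulate --scenario set1_scenario6 --n-snps 2150 --seed 7 --out study/
pleiobayes search   --bfile study/discovery --pheno study/discovery.pheno.tsv --out ranking.tsv
pleiobayes cv       --bfile study/discovery --pheno study/discovery.pheno.tsv --seed 7 --out cv.tsv
pleiobayes predict  --bfile study/discovery --pheno study/discovery.pheno.tsv \
                    --val-bfile study/validation --val-pheno study/validation.pheno.tsv \
                    --r 50 --out predictions.tsv
pleiobayes evaluate --predictions predictions.tsv --pheno study/validation.pheno.tsv --out metrics.tsv
```

## Layout

| module | contents |
| --- | --- |
| `pleiobayes.core` | genotype/phenotype containers, inheritance recoding, contingency tables |
| `pleiobayes.scoring` | Dirichlet-multinomial marginal likelihoods, Bayes factors |
| `pleiobayes.search` | phase I: 8-model first pass, pleiotropy pass, ranking |
| `pleiobayes.classify` | smoothed CPTs, joint posteriors, prediction statistics, decision rule |
| `pleiobayes.crossval` | phase II: stratified folds, out-of-fold pooling, `r*` and Youden `T*` |
| `pleiobayes.evaluate` | confusion metrics, Mann-Whitney AUC, DeLong CI, composition-by-rank |
| `pleiobayes.simulate` | causal-parameter draws, class genotype frequencies, scenario presets |
| `pleiobayes.plink` / `pleiobayes.cli` | PLINK 1 binary I/O, text tables, command-line interface |
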