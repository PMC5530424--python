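# kernboost

Pathway-based kernel boosting for case-control genetic association studies.

Genome-wide association studies (GWAS) often analyze gene sets — in
particular *pathways*, networks of interacting genes — instead of single
SNPs: grouped signals are easier to detect and easier to interpret.
`kernboost` models the disease status of `n` individuals jointly over many
pathways by using each pathway's **network-based genetic similarity kernel**
as a penalized base-learner inside **component-wise functional gradient
boosting**. The result is a sparse multivariable model that selects the
pathways with genuine explanatory power, avoids the multiple-testing problem
of single-pathway tests, and predicts case probabilities for new genotypes.
A single-pathway **logistic kernel machine test (LKMT)** is included as the
classical comparator, together with a synthetic-data generator for null and
effect simulation scenarios.

## Model

Disease status `y_i ∈ {0, 1}` follows an additive logistic model

```
logit P(y_i = 1 | x_i, z_i) = x_i β + f_1(z_i) + … + f_P(z_i)
```

where `x_i` are environmental covariates and `z_i` are minor-allele counts
(0/1/2). Each pathway effect `f_p` is a kernel-machine function
`f(Z) = K γ` built from the network-based kernel

```
K = Z A N Aᵀ Zᵀ
```

with `Z` the pathway's genotypes, `A` the SNP→gene mapping (columns scaled
`1/√m_g` so genes contribute equally regardless of SNP count) and `N` the
signed gene-interaction adjacency (+1 activation, −1 inhibition), prepared
by pruning genes without SNP data (rewiring their neighbours
multiplicatively), symmetrizing, and an eigenvalue shift `ρN + (1−ρ)I` onto
the PSD cone.

Boosting minimizes the empirical binomial risk: in every iteration each
pathway's base-learner is fitted to the current negative gradient
`u = y − expit(η)` by kernel-penalized least squares
`γ̂ = (KᵀK + λK)⁻¹ Kᵀ u` (computed in the transformed design
`K̃ = K K^{−1/2}`, where the penalty becomes the identity), the learner with
minimal residual sum of squares is selected, and the predictor moves by a
step `ν = 0.1`. The penalty `λ` is calibrated so every base-learner spends
the same degrees of freedom (default 4), keeping selection unbiased. The
number of iterations `m_stop` — the actual regularization — is tuned by
stratified subsampling with the empty model (`m = 0`) on the grid, so pure
noise can (and should) yield no selected pathway. Covariates enter as a
fixed logistic-regression offset.

## Worked example

```python
from kernboost import (SimulationScenario, simulate_scenario,
                       build_base_learners, kernel_boost, selected_pathways,
                       predict_proba, roc_auc, youden_cutpoint,
                       misclassification_rate)

scenario = SimulationScenario(n_cases=150, n_controls=150, rr_per_allele=1.5,
                              n_pathways=4, genes_per_pathway=10, density=0.3)
data = simulate_scenario(scenario, seed=11)
print("causal pathways:", data.causal_pathways)

learners = build_base_learners(data.genotypes, data.annotation, data.networks)
fit = kernel_boost(data.phenotype, learners, m_max=40, n_folds=5, seed=3)
print("m_stop:", fit.m_stop, "selected:", sorted(selected_pathways(fit)))

p = predict_proba(fit, data.genotypes)
cut, J = youden_cutpoint(data.phenotype, p)
print("AUC:", round(roc_auc(data.phenotype, p), 3),
      "misclassification at Youden cut:",
      round(misclassification_rate(data.phenotype, p, cut), 3))
```

Output:

```
causal pathways: ['pathway01', 'pathway03']
m_stop: 40 selected: ['pathway01', 'pathway03']
AUC: 0.687 misclassification at Youden cut: 0.35
```

The tuned model keeps exactly the two pathways that carry the simulated
per-allele relative risk of 1.5 and discards the noise pathways; the fitted
probabilities separate cases from controls (AUC ≈ 0.69 at this small
sample size), and the
misclassification rate is evaluated at the cut point maximizing the Youden
index (sensitivity + specificity − 1).

The same pipeline is scriptable from the shell:

```
kernboost simulate --scenario effect --rr 1.5 --n-cases 150 --n-controls 150 \
    --pathways 4 --genes-per-pathway 10 --density 0.3 --seed 11 --out data/
kernboost fit --genotypes data/genotypes.raw --pheno data/phenotype.tsv \
    --networks data/networks --annotation data/annotation.tsv \
    --mmax 40 --folds 5 --seed 3 --out run
kernboost predict --model run.model.json --genotypes data/genotypes.raw --out pred.tsv
kernboost lkmt --genotypes data/genotypes.raw --pheno data/phenotype.tsv \
    --networks data/networks --annotation data/annotation.tsv --out lkmt.tsv
```

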