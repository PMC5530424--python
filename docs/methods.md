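# Methods

## Model and estimation

`kernboost` fits the additive logistic model

```
logit P(y_i = 1 | x_i, z_i) = η_i = x_i β + Σ_p f_p(z_i),   p = 1 … P,
```

with binary case-control status `y`, environmental covariates `x` and
minor-allele counts `z ∈ {0,1,2}`. Each pathway effect is the kernel-machine
form `f(Z) = K γ` with the network-based kernel `K = Z A N Aᵀ Zᵀ`. Entries
of `K` can be read as the pairwise genetic similarity of individuals,
weighted by the pathway's interaction topology.

Estimation is component-wise functional gradient boosting under the
negative binomial log-likelihood loss. Per iteration the algorithm

1. computes the negative gradient `u = y − expit(η)`,
2. fits every pathway's base-learner to `u` by penalized least squares,
3. selects the base-learner with minimal residual sum of squares
   (smallest index on exact ties, for bit-reproducible paths), and
4. updates `η`, and the winner's function estimate, by a step `ν` times its
   fit; all other estimates are unchanged.

The additive predictor therefore always satisfies
`η = η_offset + Σ_p f̂_p`, which the test suite asserts as an invariant.

### Base-learner

The penalized criterion for one pathway is `‖u − Kγ‖² + λ γᵀKγ`: the kernel
is both design and penalty matrix, so that genetically similar individuals
receive similar fitted effects. Multiplying the design by `K^{−1/2}` turns
this into an ordinary ridge problem in `K̃ = K K^{−1/2}` with identity
penalty, `γ̂ = (K̃ᵀK̃ + λI)⁻¹ K̃ᵀ u`. Because kernels are routinely
rank-deficient (the rank is bounded by the number of represented genes),
`K^{−1/2}` is the eigen-truncated pseudo square root: eigenvalues at or
below `tol_rel = 1e−10` times the largest are dropped. On the retained rank
`K̃ K̃ᵀ = K` holds to numerical precision, and the fit coincides with the
direct kernel-penalized solution `γ̂ = (KᵀK + λK)⁻¹Kᵀu` whenever `K` has
full rank (asserted against a brute-force solve in the tests).

`λ` is calibrated per base-learner so that the trace of the ridge smoother,
`df(λ) = Σ_i d_i/(d_i + λ)` over the retained eigenvalues `d_i` of `K`,
equals a common target (default **4 degrees of freedom**; the alternative
definition `trace(2S − SᵀS)` is available via `df_method`). Equal df across
base-learners keeps the RSS selection step unbiased between pathways of very
different size and eigenstructure. The calibration solves a monotone
one-dimensional root problem by bisection on `log λ` to `|df − target| <
1e−6`; targets at or above the retained rank are rejected.

### Network preparation

Raw pathway adjacency matrices are signed (+1 activation, −1 inhibition)
and may be directed and may contain genes without genotyped SNPs. The
preparation chain is:

* **Prune and rewire.** Unrepresented genes are eliminated one at a time in
  input order; when gene `g` is removed, every pair of its neighbours gains
  a direct link with weight `w(a,g)·w(g,b)` unless a direct link already
  exists (existing links are never overwritten). This keeps the sign of
  indirect interactions mediated by unobservable genes.
* **Symmetrize.** The matrix is mirrored along its diagonal; if both
  directions carry conflicting non-zero signs the upper-triangle entry wins
  (a deterministic convention — the data do not identify a better rule).
* **PSD shift.** `ρN + (1−ρ)I` with `ρ = 1/(1 − λ_min)` when the smallest
  eigenvalue is negative (else `ρ = 1`). This is the largest `ρ` that makes
  the result PSD: the smallest eigenvalue lands exactly on zero and as much
  of the original structure as possible is preserved. The same transform
  repairs rare numerical PSD violations of the kernel itself
  (`ensure_psd_kernel`), triggered only below −1e−8, which also makes it
  idempotent.

The SNP→gene mapping `A` carries `1/√m_g` for each of the `m_g` SNPs of
gene `g`, i.e. unit column norm per represented gene — the package's
concrete choice for the gene-size adjustment, so a 50-SNP gene cannot
dominate a 5-SNP gene merely by length.

### Offset, tuning, prediction

Covariates are mandatory effects, not competitors: a standard logistic
regression of `y` on `x` is fitted first and its linear predictor is the
boosting start model (intercept-only: `η^[0] = logit(ȳ)`, the
loss-minimizing constant on the logit scale). Perfect separation raises an
error rather than being silently penalized.

`m_stop` is the principal tuning parameter. `tune_mstop` draws, per fold, a
case-status-stratified subsample of `⌊fraction·n⌋` individuals without
replacement (default fraction 0.5), fits the boosting path to `m_max` on the
subsample, and records the mean negative log-likelihood on the left-out
individuals at every `m ∈ {0,…,m_max}`. The fold-mean risk curve is
minimized (smallest `m` on ties); because `m = 0` is on the grid, a pure
noise dataset can legitimately return the empty, offset-only model.
Defaults follow the evaluated settings: `ν = 0.1`, df 4, `m_max = 200`,
20-fold subsampling.

Prediction for new genotypes uses the rectangular kernel
`K* = Z* A N Aᵀ Zᵀ` between new and training individuals (no PSD or rank
requirement) and the accumulated, `ν`-weighted coefficients mapped back
through `K^{−1/2}`: `f̂(Z*) = K* K^{−1/2} γ_agg`. Algebraically this
collapses to a per-SNP linear weight vector `w_p = A N Aᵀ Zᵀ K^{−1/2}
γ_agg`, which is what the model serialization stores — prediction from a
saved model is a plain dot product and needs no kernels. When a kernel was
PSD-repaired (`ρ < 1`) the training predictions via `K*` differ from the
in-sample fit by the tiny `(1−ρ)` diagonal term; in practice `ρ = 1` because
`K` built from a PSD-shifted `N` is PSD up to rounding.

## LKMT comparator

The logistic kernel machine score test checks a single pathway against the
covariate-only null model: `Q = ½ (y − p̂)ᵀ K (y − p̂)` with `p̂` from the
null logistic fit. The default p-value matches the first two moments of `Q`
under the null — using the projected weight matrix
`P₀ = D − DX(XᵀDX)⁻¹XᵀD`, `D = diag(p̂(1−p̂))`, with `E[Q] = tr(P₀K)/2` and
`Var[Q] = tr((P₀K)²)/2` — to a scaled chi-square (Satterthwaite). Both
traces are computed without any `n³` product. A residual-permutation mode
serves as a Monte-Carlo oracle in the tests. Exact mixture-of-chi-square
(Davies-type) inversion is out of scope; the moment approximation holds its
nominal 0.05 size within binomial error in the calibration test and agrees
with a 20,000-permutation oracle to better than 0.02 near `p ≈ 0.05`.
Bonferroni correction across `P` pathways uses the threshold `0.05/P`.

## Synthetic data

The generator reproduces the architecture of the method's simulation design
without any external haplotype engine:

* **Pseudogenes.** Every gene is a block of 5 SNPs. Per gene, per-SNP minor
  allele frequencies are uniform on `maf_range = (0.05, 0.5)`; two
  haplotypes per individual come from a Gaussian copula with AR(1)
  correlation `ld_rho = 0.5` inside the gene, thresholded at the MAF
  quantile and summed to 0/1/2 counts. Genes are mutually independent — the
  stand-in for sampling genomic segments ≥ 100 kb apart. The defaults are a
  realistic moderate within-gene LD and a common MAF spectrum; they are
  deliberately fixed once for all studies.
* **Networks.** Toy pathways are signed Erdős–Rényi graphs (default
  density 0.1 at 30 genes per pathway ≈ average degree 3, matching the
  topology range of curated pathway collections; inhibition fraction 0.1),
  with an optional gene-overlap fraction between consecutive pathways.
* **Null phenotype.** I.i.d. Bernoulli(0.5), independent of all genotypes.
* **Effect phenotype.** Two causal pathways; in each, one seed gene sampled
  with probability proportional to betweenness centrality plus two uniformly
  drawn neighbours (interconnected effects are what the network kernel is
  built for), and two influential SNPs per effect gene. Case probability is
  `expit(α + log(RR)·burden)` with the burden summed over effect SNPs and
  `α` anchored at a marginal prevalence of 0.1, where the per-allele odds
  ratio approximates the stated relative risk; individuals are sampled until
  the exact case and control quotas are met. The causal-pathway draw is
  restricted to pathways that can host three interconnected genes. Effect
  placement is planned once per study and held fixed across replicates,
  while genotypes and phenotypes are redrawn.

What the generator does **not** emulate: realistic haplotype block
structure, recombination maps, population stratification, between-gene LD,
genotyping error or missingness. Passing tests therefore demonstrate the
statistical behavior of the method under its stated model — selection
calibration under the null, power ordering under interconnected additive
effects — not robustness to the full messiness of real GWAS data.

## Study sizes and reproducibility

The replicated studies used by the test suite and by
`scripts/acceptance.py` run at reduced size chosen so a desk machine
completes them in minutes: the null study keeps the original 50-pathway
universe (the false-selection rate is a per-(pathway, replicate) percentage,
so the pathway count sets its denominator and is not scaled) with n = 400
individuals, 60 replicates in the acceptance script (20 in the test suite),
m_max = 100 and 10-fold subsampling; the effect study uses 10 pathways (2
causal), n = 1000, RR 1.5, 20 replicates. All randomness flows through
`numpy` generators seeded from a single root seed; fixed seeds give
bit-identical genotypes, networks, phenotypes, selection paths and outputs,
which the suite asserts end-to-end.

## Known limitations

* The per-allele "relative risk" enters as a log-odds coefficient at 10%
  baseline prevalence (OR ≈ RR); under quota sampling the realized marginal
  effect deviates slightly from the nominal RR.
* Tie rules (upper-triangle sign wins; first removed gene's product wins;
  smallest index on RSS ties; smallest m on risk ties) are conventions,
  stated and deterministic, not identified by the data.
* The Youden-index cut point is the J-maximizing threshold over observed
  scores; with heavily tied scores the cut is the smallest maximizer.
* Only binomial loss is implemented; competing (selectable) covariate
  base-learners and reduced-rank ("knots") kernel approximations are out of
  scope.
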