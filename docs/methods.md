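# Methods

## Model and procedure

`modnet` learns, per cohort, a partition of a target-gene universe into K
regulatory modules, each annotated with a sparse signed linear *program* over
candidate driver genes, by alternating program fitting and target
reassignment from a k-means start. The method assumes:

- expression is already normalized and log-scaled upstream; the package never
  normalizes, it only z-scores genes across samples (sample sd, ddof = 1)
  so that (a) Elastic Net penalties are comparable across drivers and (b) a
  module's mean standardized profile is a well-defined response;
- co-expression is driven by shared latent regulatory activity that is
  approximately linear in driver expression;
- one regression per module (on the module-mean profile) rather than one per
  target gene — the standard reading of "programs that best predict their
  target genes' expression", and the variant that keeps the iteration
  O(K) regressions per sweep.

Each sweep: (1) for every module, fit Elastic Net of the member-mean z-profile
on the standardized drivers, excluding members from their own module's
predictor set (a gene may still drive *other* modules, and drivers may be
targets elsewhere — only self-prediction is forbidden); (2) reassign every
target gene to the module minimizing the residual sum of squares between the
gene's z-profile and the program's predicted profile, ties to the lowest
module id. Convergence is declared when the fraction of genes that moved
falls below `conv_frac`; modules emptied by reassignment are dropped without
renumbering so module ids remain stable handles. After the last sweep the
programs are refit once on the final membership, so reported programs always
describe their reported members.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `K` (`n_modules`) | 100 | number of modules; mandatory-configurable, data-scale dependent. Synthetic validations use the planted K. |
| `percent` | 0.5 | fraction of most-varying genes forming the target universe (ties at the cutoff all kept). Drivers bypass this filter — they must stay available as predictors even when low-variance. |
| `mixing` (l1 ratio) | 0.5 | Elastic Net compromise between lasso sparsity and ridge grouping of correlated drivers. |
| penalty α | 10-fold CV, one-SE rule | seeded fold split; the one-SE rule prefers the sparsest model statistically indistinguishable from the CV optimum. |
| `conv_frac` | 0.01 | sweep-to-sweep moved-gene fraction below which iteration stops. |
| `max_iter` | 100 | hard cap; non-convergence is flagged in the network metadata, not fatal. |
| k-means init | 10 restarts | best inertia, seeded; deterministic given the seed. |
| `min_abs_corr` / `max_fdr` (driver flags) | 0.3 / 0.05 | a gene is methylation-driven when Spearman rho(met, expr) ≤ −0.3 at BH-FDR ≤ 0.05 (hypo/hyper by the gene's mean methylation vs the cohort median); copy-number-driven analogously with Pearson r ≥ +0.3. These flags are an explicit simplification: recurrent-aberration calling (segment-level copy-number recurrence, beta-mixture modeling of methylation) is treated as a pluggable upstream step whose output arrives as a driver list. |
| module map `max_fdr` / `min_overlap` | 0.05 / 5 | edge filters on the BH-corrected hypergeometric overlaps. |
| universe (module map) | union | the hypergeometric universe for a network pair is the union of the two target universes — conservative and symmetric; `intersection` is available for sensitivity analysis. |

Missing expression values: genes with > 20 % missing samples are dropped;
the remainder are mean-imputed per gene before inference (logged). Variance
for the gene filter is computed on the input scale, before any
standardization.

## Statistical tests

Module scores are per-sample means of z-scored target expression. Tests are
dispatched by declared phenotype type: Cox proportional hazards for
survival-time/event pairs, Wilcoxon rank-sum for two-class labels,
Kruskal–Wallis (tie-corrected) for ≥ 3 classes, Pearson for continuous and
Spearman (mid-ranks) for ordinal features. All p values are two-sided; the
effect direction is reported separately. BH-FDR is applied per phenotype
across the modules of one cohort (figure-level reporting conventions imply
multiplicity over modules; whether to correct across phenotypes jointly is
left to the user). Community-level results combine member modules' signed
z-scores by equal-weight Stouffer — chosen for sign-awareness; it treats
members as independent, which cross-cohort modules plausibly are.

The Cox fit is a single-covariate Newton–Raphson on the Breslow partial
likelihood (step clipped to ±2 per iteration, convergence at 1e-10, Wald p
from the observed information). Under complete separation the partial
likelihood is monotone; the coefficient is then reported at a documented
bound of |log HR| = 10 rather than diverging. Exact Wilcoxon enumeration is
used when min(n₁, n₂) ≤ 8 and there are no ties; otherwise the normal
approximation with tie and continuity correction. Zero events, constant
scores or constant features yield an *untestable* flag (missing p) rather
than an exception, so one degenerate phenotype cannot abort a battery.

## Community detection

The cross-cohort module map (cross-network pairs only; within-network pairs
are never edges) is partitioned by iterative removal of the highest
edge-betweenness edge on the unweighted filtered graph, ties broken by the
lexicographically smallest endpoint pair so runs are deterministic. The
partition kept is the one along the removal dendrogram (including the
initial connected components) with maximal Newman–Girvan modularity,
earliest on ties; singleton components are not communities. The −log₁₀ *P*
edge weights are retained as metadata only — betweenness is computed
unweighted. Known-signature collections can join the map as one-module
*guide* pseudo-networks: they form edges (annotating modules) but are
ignored when deciding whether a community spans two cohorts, so a guide set
can never flip a module to "shared" by itself.

## Synthetic data: what it emulates and what it does not

The generator mirrors the inference model exactly: i.i.d. standard-normal
driver expression; per-module latent profiles that are signed sparse
combinations (weights ±U(0.3, 1)) of 3 drivers; 25 targets per module equal
to the latent profile plus N(0, 0.5) noise; 200 samples; 40 candidate
drivers, disjoint across modules when the pool allows. Methylation and
copy-number layers are unit-variance Gaussians correlated with their
driver's expression at ρ = −0.8 / +0.8 for a declared half of the drivers.
Phenotypes are planted on realized module scores: per module a Bernoulli(½)
two-class label whose latent profile is shifted by 2 within-class latent sd
for one class; a continuous feature linear in one module's score with
r ≈ 0.6; exponential survival with log-hazard 0.7 per standardized unit of
the first module's score under uniform censoring with horizon 4.96
(≈ 20 % censoring at unit baseline rate). Multi-cohort suites reuse gene
identities (and generating weights) for shared modules across cohorts with
independent sample draws, and give distinct modules cohort-private gene
namespaces.

Consequences worth knowing:

- the class shift is latent-profile variance the drivers cannot explain, so
  module-mean program R² sits near 0.5 at the defaults — deliberately
  non-trivial for driver recovery;
- synthetic validations set `percent` to retain the planted target fraction
  (125/165): the generator's driver rows are pure noise with respect to the
  module structure, unlike real driver genes, and at `percent = 1` they enter
  the target universe as unstructured rows that the partition was never
  defined over;
- Gaussian signal only: no counts, no library-size effects, no batch
  structure, no heavy tails. Passing tests demonstrate correctness of the
  algorithms under their own model, not robustness to RNA-seq artifacts;
- driver recovery counts a driver as recovered at |weight| ≥ 0.1 — the
  Elastic Net retains tiny spurious coefficients that carry no regulatory
  claim, and a fitted weight below 0.1 is treated as absent.

## Numerical choices and degenerate inputs

- z-scores use sample sd (ddof = 1); zero-variance genes are dropped from the
  target filter, excluded from module scores, and dropped as predictors.
- Reassignment RSS is computed vectorized and ties resolve to the lowest
  module id; `argmin` over modules sorted by id makes this exact.
- Hypergeometric tails are computed in log space (`logsf`) so −log₁₀ *P*
  survives far beyond double-precision underflow of *p* itself.
- BH q-values enforce monotonicity by a reverse cumulative minimum; missing
  p values pass through untouched and do not consume ranks.
- Duplicate gene ids collapse by mean on read (warned); "NA"/empty cells are
  missing values, never zeros.
- All output tables are sorted on documented keys, making pipeline reruns
  with a fixed config and seed byte-identical.

## Problem sizes used in validation

Recovery experiments use the reference conditions above (5 seeds for module
and driver recovery; 3 seeds at n = 300 for Cox recovery; 1000 replicates at
n = 50 for type-I calibration; a 2-cohort suite with 3 shared + 2 distinct
modules for community recovery). A full single-cohort inference at the
reference size takes ~1–2 s on one CPU; the complete acceptance computation
runs in about a minute.

## Known limitations

- One regression per module: per-target-gene programs are out of scope.
- No per-covariate adjustment in survival models (single-covariate Cox only),
  no time-varying covariates, no competing risks.
- Community detection is unweighted Girvan–Newman only (no Louvain/Leiden),
  quadratic-ish in map size; module maps here are small.
- The CNV/methylation driver flags are marginal correlations, not recurrence
  calls; they will flag passenger genes in regions of correlated dosage.
- K is user-specified and not cross-validated.
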