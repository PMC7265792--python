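# modnet

Regulatory module network inference from multi-omics patient cohorts, with
cross-cohort community detection and clinical/molecular/imaging phenotype
association.

## The problem

Large tumor profiling studies provide gene expression, DNA copy-number and
DNA-methylation data alongside clinical outcomes and expert-scored imaging
features. `modnet` organizes the transcriptome of each cohort into
**regulatory modules** — sets of co-expressed target genes governed by a small
number of **driver genes** — then links modules across cohorts and asks which
modules track survival, molecular subtype, or imaging phenotypes. It is aimed
at computational biologists who want a tested, scriptable implementation of
this style of network analysis that runs on ordinary TSV/GMT inputs and is
fully verifiable on synthetic data with known ground truth.

## The model

Within one cohort, every gene is z-scored across samples. The algorithm
alternates two steps until the partition of target genes stabilizes:

1. **Regulatory programs.** For module *m* with target set *T(m)*, the module
   response is the mean standardized profile
   ȳ<sub>m</sub> = (1/|T(m)|) Σ<sub>g∈T(m)</sub> z<sub>g</sub>, and the
   program is an Elastic Net regression on the candidate drivers *d*:

       ŷ_m = β₀ + Σ_d β_d x_d ,  minimizing  ‖ȳ_m − ŷ_m‖²/2n + αλ‖β‖₁ + α(1−λ)‖β‖²/2

   with mixing λ = 0.5 and penalty α chosen by seeded 10-fold cross-validation
   with the one-standard-error rule. β<sub>d</sub> > 0 marks *d* an activator
   of the module, β<sub>d</sub> < 0 a repressor. A gene belonging to *T(m)* is
   excluded from module *m*'s own predictor set.
2. **Reassignment.** Each target gene moves to the module whose predicted
   profile has the smallest residual sum of squares against the gene's
   z-scored profile.

Initialization is k-means on z-scored target profiles; the target universe is
the most-varying fraction of genes, while candidate drivers (user lists plus
correlation-based copy-number/methylation flags) are exempt from that filter.

Across cohorts, every cross-cohort module pair is scored by the upper-tail
hypergeometric probability of its target-gene overlap (reported as
−log₁₀ *P*, BH-FDR filtered); the resulting module map is partitioned by
Girvan–Newman edge-betweenness removal at maximal modularity. Communities
spanning ≥ 2 cohorts mark *shared* regulatory behavior, everything else is
*distinct*. Module scores (per-sample mean of z-scored targets) feed a test
battery — Cox proportional hazards (Breslow ties), Wilcoxon rank-sum,
Kruskal–Wallis, Pearson and Spearman — with per-phenotype BH-FDR and
Stouffer combination of module results at the community level.

## Worked example

```python
from modnet import (generate_cohort, run_module_inference,
                    compute_module_scores, associate_phenotypes)
from modnet.metrics import target_partition_ari, driver_recovery

bundle, catalog, phenotypes, truth = generate_cohort(seed=1)   # 125 targets + 40 drivers
network = run_module_inference(bundle, catalog, K=5, percent=125/165, seed=1)
print(len(network.modules), network.n_iterations, network.converged)
print(target_partition_ari(network, truth))
print(driver_recovery(network, truth))

scores = compute_module_scores(network, bundle.expression)
results = associate_phenotypes(scores, phenotypes, cohort="cohort")
best = min((r for r in results if r.phenotype == "time"), key=lambda r: r.p_value)
print(best.module_ref, best.statistic, best.p_value, best.fdr)
```

prints

```
5 1 True
1.0
(1.0, 0.9333333333333332, 1.0)
('cohort', 2) 0.8648... 5.36e-19 2.68e-18
```

meaning: the five planted modules are recovered exactly (adjusted Rand index
1.0) in one sweep; driver precision/recall/sign agreement are 1.0/0.93/1.0;
and the module carrying the planted survival effect (inferred id 2 — module
ids are arbitrary cluster labels) shows a log hazard ratio of +0.86 per unit
score near the generating value of 0.7, at FDR ≈ 3e-18.

The same analysis runs from the shell:

```bash
modnet simulate --out demo --cohorts 2 --seed 1
modnet run demo/config.json           # modules, module map, communities,
                                      # associations, HTML report in demo/results
```

There is also a scikit-learn-style wrapper around the core:

```python
from modnet import ModuleNetworkInference
est = ModuleNetworkInference(drivers=catalog.driver_ids, n_modules=5,
                             percent=125/165, random_state=1)
scores = est.fit_transform(bundle.expression)   # modules × samples
est.assignment_, est.n_iter_
```

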