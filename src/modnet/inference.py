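"""Iterative regulatory-module network inference.

The algorithm alternates two steps until the target-gene partition stabilizes:

1. *Program fitting* — for each module, the mean of its members' z-scored
   expression profiles is regressed on the candidate drivers with Elastic
   Net (fixed l1/l2 mixing, penalty strength chosen by seeded k-fold
   cross-validation with the one-standard-error rule).  Drivers that are
   themselves members of the module are excluded from its predictor set, so
   a gene never predicts itself.
2. *Reassignment* — every target gene moves to the module whose fitted
   program's predicted per-sample profile has the smallest residual sum of
   squares against the gene's z-scored profile (ties break to the lowest
   module id).

Initialization is k-means on z-scored target rows.  Modules emptied by
reassignment are dropped without renumbering, so module ids remain stable
handles throughout.  All genes are z-scored across samples before inference,
which makes Elastic Net penalties comparable between drivers and makes the
module mean a well-defined response.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .io import filter_most_varying_genes, impute_missing
from .types import (
    DriverCatalog,
    ExpressionMatrix,
    Module,
    ModuleNetwork,
    OmicsBundle,
    RegulatoryProgram,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MIXING = 0.5
DEFAULT_CONV_FRAC = 0.01
DEFAULT_MAX_ITER = 100
DEFAULT_CV_FOLDS = 10
KMEANS_RESTARTS = 10


def _zscore_rows(data: pd.DataFrame) -> pd.DataFrame:
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    return data.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)


def initialize_module_assignments(
    expr_targets: ExpressionMatrix, K: int, seed: Optional[int] = None
) -> Dict[str, int]:
    """K-means partition of z-scored target-gene profiles into K modules.

    Runs multiple restarts and keeps the best within-cluster sum of squares;
    identical seeds give identical assignments.  Module ids are 1-based.
    """
    n_genes = expr_targets.n_genes
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n_genes / 2:
        raise ValueError(f"K={K} exceeds half the number of target genes ({n_genes})")
    z = _zscore_rows(expr_targets.data).fillna(0.0)
    km = KMeans(n_clusters=K, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return {gene: int(lab) + 1 for gene, lab in zip(expr_targets.gene_ids, labels)}


def _one_se_alpha(cv_model: ElasticNetCV) -> float:
    """Largest penalty whose mean CV error is within one standard error of
    the minimum (sklearn orders alphas_ descending)."""
    mse = cv_model.mse_path_.mean(axis=1)
    se = cv_model.mse_path_.std(axis=1, ddof=1) / math.sqrt(cv_model.mse_path_.shape[1])
    best = int(np.argmin(mse))
    threshold = mse[best] + se[best]
    eligible = np.nonzero(mse <= threshold)[0]
    return float(cv_model.alphas_[eligible[0]])


def fit_regulatory_program(
    module_mean: Sequence[float],
    drivers_expr: ExpressionMatrix,
    mixing: float = DEFAULT_MIXING,
    seed: Optional[int] = None,
    cv_folds: int = DEFAULT_CV_FOLDS,
    alpha: Optional[float] = None,
) -> RegulatoryProgram:
    """Elastic Net regression of a module's mean profile on candidate drivers.

    ``drivers_expr`` rows are standardized internally (zero-variance drivers
    dropped with a warning).  The penalty strength comes from a seeded k-fold
    cross-validation over sklearn's default path, then the one-standard-error
    rule picks the sparsest model within one SE of the CV minimum; pass an
    explicit ``alpha`` to bypass the cross-validation.
    """
    if not 0.0 < mixing <= 1.0:
        raise ValueError("mixing must be in (0, 1]")
    y = np.asarray(module_mean, dtype=float)
    z = _zscore_rows(drivers_expr.data)
    constant = z.isna().all(axis=1)
    if constant.any():
        logger.warning("dropping %d zero-variance drivers", int(constant.sum()))
        z = z.loc[~constant]
    if z.shape[0] == 0:
        return RegulatoryProgram(weights={}, intercept=float(np.mean(y)), fit_r2=0.0, raw_r2=0.0)
    X = z.to_numpy().T  # samples × drivers
    n = X.shape[0]
    if alpha is None:
        folds = cv_folds
        if n < 3 * folds:
            folds = max(2, n // 3)
            logger.warning("reducing CV folds to %d for n=%d samples", folds, n)
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_model = ElasticNetCV(l1_ratio=mixing, cv=cv, alphas=100, max_iter=5000)
        with np.errstate(all="ignore"):
            cv_model.fit(X, y)
        alpha = _one_se_alpha(cv_model)
    model = ElasticNet(alpha=alpha, l1_ratio=mixing, max_iter=5000)
    model.fit(X, y)
    pred = model.predict(X)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - pred) ** 2))
    raw_r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if raw_r2 < 0:
        logger.debug("raw fit R^2 negative (%.4f); reported clipped to 0", raw_r2)
    weights = {
        driver: float(coef)
        for driver, coef in zip(z.index, model.coef_)
        if coef != 0.0
    }
    return RegulatoryProgram(
        weights=weights,
        intercept=float(model.intercept_),
        fit_r2=raw_r2,
        raw_r2=raw_r2,
    )


def _prediction_matrix(
    modules: Sequence[Module], drivers_std: pd.DataFrame, n_samples: int
) -> np.ndarray:
    preds = np.zeros((len(modules), n_samples))
    for i, module in enumerate(modules):
        preds[i] = module.program.predict(drivers_std)
    return preds


def reassign_targets(
    expr_targets: ExpressionMatrix,
    modules: Sequence[Module],
    drivers_expr: ExpressionMatrix,
) -> Dict[str, int]:
    """Assign every target gene to the module whose program prediction has
    minimal residual sum of squares against the gene's z-scored profile.

    Ties resolve to the lowest module id.  Matches a brute-force per-gene
    scan by construction (vectorized).
    """
    if not modules:
        raise ValidationError("no modules to reassign into")
    z = _zscore_rows(expr_targets.data).fillna(0.0).to_numpy()
    drivers_std = _zscore_rows(drivers_expr.data).fillna(0.0)
    preds = _prediction_matrix(modules, drivers_std, z.shape[1])
    # RSS[g, m] = sum_s (z[g,s] - pred[m,s])^2
    rss = (
        (z ** 2).sum(axis=1)[:, None]
        - 2.0 * z @ preds.T
        + (preds ** 2).sum(axis=1)[None, :]
    )
    module_ids = np.array([m.module_id for m in modules])
    order = np.argsort(module_ids, kind="stable")  # lowest id wins ties
    rss = rss[:, order]
    ids_sorted = module_ids[order]
    best = np.argmin(rss, axis=1)  # argmin returns first minimum -> lowest id
    return {
        gene: int(ids_sorted[b]) for gene, b in zip(expr_targets.gene_ids, best)
    }


def _fit_all_programs(
    expr_targets: ExpressionMatrix,
    assignment: Mapping[str, int],
    drivers_expr: ExpressionMatrix,
    mixing: float,
    seed: Optional[int],
) -> List[Module]:
    z = _zscore_rows(expr_targets.data)
    members_by_module: Dict[int, List[str]] = {}
    for gene, mid in assignment.items():
        members_by_module.setdefault(mid, []).append(gene)
    modules: List[Module] = []
    for mid in sorted(members_by_module):
        members = [g for g in expr_targets.gene_ids if assignment.get(g) == mid]
        module_mean = z.loc[members].fillna(0.0).mean(axis=0).to_numpy()
        # self-prediction guard: drivers that are members never predict their own module
        predictors = [d for d in drivers_expr.gene_ids if d not in set(members)]
        sub_seed = None if seed is None else (seed + mid) % (2**31 - 1)
        if predictors:
            program = fit_regulatory_program(
                module_mean, drivers_expr.subset_genes(predictors),
                mixing=mixing, seed=sub_seed,
            )
        else:
            program = RegulatoryProgram(weights={}, intercept=float(module_mean.mean()))
        modules.append(Module(module_id=mid, target_ids=members, program=program))
    return modules


def run_module_inference(
    bundle: OmicsBundle | ExpressionMatrix,
    catalog: DriverCatalog,
    K: int = 100,
    percent: float = 0.5,
    mixing: float = DEFAULT_MIXING,
    max_iter: int = DEFAULT_MAX_ITER,
    conv_frac: float = DEFAULT_CONV_FRAC,
    seed: Optional[int] = None,
) -> ModuleNetwork:
    """Full iterative inference on one cohort.

    The target universe is the ``percent`` most-varying genes of the
    (missing-value-handled) expression matrix; catalog drivers bypass the
    variance filter and stay available as predictors regardless of their
    variance.  Iteration stops when the fraction of genes changing module
    falls below ``conv_frac`` or after ``max_iter`` rounds (non-convergence
    is flagged, not fatal).  Programs are refit once more on the final
    assignment so every reported program reflects its final member set.
    """
    if isinstance(bundle, ExpressionMatrix):
        bundle = OmicsBundle(expression=bundle)
    if len(catalog) == 0:
        raise ValidationError("empty driver catalog")
    expr = impute_missing(bundle.expression)
    drivers_present = [g for g in catalog.driver_ids if g in set(expr.gene_ids)]
    if not drivers_present:
        raise ValidationError("no catalog drivers present in the expression matrix")
    targets = filter_most_varying_genes(expr, percent)
    drivers_expr = expr.subset_genes(drivers_present)

    assignment = initialize_module_assignments(targets, K, seed=seed)
    trace: List[float] = []
    converged = False
    modules: List[Module] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        modules = _fit_all_programs(targets, assignment, drivers_expr, mixing, seed)
        if not modules:
            raise ValidationError("all modules empty")
        new_assignment = reassign_targets(targets, modules, drivers_expr)
        moved = sum(
            1 for g in new_assignment if new_assignment[g] != assignment.get(g)
        )
        frac_moved = moved / len(new_assignment)
        trace.append(frac_moved)
        assignment = new_assignment
        if frac_moved < conv_frac:
            converged = True
            break
    if not converged:
        logger.warning("module inference did not converge within %d iterations", max_iter)
    # final refit so programs match the final membership (and the
    # self-prediction exclusion holds for the reported network)
    modules = _fit_all_programs(targets, assignment, drivers_expr, mixing, seed)
    return ModuleNetwork(
        cohort_name=bundle.cohort_name,
        modules=modules,
        assignment=dict(sorted(assignment.items())),
        n_iterations=n_iter,
        converged=converged,
        reassignment_trace=trace,
        settings={
            "K": K, "percent": percent, "mixing": mixing,
            "max_iter": max_iter, "conv_frac": conv_frac, "seed": seed,
        },
    )


def compute_module_scores(
    network: ModuleNetwork, expr: ExpressionMatrix
) -> pd.DataFrame:
    """Per-sample module scores: mean of z-scored expression over each
    module's targets (modules × samples).

    Targets missing from ``expr`` or with zero variance are excluded with a
    warning; a module with no scorable target gets a row of NaN.
    """
    z = _zscore_rows(expr.data)
    rows = {}
    for module in network.modules:
        present = [g for g in module.target_ids if g in z.index]
        missing = set(module.target_ids) - set(present)
        if missing:
            logger.warning("module %d: %d targets missing from expression, dropped",
                           module.module_id, len(missing))
        scorable = [g for g in present if not z.loc[g].isna().all()]
        if len(scorable) < len(present):
            logger.warning("module %d: excluding %d zero-variance targets",
                           module.module_id, len(present) - len(scorable))
        if scorable:
            rows[module.module_id] = z.loc[scorable].mean(axis=0)
        else:
            logger.warning("module %d has no scorable target", module.module_id)
            rows[module.module_id] = pd.Series(np.nan, index=z.columns)
    scores = pd.DataFrame(rows).T
    scores.index.name = "module_id"
    return scores


def classify_driver_roles(program: RegulatoryProgram) -> Dict[str, str]:
    """Positive weight -> activator, negative weight -> repressor."""
    return {d: ("activator" if w > 0 else "repressor") for d, w in program.weights.items()}


class ModuleNetworkInference(BaseEstimator):
    """Scikit-learn-style wrapper around the iterative inference.

    Parameters mirror :func:`run_module_inference`.  ``fit`` consumes a gene ×
    sample expression frame (or :class:`ExpressionMatrix`) together with the
    driver catalog given at construction; ``transform`` maps expression to
    module × sample scores.

    Attributes (after ``fit``)
    --------------------------
    network_ : ModuleNetwork
    assignment_ : dict gene -> module id
    labels_ : ndarray of module ids in target-gene order
    n_iter_ : int
    """

    def __init__(
        self,
        drivers: Optional[Sequence[str]] = None,
        n_modules: int = 100,
        percent: float = 0.5,
        mixing: float = DEFAULT_MIXING,
        max_iter: int = DEFAULT_MAX_ITER,
        conv_frac: float = DEFAULT_CONV_FRAC,
        random_state: Optional[int] = None,
    ):
        self.drivers = drivers
        self.n_modules = n_modules
        self.percent = percent
        self.mixing = mixing
        self.max_iter = max_iter
        self.conv_frac = conv_frac
        self.random_state = random_state

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(X.copy())
        raise TypeError("X must be an ExpressionMatrix or a genes × samples DataFrame")

    def fit(self, X, y=None):
        matrix = self._as_matrix(X)
        if not self.drivers:
            raise ValidationError("ModuleNetworkInference requires a driver list")
        catalog = DriverCatalog(
            driver_ids=[d for d in self.drivers if d in set(matrix.gene_ids)],
            provenance={d: {"user_list"} for d in self.drivers if d in set(matrix.gene_ids)},
        )
        self.network_ = run_module_inference(
            OmicsBundle(expression=matrix),
            catalog,
            K=self.n_modules,
            percent=self.percent,
            mixing=self.mixing,
            max_iter=self.max_iter,
            conv_frac=self.conv_frac,
            seed=self.random_state,
        )
        self.assignment_ = self.network_.assignment
        self.labels_ = np.array([
            self.assignment_[g] for g in matrix.gene_ids if g in self.assignment_
        ])
        self.n_iter_ = self.network_.n_iterations
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "network_"):
            raise ValidationError("estimator is not fitted")
        return compute_module_scores(self.network_, self._as_matrix(X))

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
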