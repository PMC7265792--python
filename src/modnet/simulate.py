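"""Synthetic cohorts with known regulatory-module ground truth.

The generator mirrors the model the inference assumes: candidate driver
expression is i.i.d. standard normal; each module owns a latent profile that
is a sparse signed combination of its drivers (weights ±Uniform(0.3, 1));
every target gene equals its module's latent profile plus Gaussian noise.
Omics layers are unit-variance Gaussians correlated with driver expression
(methylation negatively at rho = -0.8, copy number positively at +0.8), so
the correlation-based driver flags have planted positives.  Phenotypes are
planted on realized module scores: a two-class label per module whose latent
profile is shifted by two within-class standard deviations for one class, a
continuous feature linear in one module's score (r ≈ 0.6 by construction),
and exponential survival times with log-hazard 0.7 per standardized unit of
module 1's score under ~20% uniform censoring.

Everything is reproducible from (parameters, seed), and the ground truth is
returned alongside (and serializable to JSON) so recovery can be measured.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    DriverCatalog,
    ExpressionMatrix,
    OmicsBundle,
    PhenotypeTable,
    ValidationError,
)

# Class-1 latent shift in units of the base (within-class) latent sd.
CLASS_SHIFT_SD = 2.0
# Pearson r between the continuous feature and its module score.
CONTINUOUS_R = 0.6
# Log hazard ratio per standardized unit of module 1's score.
SURVIVAL_LOG_HR = 0.7
# Uniform censoring horizon giving ~20% censoring for unit-rate exponentials.
CENSOR_HORIZON = 4.96
# |rho| between an omics layer and its driver's expression.
OMICS_ABS_RHO = 0.8


@dataclass
class GroundTruth:
    """Generating truth of a synthetic cohort (or multi-cohort suite)."""

    assignment: Dict[str, int]
    programs: Dict[int, Dict[str, float]]
    phenotype_effects: Dict[str, dict] = field(default_factory=dict)
    shared_correspondence: Optional[List[Dict[str, int]]] = None
    met_drivers: List[str] = field(default_factory=list)
    cnv_drivers: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "assignment": self.assignment,
            "programs": {str(k): v for k, v in self.programs.items()},
            "phenotype_effects": self.phenotype_effects,
            "shared_correspondence": self.shared_correspondence,
            "met_drivers": self.met_drivers,
            "cnv_drivers": self.cnv_drivers,
        }
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")


@dataclass
class ModuleSpec:
    module_id: int
    target_ids: List[str]
    weights: Dict[str, float]  # driver -> signed generating weight


def _draw_weights(rng: np.random.Generator, drivers: Sequence[str]) -> Dict[str, float]:
    signs = rng.choice([-1.0, 1.0], size=len(drivers))
    mags = rng.uniform(0.3, 1.0, size=len(drivers))
    return {d: float(s * m) for d, s, m in zip(drivers, signs, mags)}


def _sample_cohort_expression(
    specs: Sequence[ModuleSpec],
    driver_ids: Sequence[str],
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[int, np.ndarray]]:
    """Draw one cohort: driver rows ~ N(0,1), targets = shifted latent + noise.

    Returns (expression genes × samples with targets first, driver expression
    frame, per-module two-class label arrays).
    """
    driver_expr = pd.DataFrame(
        rng.standard_normal((len(driver_ids), n_samples)),
        index=list(driver_ids),
        columns=[f"S{i + 1:04d}" for i in range(n_samples)],
    )
    target_rows = {}
    labels: Dict[int, np.ndarray] = {}
    for spec in specs:
        latent = np.zeros(n_samples)
        for d, w in spec.weights.items():
            latent = latent + w * driver_expr.loc[d].to_numpy()
        label = rng.integers(0, 2, size=n_samples)
        shift = CLASS_SHIFT_SD * float(np.std(latent, ddof=1))
        shifted = latent + shift * label
        labels[spec.module_id] = label
        for t in spec.target_ids:
            noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
            target_rows[t] = shifted + noise
    targets = pd.DataFrame(target_rows, index=driver_expr.columns).T
    expr = pd.concat([targets, driver_expr])
    return expr, driver_expr, labels


def _module_scores(expr: pd.DataFrame, specs: Sequence[ModuleSpec]) -> Dict[int, np.ndarray]:
    """Realized per-sample scores: mean of z-scored target rows per module."""
    scores = {}
    for spec in specs:
        sub = expr.loc[spec.target_ids]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = sub.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
        scores[spec.module_id] = z.mean(axis=0).to_numpy()
    return scores


def _build_phenotypes(
    scores: Dict[int, np.ndarray],
    labels: Dict[int, np.ndarray],
    sample_ids: Sequence[str],
    rng: np.random.Generator,
) -> Tuple[PhenotypeTable, Dict[str, dict]]:
    module_ids = sorted(scores)
    effects: Dict[str, dict] = {}
    data: Dict[str, object] = {}
    for m in module_ids:
        col = f"class_m{m}"
        data[col] = np.where(labels[m] == 1, "g1", "g0")
        effects[col] = {"module": m, "class_shift_sd": CLASS_SHIFT_SD, "test": "wilcoxon"}
    cont_module = module_ids[1] if len(module_ids) > 1 else module_ids[0]
    z = scores[cont_module]
    z = (z - z.mean()) / z.std(ddof=1)
    data["imaging_feature"] = CONTINUOUS_R * z + math.sqrt(1 - CONTINUOUS_R**2) * rng.standard_normal(len(z))
    effects["imaging_feature"] = {"module": cont_module, "r": CONTINUOUS_R, "test": "pearson"}

    surv_module = module_ids[0]
    z1 = scores[surv_module]
    z1 = (z1 - z1.mean()) / z1.std(ddof=1)
    hazard = np.exp(SURVIVAL_LOG_HR * z1)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, CENSOR_HORIZON, size=len(z1))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)
    data["time"] = time
    data["event"] = event
    effects["time"] = {"module": surv_module, "log_hr": SURVIVAL_LOG_HR, "test": "cox"}

    frame = pd.DataFrame(data, index=list(sample_ids))
    schema = {c: "two_class" for c in data if c.startswith("class_m")}
    schema.update({"imaging_feature": "continuous", "time": "survival_time",
                   "event": "survival_event"})
    return PhenotypeTable(data=frame, schema=schema), effects


def _correlated_layer(
    driver_expr: pd.DataFrame, genes: Sequence[str], rho: float, rng: np.random.Generator
) -> pd.DataFrame:
    noise = rng.standard_normal((len(genes), driver_expr.shape[1]))
    base = driver_expr.loc[list(genes)].to_numpy()
    layer = rho * base + math.sqrt(1 - rho**2) * noise
    return pd.DataFrame(layer, index=list(genes), columns=driver_expr.columns)


def generate_cohort(
    n_samples: int = 200,
    n_drivers: int = 40,
    n_modules: int = 5,
    targets_per_module: int = 25,
    drivers_per_module: int = 3,
    noise_sd: float = 0.5,
    seed: Optional[int] = None,
    cohort_name: str = "cohort",
    omics_fraction: float = 0.5,
) -> Tuple[OmicsBundle, DriverCatalog, PhenotypeTable, GroundTruth]:
    """Generate one synthetic cohort with full ground truth.

    Defaults are the reference study conditions used throughout the test
    suite: 200 samples, 40 candidate drivers, 5 modules × 25 targets with 3
    generating drivers each, target noise sd 0.5.
    """
    if drivers_per_module > n_drivers:
        raise ValidationError("drivers_per_module cannot exceed n_drivers")
    if min(n_samples, n_drivers, n_modules, targets_per_module, drivers_per_module) < 1:
        raise ValidationError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    driver_ids = [f"D{i + 1:03d}" for i in range(n_drivers)]

    # driver-disjoint modules when the pool allows it
    if n_modules * drivers_per_module <= n_drivers:
        pool = list(rng.permutation(driver_ids))
        blocks = [pool[i * drivers_per_module:(i + 1) * drivers_per_module]
                  for i in range(n_modules)]
    else:
        blocks = [list(rng.choice(driver_ids, size=drivers_per_module, replace=False))
                  for _ in range(n_modules)]

    specs = []
    t_counter = 0
    for m in range(1, n_modules + 1):
        targets = [f"T{t_counter + i + 1:04d}" for i in range(targets_per_module)]
        t_counter += targets_per_module
        specs.append(ModuleSpec(module_id=m, target_ids=targets,
                                weights=_draw_weights(rng, blocks[m - 1])))

    expr, driver_expr, labels = _sample_cohort_expression(
        specs, driver_ids, n_samples, noise_sd, rng
    )
    scores = _module_scores(expr, specs)
    phenotypes, effects = _build_phenotypes(scores, labels, expr.columns, rng)

    n_layer = math.ceil(omics_fraction * n_drivers)
    met_drivers = sorted(rng.choice(driver_ids, size=n_layer, replace=False))
    cnv_drivers = sorted(rng.choice(driver_ids, size=n_layer, replace=False))
    met = _correlated_layer(driver_expr, met_drivers, -OMICS_ABS_RHO, rng)
    cnv = _correlated_layer(driver_expr, cnv_drivers, +OMICS_ABS_RHO, rng)

    bundle = OmicsBundle(
        expression=ExpressionMatrix(expr),
        cnv=ExpressionMatrix(cnv),
        methylation=ExpressionMatrix(met),
        cohort_name=cohort_name,
    )
    catalog = DriverCatalog(
        driver_ids=driver_ids,
        provenance={
            d: {"user_list"}
            | ({"met_driven"} if d in set(met_drivers) else set())
            | ({"cnv_driven"} if d in set(cnv_drivers) else set())
            for d in driver_ids
        },
    )
    truth = GroundTruth(
        assignment={t: s.module_id for s in specs for t in s.target_ids},
        programs={s.module_id: dict(s.weights) for s in specs},
        phenotype_effects=effects,
        met_drivers=list(met_drivers),
        cnv_drivers=list(cnv_drivers),
    )
    return bundle, catalog, phenotypes, truth


def generate_multi_cohort_suite(
    n_cohorts: int = 2,
    shared_modules: int = 3,
    distinct_modules_per_cohort: int = 2,
    seed: Optional[int] = None,
    n_samples: int = 200,
    n_drivers: int = 40,
    targets_per_module: int = 25,
    drivers_per_module: int = 3,
    noise_sd: float = 0.5,
) -> Tuple[List[Tuple[OmicsBundle, DriverCatalog, PhenotypeTable]], GroundTruth]:
    """Generate cohorts sharing some modules (same gene identities, independent
    sample draws) and carrying cohort-private distinct modules.

    Cohort module numbering puts the shared modules first (ids 1..S identical
    across cohorts), recorded in ``shared_correspondence``.
    """
    if n_cohorts < 2:
        raise ValidationError("suite needs >= 2 cohorts")
    rng = np.random.default_rng(seed)
    cohort_names = [f"cohort{c + 1}" for c in range(n_cohorts)]

    n_shared_drivers = max(shared_modules * drivers_per_module, n_drivers // 2)
    n_shared_drivers = min(n_shared_drivers, n_drivers)
    shared_driver_ids = [f"SD{i + 1:03d}" for i in range(n_shared_drivers)]
    n_private = n_drivers - n_shared_drivers

    shared_pool = list(rng.permutation(shared_driver_ids))
    shared_specs = []
    t_counter = 0
    for m in range(1, shared_modules + 1):
        block = shared_pool[(m - 1) * drivers_per_module: m * drivers_per_module]
        targets = [f"ST{t_counter + i + 1:04d}" for i in range(targets_per_module)]
        t_counter += targets_per_module
        shared_specs.append(ModuleSpec(module_id=m, target_ids=targets,
                                       weights=_draw_weights(rng, block)))

    cohorts = []
    assignment: Dict[str, int] = {}
    programs: Dict[int, Dict[str, float]] = {}
    all_private_genes: set = set()
    for name in cohort_names:
        private_driver_ids = [f"{name}_D{i + 1:03d}" for i in range(n_private)]
        private_pool = list(rng.permutation(private_driver_ids)) if n_private else []
        specs = list(shared_specs)
        for d in range(distinct_modules_per_cohort):
            mid = shared_modules + d + 1
            if private_pool and len(private_pool) >= drivers_per_module:
                block = private_pool[d * drivers_per_module:(d + 1) * drivers_per_module]
            else:
                block = list(rng.choice(shared_driver_ids, size=drivers_per_module,
                                        replace=False))
            targets = [f"{name}_T{d * targets_per_module + i + 1:04d}"
                       for i in range(targets_per_module)]
            collision = set(targets) & all_private_genes
            if collision:  # generator bug guard — construction makes this impossible
                raise RuntimeError(f"gene-namespace collision: {sorted(collision)[:5]}")
            all_private_genes |= set(targets)
            specs.append(ModuleSpec(module_id=mid, target_ids=targets,
                                    weights=_draw_weights(rng, block)))
        driver_ids = shared_driver_ids + private_driver_ids
        expr, _driver_expr, labels = _sample_cohort_expression(
            specs, driver_ids, n_samples, noise_sd, rng
        )
        scores = _module_scores(expr, specs)
        phenotypes, _effects = _build_phenotypes(scores, labels, expr.columns, rng)
        bundle = OmicsBundle(expression=ExpressionMatrix(expr), cohort_name=name)
        catalog = DriverCatalog(driver_ids=driver_ids,
                                provenance={d: {"user_list"} for d in driver_ids})
        cohorts.append((bundle, catalog, phenotypes))
        for spec in specs:
            for t in spec.target_ids:
                assignment[f"{name}:{t}"] = spec.module_id
            programs.setdefault(spec.module_id, dict(spec.weights))

    truth = GroundTruth(
        assignment=assignment,
        programs=programs,
        shared_correspondence=[
            {name: m for name in cohort_names} for m in range(1, shared_modules + 1)
        ],
    )
    return cohorts, truth
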