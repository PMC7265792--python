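"""Phenotype association test battery with FDR control.

Module scores (per-sample means of z-scored target expression) are tested
against declared phenotype columns: Cox proportional hazards for survival,
Wilcoxon rank-sum for two-class labels, Kruskal-Wallis for multiclass,
Pearson for continuous and Spearman for ordinal features.  P values are
two-sided throughout; the effect direction is reported separately.
Benjamini-Hochberg correction is applied per phenotype across modules.

The Cox fit is a single-covariate Newton-Raphson maximization of the Breslow
partial likelihood written here directly (the installed survival packages
expose only Efron tie handling); the rank and correlation tests delegate to
scipy.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssociationResult, PhenotypeTable, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# individual tests


def _untestable(module_ref, phenotype, test, note, n_used=0) -> AssociationResult:
    return AssociationResult(
        module_ref=module_ref, phenotype=phenotype, test=test, note=note, n_used=n_used
    )


def breslow_loglik(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray) -> float:
    """Breslow partial log-likelihood of a single covariate at ``beta``."""
    order = np.argsort(time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    eta = beta * xv
    # risk set at event time t_i: all j with t_j >= t_i
    loglik = 0.0
    exp_eta = np.exp(eta)
    for et in np.unique(t[d == 1]):
        at_risk = t >= et
        tied = (t == et) & (d == 1)
        loglik += eta[tied].sum() - tied.sum() * math.log(exp_eta[at_risk].sum())
    return float(loglik)


MAX_ABS_LOG_HR = 10.0  # divergence guard under monotone likelihood (separation)


def _cox_newton(time: np.ndarray, event: np.ndarray, x: np.ndarray,
                tol: float = 1e-10, max_iter: int = 100) -> Tuple[float, float]:
    """Newton-Raphson for the 1-D Breslow partial likelihood.

    Returns (beta_hat, standard error from the observed information).  When
    the likelihood is monotone (complete separation of the covariate), the
    estimate is reported at the admissible bound ±MAX_ABS_LOG_HR.
    """
    beta = 0.0
    for _ in range(max_iter):
        exp_eta = np.exp(beta * x)
        score = 0.0
        info = 0.0
        for et in np.unique(time[event == 1]):
            at_risk = time >= et
            tied = (time == et) & (event == 1)
            w = exp_eta[at_risk]
            s0 = w.sum()
            s1 = (w * x[at_risk]).sum()
            s2 = (w * x[at_risk] ** 2).sum()
            d = tied.sum()
            score += x[tied].sum() - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 0:
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))  # guard against overshoot
        beta = float(np.clip(beta + step, -MAX_ABS_LOG_HR, MAX_ABS_LOG_HR))
        if abs(step) < tol or abs(beta) >= MAX_ABS_LOG_HR:
            break
    exp_eta = np.exp(beta * x)
    info = 0.0
    for et in np.unique(time[event == 1]):
        at_risk = time >= et
        w = exp_eta[at_risk]
        s0 = w.sum()
        s1 = (w * x[at_risk]).sum()
        s2 = (w * x[at_risk] ** 2).sum()
        info += ((time == et) & (event == 1)).sum() * (s2 / s0 - (s1 / s0) ** 2)
    se = 1.0 / math.sqrt(info) if info > 0 else float("nan")
    return beta, se


def cox_survival_association(
    score: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    module_ref=None,
    phenotype: str = "survival",
) -> AssociationResult:
    """Single-covariate Cox proportional hazards fit (Breslow ties, Wald p).

    The statistic is the coefficient, i.e. the log hazard ratio per unit of
    module score.  Zero/one events or a constant score yield an untestable
    result (missing p) rather than an exception.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    ok = np.isfinite(score) & np.isfinite(time) & np.isfinite(event)
    score, time, event = score[ok], time[ok], event[ok]
    n = len(score)
    if event.sum() < 2:
        return _untestable(module_ref, phenotype, "cox", "fewer than 2 events", n)
    if np.ptp(score) == 0:
        return _untestable(module_ref, phenotype, "cox", "constant score", n)
    beta, se = _cox_newton(time, event, score)
    if not np.isfinite(se):
        return _untestable(module_ref, phenotype, "cox", "singular information", n)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AssociationResult(
        module_ref=module_ref, phenotype=phenotype, test="cox",
        statistic=float(beta), effect_direction=int(np.sign(beta)),
        p_value=float(p), n_used=n,
    )


def rank_sum_two_class(
    score: Sequence[float],
    labels: Sequence,
    module_ref=None,
    phenotype: str = "two_class",
) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum test between the two label groups.

    Exact enumeration when ``min(n1, n2) <= 8`` and there are no ties;
    normal approximation with tie correction otherwise.  Direction is the
    sign of ``median(group2) - median(group1)`` with groups in sorted label
    order.
    """
    score = np.asarray(score, dtype=float)
    labels = pd.Series(list(labels))
    ok = np.isfinite(score) & labels.notna().to_numpy()
    score, labels = score[ok], labels[ok]
    levels = sorted(pd.unique(labels), key=str)
    if len(levels) != 2:
        return _untestable(module_ref, phenotype, "wilcoxon",
                           f"expected 2 groups, got {len(levels)}", len(score))
    g1 = score[(labels == levels[0]).to_numpy()]
    g2 = score[(labels == levels[1]).to_numpy()]
    if len(g1) == 0 or len(g2) == 0:
        return _untestable(module_ref, phenotype, "wilcoxon", "empty group", len(score))
    has_ties = len(np.unique(score)) < len(score)
    method = "exact" if (min(len(g1), len(g2)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(g2) - np.median(g1)))
    return AssociationResult(
        module_ref=module_ref, phenotype=phenotype, test="wilcoxon",
        statistic=float(res.statistic), effect_direction=direction,
        p_value=float(min(res.pvalue, 1.0)), n_used=len(score),
    )


def kruskal_wallis_multiclass(
    score: Sequence[float],
    labels: Sequence,
    module_ref=None,
    phenotype: str = "multi_class",
) -> AssociationResult:
    """Kruskal-Wallis H test (tie-corrected) across >=3 label groups."""
    score = np.asarray(score, dtype=float)
    labels = pd.Series(list(labels))
    ok = np.isfinite(score) & labels.notna().to_numpy()
    score, labels = score[ok], labels[ok]
    levels = sorted(pd.unique(labels), key=str)
    if len(levels) < 3:
        raise ValidationError(
            "kruskal_wallis_multiclass needs >=3 groups; use rank_sum_two_class"
        )
    groups = [score[(labels == lv).to_numpy()] for lv in levels]
    if any(len(g) == 0 for g in groups):
        return _untestable(module_ref, phenotype, "kruskal_wallis", "empty group", len(score))
    if np.ptp(score) == 0:
        # degenerate: every rank tied -> H = 0 by convention
        return AssociationResult(
            module_ref=module_ref, phenotype=phenotype, test="kruskal_wallis",
            statistic=0.0, p_value=1.0, n_used=len(score),
        )
    h, p = stats.kruskal(*groups)
    return AssociationResult(
        module_ref=module_ref, phenotype=phenotype, test="kruskal_wallis",
        statistic=float(h), p_value=float(p), n_used=len(score),
    )


def _paired_clean(score, feature):
    score = np.asarray(score, dtype=float)
    feature = np.asarray(feature, dtype=float)
    ok = np.isfinite(score) & np.isfinite(feature)
    return score[ok], feature[ok]


def pearson_continuous(
    score: Sequence[float],
    feature: Sequence[float],
    module_ref=None,
    phenotype: str = "continuous",
) -> AssociationResult:
    """Pearson correlation; p from the t distribution with n-2 df."""
    x, y = _paired_clean(score, feature)
    if len(x) < 3:
        return _untestable(module_ref, phenotype, "pearson", "fewer than 3 pairs", len(x))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _untestable(module_ref, phenotype, "pearson", "constant vector", len(x))
    r, p = stats.pearsonr(x, y)
    return AssociationResult(
        module_ref=module_ref, phenotype=phenotype, test="pearson",
        statistic=float(r), effect_direction=int(np.sign(r)),
        p_value=float(p), n_used=len(x),
    )


def spearman_ordinal(
    score: Sequence[float],
    feature: Sequence[float],
    module_ref=None,
    phenotype: str = "ordinal",
) -> AssociationResult:
    """Spearman rank correlation (mid-ranks for ties); p via t approximation."""
    x, y = _paired_clean(score, feature)
    if len(x) < 3:
        return _untestable(module_ref, phenotype, "spearman", "fewer than 3 pairs", len(x))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _untestable(module_ref, phenotype, "spearman", "constant vector", len(x))
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(
        module_ref=module_ref, phenotype=phenotype, test="spearman",
        statistic=float(rho), effect_direction=int(np.sign(rho)),
        p_value=float(p), n_used=len(x),
    )


# ---------------------------------------------------------------------------
# multiplicity and combination


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = len(pv)
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest p downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        q[finite] = out
    return q


def combine_across_cohorts(
    results: Sequence[AssociationResult],
    community_id: str = "",
    phenotype: Optional[str] = None,
) -> AssociationResult:
    """Stouffer's equal-weight combination of member modules' signed z-scores.

    Each member's two-sided p is converted to a z magnitude and signed by its
    effect direction (direction 0 contributes an unsigned z of 0 only when
    p = 1; otherwise it is treated as positive).
    """
    members = [r for r in results if r.testable]
    phen = phenotype or (results[0].phenotype if results else "")
    if not members:
        return _untestable(community_id, phen, "stouffer", "no testable members")
    zs = []
    for r in members:
        z = stats.norm.isf(min(max(r.p_value, 1e-300), 1.0) / 2.0)
        sign = r.effect_direction if r.effect_direction != 0 else 1
        zs.append(sign * z)
    combined = float(np.sum(zs) / math.sqrt(len(zs)))
    p = float(2.0 * stats.norm.sf(abs(combined)))
    return AssociationResult(
        module_ref=community_id, phenotype=phen, test="stouffer",
        statistic=combined, effect_direction=int(np.sign(combined)),
        p_value=p, n_used=len(members),
        note=";".join(str(r.module_ref) for r in members),
    )


# ---------------------------------------------------------------------------
# dispatch


def _survival_pairs(schema: Mapping[str, str]) -> List[Tuple[str, str]]:
    times = [c for c, t in schema.items() if t == "survival_time"]
    events = [c for c, t in schema.items() if t == "survival_event"]
    if len(times) != len(events):
        raise ValidationError("survival_time and survival_event columns must pair up")
    return list(zip(times, events))


def associate_phenotypes(
    scores: pd.DataFrame,
    phenotypes: PhenotypeTable,
    cohort: str = "",
) -> List[AssociationResult]:
    """Test every module score row against every declared phenotype.

    ``scores`` is modules × samples.  Samples missing a phenotype value are
    excluded per test and ``n_used`` records the count actually used.
    BH-FDR is applied per phenotype across modules.
    """
    shared = [s for s in scores.columns if s in set(phenotypes.sample_ids)]
    results: List[AssociationResult] = []
    by_phenotype: Dict[str, List[AssociationResult]] = defaultdict(list)

    def run_for_modules(phen_name: str, func) -> None:
        for module_id in scores.index:
            ref = (cohort, module_id) if cohort else module_id
            if not shared:
                res = _untestable(ref, phen_name, "none", "no overlapping samples")
            else:
                res = func(module_id, ref)
            by_phenotype[phen_name].append(res)

    if not shared:
        logger.warning("no overlapping samples between scores and phenotype table")

    schema = phenotypes.schema
    handled = set()
    for time_col, event_col in _survival_pairs(schema):
        handled |= {time_col, event_col}
        phen = time_col

        def cox_runner(module_id, ref, _t=time_col, _e=event_col):
            s = scores.loc[module_id, shared].to_numpy(dtype=float)
            t = phenotypes.column(_t).reindex(shared).to_numpy(dtype=float)
            e = phenotypes.column(_e).reindex(shared).to_numpy(dtype=float)
            return cox_survival_association(s, t, e, module_ref=ref, phenotype=_t)

        run_for_modules(phen, cox_runner)

    for col, typ in schema.items():
        if col in handled:
            continue
        if typ == "two_class":
            func = lambda mid, ref, _c=col: rank_sum_two_class(
                scores.loc[mid, shared].to_numpy(dtype=float),
                phenotypes.column(_c).reindex(shared), module_ref=ref, phenotype=_c)
        elif typ == "multi_class":
            func = lambda mid, ref, _c=col: kruskal_wallis_multiclass(
                scores.loc[mid, shared].to_numpy(dtype=float),
                phenotypes.column(_c).reindex(shared), module_ref=ref, phenotype=_c)
        elif typ == "continuous":
            func = lambda mid, ref, _c=col: pearson_continuous(
                scores.loc[mid, shared].to_numpy(dtype=float),
                phenotypes.column(_c).reindex(shared).to_numpy(dtype=float),
                module_ref=ref, phenotype=_c)
        elif typ == "ordinal":
            func = lambda mid, ref, _c=col: spearman_ordinal(
                scores.loc[mid, shared].to_numpy(dtype=float),
                phenotypes.column(_c).reindex(shared).to_numpy(dtype=float),
                module_ref=ref, phenotype=_c)
        else:
            continue
        run_for_modules(col, func)

    for phen, group in by_phenotype.items():
        qs = adjust_fdr([r.p_value for r in group])
        for r, q in zip(group, qs):
            r.fdr = float(q) if np.isfinite(q) else float("nan")
        results.extend(group)
    return results


def results_to_frame(results: Iterable[AssociationResult], cohort: str = "") -> pd.DataFrame:
    rows = []
    for r in results:
        ref = r.module_ref
        if isinstance(ref, tuple):
            cohort_name, module_id = ref
        else:
            cohort_name, module_id = cohort, ref
        rows.append({
            "cohort": cohort_name, "module_id": module_id, "phenotype": r.phenotype,
            "test": r.test, "statistic": r.statistic, "direction": r.effect_direction,
            "p_value": r.p_value, "fdr": r.fdr, "n_used": r.n_used, "note": r.note,
        })
    frame = pd.DataFrame(rows, columns=["cohort", "module_id", "phenotype", "test",
                                        "statistic", "direction", "p_value", "fdr",
                                        "n_used", "note"])
    return frame.sort_values(["cohort", "phenotype", "module_id"], kind="stable").reset_index(drop=True)
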