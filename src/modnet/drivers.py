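"""Candidate-driver catalog assembly.

User-supplied driver lists are unioned with simplified data-driven flags:
a gene is *methylation-driven* when its methylation is significantly
inversely rank-correlated with its expression, and *copy-number-driven*
when its copy number is significantly positively correlated with its
expression.  These flags are deliberately lightweight stand-ins for full
recurrent-aberration callers: driver nomination is treated as a pluggable
upstream step and any externally derived list can be supplied instead.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .associations import adjust_fdr
from .types import DriverCatalog, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

MIN_SHARED_SAMPLES = 10


def _correlation_table(
    expr: ExpressionMatrix,
    layer: ExpressionMatrix,
    method: str,
) -> pd.DataFrame:
    """Per-gene correlation between an omics layer and expression over the
    shared genes/samples; constant rows are skipped with a warning."""
    genes = [g for g in expr.gene_ids if g in set(layer.gene_ids)]
    samples = [s for s in expr.sample_ids if s in set(layer.sample_ids)]
    if len(samples) < MIN_SHARED_SAMPLES:
        raise ValidationError(
            f"need >= {MIN_SHARED_SAMPLES} shared samples, got {len(samples)}"
        )
    if not genes:
        raise ValidationError("expression and omics layer share no genes")
    e = expr.data.loc[genes, samples]
    m = layer.data.loc[genes, samples]
    rows = []
    for gene in genes:
        x = m.loc[gene].to_numpy(dtype=float)
        y = e.loc[gene].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < MIN_SHARED_SAMPLES:
            logger.warning("gene %s: too few paired observations, skipped", gene)
            continue
        x, y = x[ok], y[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("gene %s: constant values, skipped", gene)
            continue
        if method == "spearman":
            corr, p = stats.spearmanr(x, y)
        else:
            corr, p = stats.pearsonr(x, y)
        rows.append({"gene": gene, "corr": float(corr), "p_value": float(p),
                     "mean_layer": float(np.mean(x))})
    table = pd.DataFrame(rows, columns=["gene", "corr", "p_value", "mean_layer"])
    if len(table):
        table["fdr"] = adjust_fdr(table["p_value"].to_numpy())
    else:
        table["fdr"] = []
    return table


def flag_methylation_driven(
    expr: ExpressionMatrix,
    met: ExpressionMatrix,
    min_abs_corr: float = 0.3,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Flag genes whose methylation is inversely associated with expression.

    A gene is flagged iff its Spearman rho is negative, ``|rho| >= min_abs_corr``
    and the BH-FDR of the correlation test is ``<= max_fdr``.  Direction is
    "hypo" when the gene's mean methylation lies below the cohort median of
    gene-mean methylation, else "hyper".
    """
    table = _correlation_table(expr, met, method="spearman")
    if not len(table):
        table["flagged"] = []
        table["direction"] = []
        return table
    table["flagged"] = (
        (table["corr"] < 0)
        & (table["corr"].abs() >= min_abs_corr)
        & (table["fdr"] <= max_fdr)
    )
    cohort_median = float(table["mean_layer"].median())
    table["direction"] = np.where(table["mean_layer"] < cohort_median, "hypo", "hyper")
    table.loc[~table["flagged"], "direction"] = ""
    return table


def flag_copy_number_driven(
    expr: ExpressionMatrix,
    cnv: ExpressionMatrix,
    min_abs_corr: float = 0.3,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Flag genes whose copy number is positively associated with expression
    (Pearson r >= min_abs_corr at BH-FDR <= max_fdr)."""
    table = _correlation_table(expr, cnv, method="pearson")
    if not len(table):
        table["flagged"] = []
        return table
    table["flagged"] = (table["corr"] >= min_abs_corr) & (table["fdr"] <= max_fdr)
    return table


def assemble_candidate_drivers(
    user_lists: Sequence[Sequence[str]],
    expr: ExpressionMatrix,
    cnv_flags: Optional[pd.DataFrame] = None,
    met_flags: Optional[pd.DataFrame] = None,
) -> DriverCatalog:
    """Union user driver lists with data-driven flags, restricted to genes
    present in the expression matrix.

    Drivers are exempt from the most-varying-gene filter downstream: the
    catalog is checked against the *unfiltered* expression gene space.
    """
    provenance: Dict[str, Set[str]] = {}
    direction: Dict[str, Optional[str]] = {}
    expr_genes = set(expr.gene_ids)

    def add(gene: str, tag: str, direc: Optional[str] = None) -> None:
        if gene not in expr_genes:
            logger.warning("driver %s absent from expression matrix, excluded", gene)
            return
        provenance.setdefault(gene, set()).add(tag)
        if direc:
            direction[gene] = direc

    for lst in user_lists:
        for gene in lst:
            add(gene, "user_list")
    if cnv_flags is not None and len(cnv_flags):
        for gene in cnv_flags.loc[cnv_flags["flagged"], "gene"]:
            add(gene, "cnv_driven")
    if met_flags is not None and len(met_flags):
        flagged = met_flags.loc[met_flags["flagged"]]
        for gene, direc in zip(flagged["gene"], flagged["direction"]):
            add(gene, "met_driven", direc or None)

    if not provenance:
        raise ValidationError(
            "no candidate drivers found: supply a driver list or omics layers "
            "that yield data-driven flags"
        )
    order: List[str] = [g for g in expr.gene_ids if g in provenance]
    return DriverCatalog(driver_ids=order, provenance=provenance, direction=direction)
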