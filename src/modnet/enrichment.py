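"""Functional enrichment and perturbation-based driver validation.

Modules (or community unions) are tested for over-representation in gene-set
collections with the same upper-tail hypergeometric statistic the module map
uses, BH-corrected across the collection.  Driver roles inferred from program
weight signs are checked against directional knockdown/overexpression
signatures: silencing an activator should deplete its targets (kd-down), and
overexpressing it should induce them (oe-up); the mirror rule holds for
repressors.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .associations import adjust_fdr
from .communities import overlap_significance
from .inference import classify_driver_roles
from .types import GeneSetCollection, Module, ValidationError

logger = logging.getLogger(__name__)

SIGNATURE_NAME = re.compile(r"^(?P<driver>.+)__(?P<perturbation>kd|oe)__(?P<direction>up|down)$")

# role × perturbation × signature-direction -> does a significant overlap
# support the role?  (activator: knockdown depletes / overexpression induces)
CONSISTENT: Dict[Tuple[str, str, str], bool] = {
    ("activator", "kd", "down"): True,
    ("activator", "kd", "up"): False,
    ("activator", "oe", "up"): True,
    ("activator", "oe", "down"): False,
    ("repressor", "kd", "up"): True,
    ("repressor", "kd", "down"): False,
    ("repressor", "oe", "down"): True,
    ("repressor", "oe", "up"): False,
}


def enrich_gene_sets(
    gene_set: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of one gene set against a collection.

    Returns a table sorted by ascending p (name as tiebreak) with BH-FDR
    across the collection.  An empty collection yields an empty table.
    """
    universe_set = set(universe)
    query = set(gene_set)
    if not query <= universe_set:
        raise ValidationError("query gene set must be a subset of the universe")
    rows = []
    for name in collection.names():
        members = set(collection.genes(name)) & universe_set
        if not members:
            k, p = 0, 1.0
        else:
            k, p = overlap_significance(query, members, len(universe_set))
        rows.append({
            "set_name": name,
            "description": collection.description(name),
            "set_size": len(members),
            "query_size": len(query),
            "overlap": k,
            "p_value": p,
        })
    table = pd.DataFrame(rows, columns=["set_name", "description", "set_size",
                                        "query_size", "overlap", "p_value"])
    if len(table):
        table["fdr"] = adjust_fdr(table["p_value"].to_numpy())
        table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = []
    return table


def parse_signature_name(name: str) -> Optional[Tuple[str, str, str]]:
    """Parse '<driver>__<kd|oe>__<up|down>' into its parts (None if not parseable)."""
    match = SIGNATURE_NAME.match(name)
    if not match:
        return None
    return match["driver"], match["perturbation"], match["direction"]


def validate_driver_perturbation(
    module: Module,
    perturbation_sigs: GeneSetCollection,
    universe: Iterable[str],
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Check each module driver's role against directional perturbation
    signatures.

    A driver's role (activator/repressor from its weight sign) is "validated"
    when at least one role-consistent directional signature overlaps the
    module targets significantly (BH-FDR <= ``max_fdr`` across the tested
    signatures of the module); otherwise "unsupported".  Drivers with no
    parseable matching signature are absent from the table (warned).
    """
    universe_set = set(universe)
    targets = set(module.target_ids) & universe_set
    roles = classify_driver_roles(module.program)

    sig_index: Dict[str, List[Tuple[str, str, str]]] = {}
    for name in perturbation_sigs.names():
        parsed = parse_signature_name(name)
        if parsed is None:
            logger.warning("unparseable signature name %r, skipped", name)
            continue
        driver, perturbation, direction = parsed
        sig_index.setdefault(driver, []).append((name, perturbation, direction))

    rows = []
    for driver, role in roles.items():
        matches = sig_index.get(driver)
        if not matches:
            logger.warning("driver %s has no matching perturbation signature", driver)
            continue
        for name, perturbation, direction in matches:
            members = set(perturbation_sigs.genes(name)) & universe_set
            k, p = overlap_significance(targets, members, len(universe_set)) if members else (0, 1.0)
            rows.append({
                "driver": driver, "role": role, "signature": name,
                "perturbation": perturbation, "direction": direction,
                "overlap": k, "p_value": p,
                "consistent": CONSISTENT[(role, perturbation, direction)],
            })
    table = pd.DataFrame(rows, columns=["driver", "role", "signature", "perturbation",
                                        "direction", "overlap", "p_value", "consistent"])
    if not len(table):
        table["fdr"] = []
        table["verdict"] = []
        return table
    table["fdr"] = adjust_fdr(table["p_value"].to_numpy())
    significant = table["fdr"] <= max_fdr
    supported = set(table.loc[significant & table["consistent"], "driver"])
    table["verdict"] = table["driver"].map(
        lambda d: "validated" if d in supported else "unsupported"
    )
    return table.sort_values(["driver", "signature"], kind="stable").reset_index(drop=True)
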