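"""Recovery metrics against synthetic ground truth.

Inferred module ids are arbitrary (k-means labels), so driver-recovery
metrics first match each inferred module to the generating module that
contributes the majority of its targets.  A driver counts as *recovered*
only when its fitted |weight| reaches ``min_weight`` (0.1 by default):
Elastic Net retains tiny spurious coefficients that carry no regulatory
claim, and the program contract treats such near-zero weights as absent.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .simulate import GroundTruth
from .types import ModuleNetwork

MIN_RECOVERED_WEIGHT = 0.1


def target_partition_ari(network: ModuleNetwork, truth: GroundTruth) -> float:
    """Adjusted Rand index between the inferred and generating target
    partitions, over the genes present in both."""
    genes = sorted(set(network.assignment) & set(truth.assignment))
    if not genes:
        return float("nan")
    return float(adjusted_rand_score(
        [truth.assignment[g] for g in genes],
        [network.assignment[g] for g in genes],
    ))


def match_modules(network: ModuleNetwork, truth: GroundTruth) -> Dict[int, int]:
    """Map each inferred module id to the generating module supplying the
    majority of its targets (modules with no known targets are skipped)."""
    matches: Dict[int, int] = {}
    for module in network.modules:
        counts = Counter(
            truth.assignment[t] for t in module.target_ids if t in truth.assignment
        )
        if counts:
            matches[module.module_id] = counts.most_common(1)[0][0]
    return matches


def driver_recovery(
    network: ModuleNetwork,
    truth: GroundTruth,
    min_weight: float = MIN_RECOVERED_WEIGHT,
) -> Tuple[float, float, float]:
    """(mean precision, mean recall, sign agreement) of recovered drivers.

    Precision/recall are averaged over inferred modules against their matched
    generating programs; sign agreement is the fraction of recovered true
    drivers whose weight sign matches the generating sign.
    """
    matches = match_modules(network, truth)
    precisions, recalls = [], []
    sign_ok = sign_total = 0
    for module in network.modules:
        if module.module_id not in matches:
            continue
        true_weights = truth.programs[matches[module.module_id]]
        recovered = {d: w for d, w in module.program.weights.items()
                     if abs(w) >= min_weight}
        hits = set(recovered) & set(true_weights)
        precisions.append(len(hits) / len(recovered) if recovered else 0.0)
        recalls.append(len(hits) / len(true_weights) if true_weights else 1.0)
        for d in hits:
            sign_total += 1
            sign_ok += int(np.sign(recovered[d]) == np.sign(true_weights[d]))
    precision = float(np.mean(precisions)) if precisions else float("nan")
    recall = float(np.mean(recalls)) if recalls else float("nan")
    agreement = sign_ok / sign_total if sign_total else float("nan")
    return precision, recall, float(agreement)
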