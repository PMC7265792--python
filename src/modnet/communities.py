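"""Cross-cohort module map and community detection.

Every pair of modules from *different* cohorts is scored by the one-sided
upper-tail hypergeometric probability of their target-gene overlap; edges
passing a joint BH-FDR filter and a minimum-overlap filter form the module
map.  The map is partitioned with Girvan-Newman edge-betweenness removal,
keeping the partition along the removal dendrogram of maximal (unweighted)
Newman-Girvan modularity.  Communities spanning two or more cohorts mark
"shared" regulatory behavior; everything else is "distinct".
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import modularity as nx_modularity
from scipy import stats

from .associations import adjust_fdr
from .types import (
    Community,
    GeneSetCollection,
    ModuleMapEdge,
    ModuleNetwork,
    ModuleRef,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_FDR = 0.05
DEFAULT_MIN_OVERLAP = 5


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> Tuple[int, float]:
    """Hypergeometric upper-tail P(X >= k) for the overlap of two gene sets.

    Population = ``universe_size``, successes = ``|set_a|``, draws =
    ``|set_b|``, observed overlap k = ``|a ∩ b|``.  Computed in log space so
    tiny tail probabilities survive; symmetric in (set_a, set_b).
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValidationError(
            f"universe ({universe_size}) smaller than the union of the sets ({len(a | b)})"
        )
    k = len(a & b)
    if k == 0:
        return 0, 1.0
    logp = stats.hypergeom.logsf(k - 1, universe_size, len(a), len(b))
    return k, float(min(1.0, math.exp(logp)))


def _neg_log10_p(k: int, universe: int, na: int, nb: int) -> float:
    if k == 0:
        return 0.0
    logp = stats.hypergeom.logsf(k - 1, universe, na, nb)
    return float(-logp / math.log(10.0))


def build_module_map(
    networks: Sequence[ModuleNetwork],
    max_fdr: float = DEFAULT_MAX_FDR,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    universe_mode: str = "union",
) -> List[ModuleMapEdge]:
    """All pairwise cross-network module comparisons, jointly FDR-filtered.

    The hypergeometric universe for a pair of networks is the union (default)
    or intersection of the two cohorts' target-gene universes; with
    ``"intersection"`` the compared sets are restricted to that universe.
    Edges are kept when ``fdr <= max_fdr`` and ``overlap >= min_overlap``.
    Output order is deterministic: sorted by cohort/module of each endpoint.
    """
    if len(networks) < 2:
        raise ValidationError("module map requires >= 2 networks")
    if universe_mode not in ("union", "intersection"):
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    names = [n.cohort_name for n in networks]
    if len(set(names)) != len(names):
        raise ValidationError("cohort names must be unique across networks")

    any_shared = any(
        networks[i].target_universe & networks[j].target_universe
        for i in range(len(networks))
        for j in range(i + 1, len(networks))
    )
    if not any_shared:
        raise ValidationError("networks share no gene namespace")

    candidates: List[ModuleMapEdge] = []
    for i in range(len(networks)):
        for j in range(i + 1, len(networks)):
            net_a, net_b = networks[i], networks[j]
            uni_a, uni_b = net_a.target_universe, net_b.target_universe
            universe = uni_a | uni_b if universe_mode == "union" else uni_a & uni_b
            if not universe:
                continue
            for mod_a in net_a.modules:
                ta = set(mod_a.target_ids) & universe
                for mod_b in net_b.modules:
                    tb = set(mod_b.target_ids) & universe
                    if not ta or not tb:
                        continue
                    k, p = overlap_significance(ta, tb, len(universe))
                    candidates.append(ModuleMapEdge(
                        module_a=ModuleRef(net_a.cohort_name, mod_a.module_id),
                        module_b=ModuleRef(net_b.cohort_name, mod_b.module_id),
                        overlap_count=k,
                        p_value=p,
                        neg_log10_p=_neg_log10_p(k, len(universe), len(ta), len(tb)),
                    ))
    if not candidates:
        return []
    qs = adjust_fdr([e.p_value for e in candidates])
    kept = []
    for edge, q in zip(candidates, qs):
        edge.fdr = float(q)
        if edge.fdr <= max_fdr and edge.overlap_count >= min_overlap:
            kept.append(edge)
    kept.sort(key=lambda e: (e.module_a, e.module_b))
    return kept


def guide_networks(collection: GeneSetCollection, prefix: str = "guide") -> List[ModuleNetwork]:
    """Turn each gene set of a collection into a one-module pseudo-network.

    Guide networks participate in module-map edges (so modules can be
    annotated by known signatures) but are ignored when deciding whether a
    community spans multiple cohorts.
    """
    from .types import Module, RegulatoryProgram

    nets = []
    for name in collection.names():
        genes = collection.genes(name)
        nets.append(ModuleNetwork(
            cohort_name=f"{prefix}:{name}",
            modules=[Module(module_id=1, target_ids=list(genes),
                            program=RegulatoryProgram(weights={}))],
            assignment={g: 1 for g in genes},
            is_guide=True,
        ))
    return nets


def _edge_key(u, v) -> Tuple:
    return tuple(sorted((u, v)))


def module_map_graph(edges: Sequence[ModuleMapEdge]) -> nx.Graph:
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.module_a, e.module_b,
                       overlap=e.overlap_count, p_value=e.p_value,
                       neg_log10_p=e.neg_log10_p, fdr=e.fdr)
    return graph


def detect_communities(edges: Sequence[ModuleMapEdge]) -> List[Community]:
    """Girvan-Newman partition of the filtered module map.

    Repeatedly removes the edge of highest betweenness (ties broken by the
    lexicographically smallest endpoint pair), recording each new component
    partition, and returns the partition of maximal unweighted modularity on
    the original graph (earliest such partition on ties).  Components of size
    one are not communities.
    """
    if not edges:
        raise ValidationError("empty module map: no edges to partition")
    original = module_map_graph(edges)
    work = original.copy()

    def components(g: nx.Graph) -> List[Set]:
        return [set(c) for c in nx.connected_components(g)]

    partitions = [components(work)]
    while work.number_of_edges():
        betweenness = nx.edge_betweenness_centrality(work)
        top = max(betweenness.values())
        tied = [_edge_key(u, v) for (u, v), val in betweenness.items()
                if val >= top - 1e-12]
        u, v = min(tied)
        work.remove_edge(u, v)
        comps = components(work)
        if len(comps) != len(partitions[-1]):
            partitions.append(comps)

    scores = [nx_modularity(original, part) for part in partitions]
    best = int(np.argmax(scores))  # argmax keeps the earliest on exact ties
    chosen = partitions[best]

    communities = []
    multi = sorted(
        (sorted(c) for c in chosen if len(c) >= 2),
        key=lambda members: members[0],
    )
    for cid, members in enumerate(multi, start=1):
        member_set = set(members)
        internal = [e for e in edges
                    if e.module_a in member_set and e.module_b in member_set]
        communities.append(Community(community_id=cid, members=list(members),
                                     edges=internal))
    return communities


def classify_shared_distinct(
    networks: Sequence[ModuleNetwork],
    communities: Sequence[Community],
) -> Dict[ModuleRef, str]:
    """Label every (non-guide) module "shared" or "distinct".

    A module is "shared" iff it sits in a community whose members span at
    least two distinct non-guide cohorts; guide pseudo-networks never flip a
    label by themselves.
    """
    guide_cohorts = {n.cohort_name for n in networks if n.is_guide}
    labels: Dict[ModuleRef, str] = {}
    for net in networks:
        if net.is_guide:
            continue
        for module in net.modules:
            labels[ModuleRef(net.cohort_name, module.module_id)] = "distinct"
    for community in communities:
        real_cohorts = {m.cohort for m in community.members if m.cohort not in guide_cohorts}
        if len(real_cohorts) >= 2:
            for member in community.members:
                if member in labels:
                    labels[member] = "shared"
    return labels


def module_map_to_frame(edges: Sequence[ModuleMapEdge]) -> pd.DataFrame:
    rows = [{
        "cohort_a": e.module_a.cohort, "module_a": e.module_a.module_id,
        "cohort_b": e.module_b.cohort, "module_b": e.module_b.module_id,
        "overlap": e.overlap_count, "p_value": e.p_value,
        "neg_log10_p": e.neg_log10_p, "fdr": e.fdr,
    } for e in edges]
    return pd.DataFrame(rows, columns=["cohort_a", "module_a", "cohort_b", "module_b",
                                       "overlap", "p_value", "neg_log10_p", "fdr"])


def communities_to_frame(communities: Sequence[Community]) -> pd.DataFrame:
    rows = []
    for c in communities:
        for m in c.members:
            rows.append({"community_id": c.community_id, "cohort": m.cohort,
                         "module_id": m.module_id})
    return pd.DataFrame(rows, columns=["community_id", "cohort", "module_id"])
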