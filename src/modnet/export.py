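"""Serialization of inferred networks: TSV tables and node-link graph JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .inference import classify_driver_roles
from .types import Community, ModuleNetwork, ModuleRef

GRAPH_SCHEMA_VERSION = "1.0"


def modules_to_frame(network: ModuleNetwork) -> pd.DataFrame:
    rows = [{
        "module_id": m.module_id,
        "n_targets": len(m.target_ids),
        "fit_r2": m.program.fit_r2,
        "targets": ",".join(m.target_ids),
    } for m in sorted(network.modules, key=lambda m: m.module_id)]
    return pd.DataFrame(rows, columns=["module_id", "n_targets", "fit_r2", "targets"])


def programs_to_frame(network: ModuleNetwork) -> pd.DataFrame:
    rows = []
    for m in sorted(network.modules, key=lambda m: m.module_id):
        roles = classify_driver_roles(m.program)
        for driver in sorted(m.program.weights):
            rows.append({
                "module_id": m.module_id, "driver": driver,
                "weight": m.program.weights[driver], "role": roles[driver],
            })
    return pd.DataFrame(rows, columns=["module_id", "driver", "weight", "role"])


def network_metadata(network: ModuleNetwork) -> Dict[str, object]:
    return {
        "cohort_name": network.cohort_name,
        "n_modules": len(network.modules),
        "n_targets": len(network.assignment),
        "n_iterations": network.n_iterations,
        "converged": network.converged,
        "reassignment_trace": network.reassignment_trace,
        "settings": network.settings,
    }


def write_network(network: ModuleNetwork, outdir, prefix: str = "") -> Dict[str, Path]:
    """Write modules/programs TSVs and run metadata JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or network.cohort_name
    paths = {
        "modules": outdir / f"{prefix}_modules.tsv",
        "programs": outdir / f"{prefix}_programs.tsv",
        "metadata": outdir / f"{prefix}_run_metadata.json",
    }
    modules_to_frame(network).to_csv(paths["modules"], sep="\t", index=False)
    programs_to_frame(network).to_csv(paths["programs"], sep="\t", index=False)
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        json.dump(network_metadata(network), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_network(modules_path, programs_path, metadata_path=None) -> ModuleNetwork:
    """Rebuild a ModuleNetwork from its modules/programs TSVs (and optional
    run-metadata JSON)."""
    from .types import Module, RegulatoryProgram

    modules_frame = pd.read_csv(modules_path, sep="\t")
    programs_frame = pd.read_csv(programs_path, sep="\t")
    meta: Dict[str, object] = {}
    if metadata_path is not None:
        with open(metadata_path, encoding="utf-8") as fh:
            meta = json.load(fh)
    modules = []
    assignment: Dict[str, int] = {}
    for _, row in modules_frame.iterrows():
        mid = int(row["module_id"])
        targets = str(row["targets"]).split(",") if str(row["targets"]) else []
        weights = {
            r["driver"]: float(r["weight"])
            for _, r in programs_frame[programs_frame["module_id"] == mid].iterrows()
        }
        modules.append(Module(
            module_id=mid, target_ids=targets,
            program=RegulatoryProgram(weights=weights,
                                      fit_r2=float(row.get("fit_r2", 0.0)),
                                      raw_r2=float(row.get("fit_r2", 0.0))),
        ))
        for t in targets:
            assignment[t] = mid
    return ModuleNetwork(
        cohort_name=str(meta.get("cohort_name", Path(str(modules_path)).stem.replace("_modules", ""))),
        modules=modules,
        assignment=assignment,
        n_iterations=int(meta.get("n_iterations", 0)),
        converged=bool(meta.get("converged", True)),
        reassignment_trace=list(meta.get("reassignment_trace", [])),
        settings=dict(meta.get("settings", {})),
    )


def export_network_json(
    networks: Sequence[ModuleNetwork],
    communities: Optional[Sequence[Community]] = None,
    module_map_edges=None,
) -> Dict[str, object]:
    """Generic node-link document of drivers, targets, modules and communities.

    Nodes carry a ``type`` attribute in {driver, target, module, community};
    edges one of {driver_module (signed weight), module_target,
    module_module (overlap stats), module_community}.  The schema is
    versioned via ``schema_version``.
    """
    nodes: List[dict] = []
    edges: List[dict] = []
    seen = set()

    def add_node(node_id: str, node_type: str, **attrs) -> None:
        if node_id not in seen:
            seen.add(node_id)
            nodes.append({"id": node_id, "type": node_type, **attrs})

    for net in networks:
        for module in sorted(net.modules, key=lambda m: m.module_id):
            mid = str(ModuleRef(net.cohort_name, module.module_id))
            add_node(mid, "module", cohort=net.cohort_name,
                     n_targets=len(module.target_ids), fit_r2=module.program.fit_r2)
            for driver, weight in sorted(module.program.weights.items()):
                add_node(driver, "driver")
                edges.append({"source": driver, "target": mid,
                              "type": "driver_module", "weight": weight})
            for target in module.target_ids:
                add_node(target, "target")
                edges.append({"source": mid, "target": target, "type": "module_target"})
    if module_map_edges:
        for e in module_map_edges:
            edges.append({
                "source": str(e.module_a), "target": str(e.module_b),
                "type": "module_module", "overlap": e.overlap_count,
                "p_value": e.p_value, "neg_log10_p": e.neg_log10_p, "fdr": e.fdr,
            })
    if communities:
        for c in communities:
            cid = f"community:{c.community_id}"
            add_node(cid, "community", n_members=len(c.members))
            for member in c.members:
                edges.append({"source": str(member), "target": cid,
                              "type": "module_community"})
    return {"schema_version": GRAPH_SCHEMA_VERSION, "nodes": nodes, "edges": edges}


def validate_graph_document(doc: Dict[str, object]) -> None:
    """Raise ValueError when a node-link document violates the schema."""
    if doc.get("schema_version") != GRAPH_SCHEMA_VERSION:
        raise ValueError("missing or unsupported schema_version")
    node_ids = set()
    for node in doc["nodes"]:
        if "id" not in node or node.get("type") not in {"driver", "target", "module", "community"}:
            raise ValueError(f"invalid node: {node}")
        node_ids.add(node["id"])
    for edge in doc["edges"]:
        if edge.get("type") not in {"driver_module", "module_target",
                                    "module_module", "module_community"}:
            raise ValueError(f"invalid edge type: {edge}")
        if edge["source"] not in node_ids or edge["target"] not in node_ids:
            raise ValueError(f"edge references unknown node: {edge}")
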