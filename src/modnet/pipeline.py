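"""End-to-end orchestration: per-cohort inference, cross-cohort communities,
phenotype associations, enrichment/validation, and report generation.

The pipeline is driven by a YAML/JSON config (or an equivalent dict):

.. code-block:: yaml

    output_dir: out
    seed: 1
    parameters: {n_modules: 5, percent: 1.0, mixing: 0.5,
                 max_iter: 100, conv_frac: 0.01, max_fdr: 0.05, min_overlap: 5}
    cohorts:
      - name: cohortA
        expression: cohortA_expression.tsv
        cnv: cohortA_cnv.tsv             # optional
        methylation: cohortA_met.tsv     # optional
        driver_list: cohortA_drivers.txt # optional if omics layers given
        phenotypes: cohortA_phenotypes.tsv        # optional
        phenotype_schema: cohortA_schema.json     # required with phenotypes
    gene_sets: collections.gmt           # optional, enrichment
    perturbation_sets: perturbations.gmt # optional, driver validation

Each stage appends to a manifest written to the output directory; a failing
stage leaves completed artifacts in place with the manifest recording how far
the run got.  All output tables are sorted on documented keys so reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .associations import (
    associate_phenotypes,
    combine_across_cohorts,
    results_to_frame,
)
from .communities import (
    build_module_map,
    classify_shared_distinct,
    communities_to_frame,
    detect_communities,
    guide_networks,
    module_map_to_frame,
)
from .drivers import (
    assemble_candidate_drivers,
    flag_copy_number_driven,
    flag_methylation_driven,
)
from .enrichment import enrich_gene_sets, validate_driver_perturbation
from .export import export_network_json, write_network
from .inference import compute_module_scores, run_module_inference
from .io import (
    read_driver_list,
    read_expression_table,
    read_gene_sets,
    read_phenotype_table,
    write_expression_table,
    write_gene_sets,
    write_phenotype_schema,
    write_phenotype_table,
)
from .report import write_report
from .types import (
    DriverCatalog,
    ExpressionMatrix,
    ModuleRef,
    OmicsBundle,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config is missing or misdeclaring a required key."""


DEFAULT_PARAMETERS: Dict[str, object] = {
    "n_modules": 100,
    "percent": 0.5,
    "mixing": 0.5,
    "max_iter": 100,
    "conv_frac": 0.01,
    "max_fdr": 0.05,
    "min_overlap": 5,
    "min_abs_corr": 0.3,
    "universe_mode": "union",
}


def load_config(config: Union[str, Path, Mapping]) -> Dict:
    if isinstance(config, Mapping):
        return dict(config)
    path = Path(config)
    with open(path, encoding="utf-8") as fh:
        loaded = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    loaded.setdefault("_base_dir", str(path.parent))
    return loaded


def _resolve(base_dir: Optional[str], value: str) -> Path:
    path = Path(value)
    if not path.is_absolute() and base_dir:
        path = Path(base_dir) / path
    return path


def _load_cohort(entry: Mapping, base_dir: Optional[str], params: Mapping):
    if "name" not in entry:
        raise ConfigError("cohort entry missing required key 'name'")
    name = entry["name"]
    if "expression" not in entry:
        raise ConfigError(f"cohort {name!r}: missing required key 'expression'")
    expr = read_expression_table(_resolve(base_dir, entry["expression"]))
    cnv = met = None
    if entry.get("cnv"):
        cnv = read_expression_table(_resolve(base_dir, entry["cnv"]))
    if entry.get("methylation"):
        met = read_expression_table(_resolve(base_dir, entry["methylation"]))
    bundle = OmicsBundle(expression=expr, cnv=cnv, methylation=met, cohort_name=name)

    user_lists: List[List[str]] = []
    if entry.get("driver_list"):
        user_lists.append(read_driver_list(_resolve(base_dir, entry["driver_list"])))
    cnv_flags = met_flags = None
    if cnv is not None:
        cnv_flags = flag_copy_number_driven(
            expr, cnv, min_abs_corr=params["min_abs_corr"], max_fdr=params["max_fdr"])
    if met is not None:
        met_flags = flag_methylation_driven(
            expr, met, min_abs_corr=params["min_abs_corr"], max_fdr=params["max_fdr"])
    if not user_lists and cnv is None and met is None:
        raise ConfigError(
            f"cohort {name!r}: expression-only cohorts require a 'driver_list'"
        )
    catalog = assemble_candidate_drivers(user_lists, expr,
                                         cnv_flags=cnv_flags, met_flags=met_flags)

    phenotypes = None
    if entry.get("phenotypes"):
        if not entry.get("phenotype_schema"):
            raise ConfigError(f"cohort {name!r}: 'phenotypes' requires 'phenotype_schema'")
        phenotypes = read_phenotype_table(
            _resolve(base_dir, entry["phenotypes"]),
            _resolve(base_dir, entry["phenotype_schema"]),
        )
    return bundle, catalog, phenotypes


def run_pipeline(config: Union[str, Path, Mapping], output_dir: Optional[Union[str, Path]] = None) -> Dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    cfg = load_config(config)
    base_dir = cfg.get("_base_dir")
    if output_dir is None:
        if "output_dir" not in cfg:
            raise ConfigError("config missing required key 'output_dir'")
        output_dir = _resolve(base_dir, cfg["output_dir"])
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = dict(DEFAULT_PARAMETERS)
    params.update(cfg.get("parameters", {}))
    seed = int(cfg.get("seed", 0))
    manifest: Dict[str, object] = {"completed_stages": [], "artifacts": []}

    def record(stage: str, *paths: Path) -> None:
        manifest["completed_stages"].append(stage)
        manifest["artifacts"].extend(str(Path(p).name) for p in paths)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    try:
        cohort_entries = cfg.get("cohorts")
        if not cohort_entries:
            raise ConfigError("config missing required key 'cohorts'")

        # -- stage 1: per-cohort inference ---------------------------------
        networks = []
        scores_by_cohort: Dict[str, pd.DataFrame] = {}
        phenotypes_by_cohort: Dict[str, Optional[PhenotypeTable]] = {}
        universes: Dict[str, List[str]] = {}
        for entry in cohort_entries:
            bundle, catalog, phenotypes = _load_cohort(entry, base_dir, params)
            name = bundle.cohort_name
            network = run_module_inference(
                bundle, catalog,
                K=int(params["n_modules"]), percent=float(params["percent"]),
                mixing=float(params["mixing"]), max_iter=int(params["max_iter"]),
                conv_frac=float(params["conv_frac"]), seed=seed,
            )
            networks.append(network)
            scores = compute_module_scores(network, bundle.expression)
            scores_by_cohort[name] = scores
            phenotypes_by_cohort[name] = phenotypes
            universes[name] = sorted(network.target_universe)
            paths = write_network(network, outdir)
            catalog.to_frame().to_csv(outdir / f"{name}_drivers.tsv", sep="\t", index=False)
            scores_path = outdir / f"{name}_scores.tsv"
            scores.sort_index().to_csv(scores_path, sep="\t")
            record(f"inference:{name}", *paths.values(),
                   outdir / f"{name}_drivers.tsv", scores_path)

        # -- stage 2: module map and communities ---------------------------
        edges: List = []
        communities: List = []
        labels: Dict[ModuleRef, str] = {}
        if len(networks) >= 2:
            all_networks = list(networks)
            if cfg.get("gene_sets"):
                all_networks += guide_networks(
                    read_gene_sets(_resolve(base_dir, cfg["gene_sets"])))
            edges = build_module_map(
                all_networks, max_fdr=float(params["max_fdr"]),
                min_overlap=int(params["min_overlap"]),
                universe_mode=str(params["universe_mode"]),
            )
            communities = detect_communities(edges) if edges else []
            labels = classify_shared_distinct(all_networks, communities)
            map_path = outdir / "module_map.tsv"
            module_map_to_frame(edges).to_csv(map_path, sep="\t", index=False)
            com_path = outdir / "communities.tsv"
            communities_to_frame(communities).to_csv(com_path, sep="\t", index=False)
            labels_frame = pd.DataFrame(
                [{"cohort": ref.cohort, "module_id": ref.module_id, "label": lab}
                 for ref, lab in sorted(labels.items())],
                columns=["cohort", "module_id", "label"],
            )
            labels_path = outdir / "module_labels.tsv"
            labels_frame.to_csv(labels_path, sep="\t", index=False)
            record("communities", map_path, com_path, labels_path)

        # -- stage 3: phenotype associations -------------------------------
        module_results = {}
        association_frames = []
        for name, scores in scores_by_cohort.items():
            phenotypes = phenotypes_by_cohort[name]
            if phenotypes is None:
                continue
            results = associate_phenotypes(scores, phenotypes, cohort=name)
            module_results[name] = results
            association_frames.append(results_to_frame(results))
        if association_frames:
            assoc = pd.concat(association_frames, ignore_index=True)
            assoc = assoc.sort_values(["cohort", "phenotype", "module_id"],
                                      kind="stable").reset_index(drop=True)
            assoc_path = outdir / "associations.tsv"
            assoc.to_csv(assoc_path, sep="\t", index=False)
            record("associations", assoc_path)

            if communities:
                combined_rows = []
                lookup = {}
                for results in module_results.values():
                    for r in results:
                        lookup.setdefault((r.module_ref, r.phenotype), r)
                phenos = sorted({r.phenotype for rs in module_results.values() for r in rs})
                for community in communities:
                    for phen in phenos:
                        members = [lookup[((m.cohort, m.module_id), phen)]
                                   for m in community.members
                                   if ((m.cohort, m.module_id), phen) in lookup]
                        if not members:
                            continue
                        combined = combine_across_cohorts(
                            members, community_id=f"community:{community.community_id}",
                            phenotype=phen)
                        combined_rows.append({
                            "community_id": community.community_id, "phenotype": phen,
                            "test": combined.test, "statistic": combined.statistic,
                            "direction": combined.effect_direction,
                            "p_value": combined.p_value, "n_members": combined.n_used,
                            "members": combined.note,
                        })
                cassoc = pd.DataFrame(combined_rows,
                                      columns=["community_id", "phenotype", "test",
                                               "statistic", "direction", "p_value",
                                               "n_members", "members"])
                cassoc = cassoc.sort_values(["community_id", "phenotype"],
                                            kind="stable").reset_index(drop=True)
                cpath = outdir / "community_associations.tsv"
                cassoc.to_csv(cpath, sep="\t", index=False)
                record("community_associations", cpath)

        # -- stage 4: enrichment and driver validation ---------------------
        if cfg.get("gene_sets"):
            collection = read_gene_sets(_resolve(base_dir, cfg["gene_sets"]))
            enrich_frames = []
            for network in networks:
                universe = universes[network.cohort_name]
                universe_set = set(universe)
                for module in network.modules:
                    table = enrich_gene_sets(
                        set(module.target_ids) & universe_set, collection, universe)
                    table.insert(0, "module_id", module.module_id)
                    table.insert(0, "cohort", network.cohort_name)
                    enrich_frames.append(table)
            enrichment = pd.concat(enrich_frames, ignore_index=True)
            enrichment = enrichment.sort_values(
                ["cohort", "module_id", "p_value", "set_name"],
                kind="stable").reset_index(drop=True)
            epath = outdir / "enrichment.tsv"
            enrichment.to_csv(epath, sep="\t", index=False)
            record("enrichment", epath)

        if cfg.get("perturbation_sets"):
            sigs = read_gene_sets(_resolve(base_dir, cfg["perturbation_sets"]))
            val_frames = []
            for network in networks:
                universe = universes[network.cohort_name]
                for module in network.modules:
                    table = validate_driver_perturbation(
                        module, sigs, universe, max_fdr=float(params["max_fdr"]))
                    if len(table):
                        table.insert(0, "module_id", module.module_id)
                        table.insert(0, "cohort", network.cohort_name)
                        val_frames.append(table)
            if val_frames:
                validation = pd.concat(val_frames, ignore_index=True)
                validation = validation.sort_values(
                    ["cohort", "module_id", "driver", "signature"],
                    kind="stable").reset_index(drop=True)
                vpath = outdir / "validation.tsv"
                validation.to_csv(vpath, sep="\t", index=False)
                record("validation", vpath)

        # -- stage 5: exports, metadata, report ----------------------------
        doc = export_network_json(networks, communities=communities,
                                  module_map_edges=edges)
        graph_path = outdir / "network.json"
        with open(graph_path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
        meta = {
            "parameters": params, "seed": seed,
            "modnet_version": __version__,
            "python_version": platform.python_version(),
            "cohorts": [n.cohort_name for n in networks],
        }
        meta_path = outdir / "run_metadata.json"
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
        record("export", graph_path, meta_path)

        tables = {}
        for network in networks:
            frame = pd.read_csv(outdir / f"{network.cohort_name}_modules.tsv", sep="\t")
            tables[f"Modules ({network.cohort_name})"] = frame.drop(columns=["targets"])
        for fname, title in [("module_map.tsv", "Module map"),
                             ("communities.tsv", "Communities"),
                             ("module_labels.tsv", "Shared/distinct labels"),
                             ("associations.tsv", "Module-phenotype associations"),
                             ("community_associations.tsv", "Community-phenotype associations"),
                             ("enrichment.tsv", "Functional enrichment"),
                             ("validation.tsv", "Driver perturbation validation")]:
            path = outdir / fname
            if path.exists():
                tables[title] = pd.read_csv(path, sep="\t")
        report_path = write_report(tables, outdir / "index.html",
                                   artifacts=sorted(set(manifest["artifacts"])))
        record("report", report_path)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def write_cohort(
    outdir: Union[str, Path],
    name: str,
    bundle: OmicsBundle,
    catalog: DriverCatalog,
    phenotypes: Optional[PhenotypeTable] = None,
    truth=None,
) -> Dict[str, str]:
    """Write a (typically simulated) cohort in the formats the pipeline reads;
    returns a config-ready cohort entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entry: Dict[str, str] = {"name": name}
    write_expression_table(bundle.expression, outdir / f"{name}_expression.tsv")
    entry["expression"] = f"{name}_expression.tsv"
    if bundle.cnv is not None:
        write_expression_table(bundle.cnv, outdir / f"{name}_cnv.tsv")
        entry["cnv"] = f"{name}_cnv.tsv"
    if bundle.methylation is not None:
        write_expression_table(bundle.methylation, outdir / f"{name}_met.tsv")
        entry["methylation"] = f"{name}_met.tsv"
    with open(outdir / f"{name}_drivers.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(catalog.driver_ids) + "\n")
    entry["driver_list"] = f"{name}_drivers.txt"
    if phenotypes is not None:
        write_phenotype_table(phenotypes, outdir / f"{name}_phenotypes.tsv")
        write_phenotype_schema(phenotypes, outdir / f"{name}_schema.json")
        entry["phenotypes"] = f"{name}_phenotypes.tsv"
        entry["phenotype_schema"] = f"{name}_schema.json"
    if truth is not None:
        truth.to_json(outdir / f"{name}_ground_truth.json")
    return entry
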