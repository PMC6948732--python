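"""Pipeline orchestration: one validated configuration drives
preprocess -> differential -> enrichment -> cross-omics -> network stages.

Stages communicate through files (TSV/JSON) under the configured output
directory, so any stage can be re-run independently; every random choice
derives from the single configured seed; the run report collects the
detected/filtered/significant counts per layer together with enrichment,
concordance and network summaries, and is written both as JSON and as
human-readable markdown. The report contains no timestamps, so two runs
from one config are byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import crossomics, differential, enrichment, io, netpath, preprocess
from .containers import FeatureMatrix
from .differential import DesignSpec
from .lipids import build_lipid_sets, parse_lipid_name, FeatureSet, LipidNameError

log = logging.getLogger(__name__)

__all__ = ["ConfigError", "StageError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Configuration failed validation; ``errors`` lists every problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid pipeline configuration:\n- " + "\n- ".join(errors))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


_LAYER_KEYS = {
    "untargeted_lipidomics": {"path", "groups"},
    "targeted_lipidomics": {"path", "format", "groups"},
    "proteomics": {"path", "format", "groups"},
    "transcriptomics": {"gct", "groups", "probe_map"},
    "network": {"json"},
    "gene_sets": {"gmt"},
}

_DEFAULTS = {
    "seed": 0,
    "output_dir": "results/pipeline",
    "preprocess": {"presence_threshold": 0.75, "min_unique_peptides": 2,
                   "min_score": 5.0, "mar_cutoff": 0.25, "lls_neighbors": 10,
                   "mnar_sd_factor": 0.3},
    "differential": {"p_threshold": 0.05, "lfc_threshold": 1.5,
                     "use_adjusted": False},
    "enrichment": {"n_perm": 1000, "weight_exponent": 1.0, "min_size": 3},
    "network": {"k": 50, "min_length": 6, "max_length": 12, "aggregate": "max"},
}


def validate_config(source) -> dict:
    """Validate and normalize a pipeline configuration.

    ``source`` is a YAML/JSON file path or an already-loaded mapping.
    Unknown keys are rejected (typo safety), defaults are filled in, and
    every defaulted parameter is echoed under ``provenance.defaulted``.
    Raises :class:`ConfigError` carrying the full error list.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = copy.deepcopy(source)
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])

    errors: list[str] = []
    defaulted: list[str] = []
    cfg: dict = {}

    known_top = set(_DEFAULTS) | {"comparisons", "layers"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown key: {key!r}")

    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            block = raw.get(key, {})
            if not isinstance(block, dict):
                errors.append(f"{key} must be a mapping")
                block = {}
            for sub in block:
                if sub not in default:
                    errors.append(f"unknown key: {key}.{sub!r}")
            merged = dict(default)
            for sub, dv in default.items():
                if sub in block:
                    merged[sub] = block[sub]
                else:
                    defaulted.append(f"{key}.{sub}={dv}")
            cfg[key] = merged
        else:
            if key in raw:
                cfg[key] = raw[key]
            else:
                cfg[key] = default
                defaulted.append(f"{key}={default}")

    comparisons = raw.get("comparisons", [])
    if not comparisons:
        errors.append("comparisons: at least one comparison is required")
    norm_comps = []
    for i, comp in enumerate(comparisons):
        if not isinstance(comp, dict):
            errors.append(f"comparisons[{i}] must be a mapping")
            continue
        unknown = set(comp) - {"name", "numerator", "denominator"}
        if unknown:
            errors.append(f"comparisons[{i}]: unknown keys {sorted(unknown)}")
        num, den = comp.get("numerator"), comp.get("denominator")
        if not num or not den or num == den:
            errors.append(f"comparisons[{i}] ({comp.get('name', '?')}): needs two "
                          "distinct groups (numerator and denominator)")
            continue
        norm_comps.append({"name": comp.get("name", f"{num}.{den}"),
                           "numerator": num, "denominator": den})
    cfg["comparisons"] = norm_comps

    layers = raw.get("layers", {})
    norm_layers = {}
    for name, block in layers.items():
        if name not in _LAYER_KEYS:
            errors.append(f"unknown layer: {name!r}")
            continue
        unknown = set(block) - _LAYER_KEYS[name]
        if unknown:
            errors.append(f"layers.{name}: unknown keys {sorted(unknown)}")
            continue
        for fkey in ("path", "gct", "json", "gmt", "probe_map"):
            if fkey in block and block[fkey] is not None:
                if not Path(block[fkey]).exists():
                    errors.append(f"layers.{name}.{fkey}: file not found: "
                                  f"{block[fkey]}")
        norm_layers[name] = dict(block)
    cfg["layers"] = norm_layers

    p = cfg["preprocess"]
    for fkey in ("presence_threshold", "mar_cutoff"):
        if not 0 < p[fkey] <= 1:
            errors.append(f"preprocess.{fkey}: must be in (0, 1], got {p[fkey]}")

    if errors:
        raise ConfigError(errors)
    cfg["provenance"] = {"defaulted": sorted(defaulted)}
    return cfg


# --------------------------------------------------------------------- run
def _load_feature_layer(name: str, block: dict) -> FeatureMatrix:
    groups = {str(k): str(v) for k, v in block["groups"].items()}
    fmt = block.get("format", "tsv")
    if fmt == "skyline":
        return io.read_skyline_long(block["path"], groups)
    return io.read_feature_matrix(block["path"], groups)


def _layer_designs(cfg: dict, groups: dict) -> list[DesignSpec]:
    labels = set(groups.values())
    d = cfg["differential"]
    return [DesignSpec(contrast=(c["numerator"], c["denominator"]),
                       use_adjusted=d["use_adjusted"],
                       p_threshold=d["p_threshold"],
                       lfc_threshold=d["lfc_threshold"])
            for c in cfg["comparisons"]
            if {c["numerator"], c["denominator"]} <= labels]


def run_pipeline(config) -> dict:
    """Execute every stage the configuration enables; return the run report.

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage. Artifacts (per-stage TSV/JSON files, the report as
    ``report.json`` and ``report.md``) are written under ``output_dir``.
    """
    cfg = validate_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    pcfg = preprocess.PreprocessConfig(seed=seed, **{
        k: v for k, v in cfg["preprocess"].items()})

    report: dict = {"layers": {}, "enrichment": {}, "concordance": {},
                    "network": {},
                    "provenance": {"seed": seed,
                                   "defaulted": cfg["provenance"]["defaulted"],
                                   "parameters": {k: cfg[k] for k in _DEFAULTS
                                                  if isinstance(cfg[k], dict)}}}

    processed: dict[str, FeatureMatrix] = {}
    diff_results: dict[tuple[str, str], pd.DataFrame] = {}

    # ---- preprocess + differential per layer
    for layer in ("untargeted_lipidomics", "targeted_lipidomics", "proteomics"):
        if layer not in cfg["layers"]:
            continue
        try:
            block = cfg["layers"][layer]
            if layer == "proteomics":
                fmt = block.get("format", "tsv")
                groups = {str(k): str(v) for k, v in block["groups"].items()}
                if fmt == "maxquant":
                    table = io.read_maxquant(block["path"], groups)
                else:
                    table = io.read_protein_table(block["path"], groups)
                detected = len(table.protein_ids)
                table = preprocess.preprocess_proteomics(table, pcfg)
                m = table.as_feature_matrix()
                m.scale = "log2"
            else:
                raw_m = _load_feature_layer(layer, block)
                detected = len(raw_m.feature_ids)
                if layer == "untargeted_lipidomics":
                    m = preprocess.preprocess_untargeted_lipidomics(raw_m, pcfg)
                else:
                    m = preprocess.preprocess_targeted_lipidomics(raw_m, pcfg)
            processed[layer] = m
            io.write_feature_matrix(m, out / f"{layer}.processed.tsv")
            io.write_provenance(out / f"{layer}.provenance.json",
                                steps=[s for s in m.provenance
                                       if isinstance(s, str)],
                                parameters=cfg["preprocess"], seed=seed)
            layer_report = {"detected": detected, "filtered": len(m.feature_ids),
                            "comparisons": {}}
            for design in _layer_designs(cfg, m.groups):
                res = differential.run_differential(m, design)
                diff_results[(layer, design.name)] = res
                differential.write_results(
                    res, out / f"{layer}.{design.name}.differential.tsv")
                layer_report["comparisons"][design.name] = (
                    differential.summarize_counts(res))
            report["layers"][layer] = layer_report
        except Exception as exc:                      # noqa: BLE001
            raise StageError(layer, exc) from exc

    # ---- transcriptomics (GCT + probe collapse)
    if "transcriptomics" in cfg["layers"]:
        try:
            block = cfg["layers"]["transcriptomics"]
            expr = io.read_gct(block["gct"])
            detected = expr.shape[0]
            if block.get("probe_map"):
                mapping = io.read_id_mapping(block["probe_map"])
                expr = crossomics.collapse_probes(expr, mapping)
            groups = {str(k): str(v) for k, v in block["groups"].items()}
            m = FeatureMatrix(values=expr[[c for c in expr.columns
                                           if c in groups]],
                              groups=groups, scale="log2")
            processed["transcriptomics"] = m
            layer_report = {"detected": detected, "filtered": len(m.feature_ids),
                            "comparisons": {}}
            for design in _layer_designs(cfg, m.groups):
                res = differential.run_differential(m, design)
                diff_results[("transcriptomics", design.name)] = res
                differential.write_results(
                    res, out / f"transcriptomics.{design.name}.differential.tsv")
                layer_report["comparisons"][design.name] = (
                    differential.summarize_counts(res))
            report["layers"]["transcriptomics"] = layer_report
        except Exception as exc:                      # noqa: BLE001
            raise StageError("transcriptomics", exc) from exc

    # ---- enrichment
    ecfg = cfg["enrichment"]
    enrich_results: dict[tuple[str, str], pd.DataFrame] = {}
    try:
        # lipid sets for the targeted panel
        if "targeted_lipidomics" in processed:
            m = processed["targeted_lipidomics"]
            species = []
            for f in m.feature_ids:
                try:
                    species.append(parse_lipid_name(f))
                except LipidNameError:
                    log.warning("unparseable lipid name skipped: %r", f)
            sets = build_lipid_sets(species)
            for (layer, comp), res in list(diff_results.items()):
                if layer != "targeted_lipidomics":
                    continue
                ranking = res["logFC"].dropna().to_dict()
                edf = enrichment.preranked_enrichment(
                    ranking, sets, n_perm=ecfg["n_perm"],
                    weight_exponent=ecfg["weight_exponent"], seed=seed,
                    min_size=ecfg["min_size"])
                enrich_results[(layer, comp)] = edf
                enrichment.write_enrichment(
                    edf, out / f"{layer}.{comp}.enrichment.tsv")
        # pathway sets for proteomics / transcriptomics
        if "gene_sets" in cfg["layers"]:
            gmt = io.read_gmt(cfg["layers"]["gene_sets"]["gmt"])
            sets = [FeatureSet(sid, "pathway", members)
                    for sid, members in gmt.items()]
            for (layer, comp), res in list(diff_results.items()):
                if layer not in ("proteomics", "transcriptomics"):
                    continue
                ranking = res["logFC"].dropna().to_dict()
                edf = enrichment.preranked_enrichment(
                    ranking, sets, n_perm=ecfg["n_perm"],
                    weight_exponent=ecfg["weight_exponent"], seed=seed,
                    min_size=ecfg["min_size"])
                enrich_results[(layer, comp)] = edf
                enrichment.write_enrichment(
                    edf, out / f"{layer}.{comp}.enrichment.tsv")
        for (layer, comp), edf in enrich_results.items():
            report["enrichment"][f"{layer}:{comp}"] = {
                "n_sets": int(edf.shape[0]),
                "significant_adj": int((edf["adj_p_value"] < 0.05).sum()),
            }
    except Exception as exc:                          # noqa: BLE001
        raise StageError("enrichment", exc) from exc

    # ---- cross-omics concordance (proteomics vs transcriptomics)
    try:
        for comp in {c["name"] for c in cfg["comparisons"]}:
            key_p = ("proteomics", comp)
            key_t = ("transcriptomics", comp)
            if key_p in diff_results and key_t in diff_results:
                rp, rt = diff_results[key_p], diff_results[key_t]
                universe = sorted(set(rp.index) & set(rt.index))
                if not universe:
                    continue
                summ = crossomics.concordance(
                    rp[rp["significant_raw"]], rt[rt["significant_raw"]],
                    universe)
                report["concordance"][f"genes:{comp}"] = summ.as_dict()
            if key_p in enrich_results and key_t in enrich_results:
                ep, et = enrich_results[key_p], enrich_results[key_t]
                uni = sorted(set(ep.index) & set(et.index))
                if not uni:
                    continue
                sig_p = ep[ep["p_value"] < 0.05].assign(logFC=lambda d: d["ES"])
                sig_t = et[et["p_value"] < 0.05].assign(logFC=lambda d: d["ES"])
                summ = crossomics.concordance(sig_p, sig_t, uni)
                report["concordance"][f"pathways:{comp}"] = summ.as_dict()
        if report["concordance"]:
            (out / "concordance.json").write_text(
                json.dumps(report["concordance"], indent=2, sort_keys=True) + "\n")
    except Exception as exc:                          # noqa: BLE001
        raise StageError("crossomics", exc) from exc

    # ---- network path mining (needs network JSON + transcriptomics)
    if "network" in cfg["layers"] and "transcriptomics" in processed:
        try:
            ncfg = cfg["network"]
            net = netpath.MetabolicNetwork.from_json(
                cfg["layers"]["network"]["json"])
            g = netpath.build_reaction_graph(net)
            m = processed["transcriptomics"]
            g = netpath.weight_edges(g, m.values, dict(m.groups),
                                     aggregate=ncfg["aggregate"])
            labels = sorted(set(m.groups.values()))
            paths_by = {}
            for lab in labels:
                paths = netpath.extract_top_paths(
                    g, lab, k=ncfg["k"], min_length=ncfg["min_length"],
                    max_length=ncfg["max_length"])
                paths_by[lab] = paths
                netpath.write_paths_tsv(paths, out / f"paths.{lab}.tsv")
            net_report = {"graph_nodes": g.number_of_nodes(),
                          "graph_edges": g.number_of_edges(),
                          "paths": {lab: len(p) for lab, p in paths_by.items()}}
            if all(len(p) >= 5 for p in paths_by.values()):
                model = netpath.train_path_classifier(paths_by, seed=seed)
                all_paths = [p for lab in labels for p in paths_by[lab]]
                all_labels = [lab for lab in labels for _ in paths_by[lab]]
                roc = netpath.classify_paths(model, all_paths, all_labels)
                (out / "roc.json").write_text(
                    json.dumps(roc, indent=2, sort_keys=True) + "\n")
                net_report["classifier_auc"] = roc["auc"]
                net_report["component_auc"] = {
                    k: v["auc"] for k, v in roc["components"].items()}
            sub = netpath.extract_subnetwork(paths_by[labels[0]],
                                             paths_by[labels[1]])
            netpath.write_sif(sub, out / "subnetwork.sif")
            net_report["subnetwork"] = sub.graph["counts"]
            comp = cfg["comparisons"][0]["name"]
            if ("proteomics", comp) in diff_results:
                gene_map = {r["id"]: r.get("genes", []) for r in net.reactions}
                annotated = netpath.project_differential(
                    sub, diff_results[("proteomics", comp)], gene_map)
                net_report["proteomics_coverage"] = annotated.graph["coverage"]
            report["network"] = net_report
        except Exception as exc:                      # noqa: BLE001
            raise StageError("network", exc) from exc

    # ---- report
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Pipeline run report", ""]
    lines.append("## Feature counts")
    lines.append("")
    lines.append("| layer | detected | filtered | comparison | sig (raw) | "
                 "sig (adj) | up | down |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for layer, lr in report["layers"].items():
        comps = lr.get("comparisons") or {"-": {}}
        for comp, cc in comps.items():
            lines.append(
                f"| {layer} | {lr['detected']} | {lr['filtered']} | {comp} | "
                f"{cc.get('significant_raw', '-')} | "
                f"{cc.get('significant_adj', '-')} | "
                f"{cc.get('up_regulated', '-')} | "
                f"{cc.get('down_regulated', '-')} |")
    if report.get("enrichment"):
        lines += ["", "## Enrichment", ""]
        for key, er in report["enrichment"].items():
            lines.append(f"- {key}: {er['significant_adj']} of {er['n_sets']} "
                         "sets significant (BH < 0.05)")
    if report.get("concordance"):
        lines += ["", "## Cross-omics concordance", ""]
        for key, cs in report["concordance"].items():
            lines.append(
                f"- {key}: overlap {cs['n_overlap']} "
                f"(same direction {cs['n_same_direction']}), "
                f"p_overlap={cs['p_overlap']:.3g}, "
                f"p_direction={cs['p_direction']:.3g}")
    if report.get("network"):
        nr = report["network"]
        lines += ["", "## Network", ""]
        lines.append(f"- reaction graph: {nr.get('graph_nodes')} nodes, "
                     f"{nr.get('graph_edges')} edges")
        if "classifier_auc" in nr:
            lines.append(f"- path classifier AUC: {nr['classifier_auc']:.3f}")
        if "subnetwork" in nr:
            lines.append(f"- subnetwork: {nr['subnetwork']}")
    return "\n".join(lines) + "\n"
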