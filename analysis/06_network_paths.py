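"""Metabolic-network path mining and path classification.

Builds the reaction graph (ubiquitous compounds removed), weights edges
per condition by adjacent pairwise gene-expression correlation, extracts
the top correlated simple paths of at least 6 edges per condition, trains
the Markov-mixture path classifier and reports its ROC/AUC, then extracts
the condition-exclusive subnetwork and projects the proteomics fold
changes onto it. Writes path tables, the ROC curve, and SIF exports.
"""

import json

import pandas as pd

from common import OUT, load_config

from mmomics import io, netpath, plots


def main() -> None:
    cfg = load_config()
    out = OUT / "network"
    out.mkdir(parents=True, exist_ok=True)
    ncfg = cfg["network"]

    net = netpath.MetabolicNetwork.from_json(cfg["layers"]["network"]["json"])
    g = netpath.build_reaction_graph(net)
    print(f"reaction graph: {g.number_of_nodes()} nodes, "
          f"{g.number_of_edges()} edges after ubiquitous-compound removal")

    block = cfg["layers"]["transcriptomics"]
    expr = io.read_gct(block["gct"])
    from mmomics.crossomics import collapse_probes
    expr = collapse_probes(expr, io.read_id_mapping(block["probe_map"]))
    g = netpath.weight_edges(g, expr, block["groups"],
                             aggregate=ncfg["aggregate"])

    top = {}
    for lab in sorted(set(block["groups"].values())):
        top[lab] = netpath.extract_top_paths(g, lab, k=ncfg["k"],
                                             min_length=ncfg["min_length"],
                                             max_length=ncfg["max_length"])
        netpath.write_paths_tsv(top[lab], out / f"paths.{lab}.tsv")
        print(f"{lab}: {len(top[lab])} top paths, best score "
              f"{top[lab][0].score:.3f}")

    labs = sorted(top)
    model = netpath.train_path_classifier(top, seed=cfg["seed"])
    paths = [p for lab in labs for p in top[lab]]
    labels = [lab for lab in labs for _ in top[lab]]
    roc = netpath.classify_paths(model, paths, labels)
    (out / "roc.json").write_text(json.dumps(roc, indent=2) + "\n")
    plots.plot_roc(roc, out / "roc.png")
    comp = {k: f"{v['condition']} (AUC {v['auc']:.3f})"
            for k, v in roc["components"].items()}
    print(f"path classifier AUC {roc['auc']:.3f}; components: {comp}")

    sub = netpath.extract_subnetwork(top[labs[0]], top[labs[1]])
    netpath.write_sif(sub, out / "subnetwork.sif")
    print(f"subnetwork: {sub.graph['counts']}")

    prot = pd.read_csv(OUT / "differential" / "proteomics.tsv", sep="\t",
                       index_col=0)
    gene_map = {r["id"]: r.get("genes", []) for r in net.reactions}
    annotated = netpath.project_differential(sub, prot, gene_map)
    netpath.write_graphml(annotated, out / "subnetwork_annotated.graphml")
    print(f"proteomics projection: {annotated.graph['coverage']:.0%} of "
          "subnetwork reactions covered by a significant protein")


if __name__ == "__main__":
    main()
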