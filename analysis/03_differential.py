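"""Moderated differential analysis (RRMM vs NDMM) for every layer.

Empirical-Bayes moderated t per feature; significance at raw and BH-
adjusted p < 0.05; up/down tallies additionally require |logFC| > 1.5.
Writes per-layer result tables and a summary JSON shaped like the study's
feature-count overview.
"""

import json

from common import OUT, load_config

from mmomics import crossomics, differential, io
from mmomics.containers import FeatureMatrix


def main() -> None:
    cfg = load_config()
    pre = OUT / "preprocessed"
    out = OUT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    design = differential.DesignSpec(contrast=("RRMM", "NDMM"))
    summary = {}

    for layer in ("targeted_lipidomics", "untargeted_lipidomics"):
        groups = cfg["layers"][layer]["groups"]
        m = io.read_feature_matrix(pre / f"{layer}.tsv", groups, scale="log2")
        res = differential.run_differential(m, design)
        differential.write_results(res, out / f"{layer}.tsv")
        summary[layer] = differential.summarize_counts(res)

    groups = cfg["layers"]["proteomics"]["groups"]
    table = io.read_protein_table(pre / "proteomics.tsv", groups, scale="log2")
    res = differential.run_differential(table.as_feature_matrix(), design)
    differential.write_results(res, out / "proteomics.tsv")
    summary["proteomics"] = differential.summarize_counts(res)

    block = cfg["layers"]["transcriptomics"]
    expr = io.read_gct(block["gct"])
    expr = crossomics.collapse_probes(expr, io.read_id_mapping(block["probe_map"]))
    m = FeatureMatrix(values=expr, groups=block["groups"], scale="log2")
    res = differential.run_differential(m, design)
    differential.write_results(res, out / "transcriptomics.tsv")
    summary["transcriptomics"] = differential.summarize_counts(res)

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    for layer, counts in summary.items():
        print(f"{layer}: {counts['tested']} tested, "
              f"{counts['significant_raw']} raw / "
              f"{counts['significant_adj']} adjusted significant, "
              f"{counts['up_regulated']} up / "
              f"{counts['down_regulated']} down (|logFC| > 1.5)")


if __name__ == "__main__":
    main()
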