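"""Proteomics vs transcriptomics concordance at gene and pathway level.

Gene level: overlap of raw-significant lists over the shared tested
universe (upper-tail hypergeometric) and direction agreement (one-sided
sign test). Pathway level: the same over preranked pathway-enrichment
results from the shared GMT. Writes the summaries and a grouped bar
chart.
"""

import json
import warnings

import pandas as pd

from common import OUT, load_config

from mmomics import crossomics, enrichment, io, plots
from mmomics.lipids import FeatureSet


def _enrich(res, sets, cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return enrichment.preranked_enrichment(
            res["logFC"].dropna().to_dict(), sets,
            n_perm=cfg["enrichment"]["n_perm"], seed=cfg["seed"])


def main() -> None:
    cfg = load_config()
    out = OUT / "crossomics"
    out.mkdir(parents=True, exist_ok=True)
    diff = OUT / "differential"
    prot = pd.read_csv(diff / "proteomics.tsv", sep="\t", index_col=0)
    trans = pd.read_csv(diff / "transcriptomics.tsv", sep="\t", index_col=0)

    universe = sorted(set(prot.index) & set(trans.index))
    genes = crossomics.concordance(prot[prot["significant_raw"]],
                                   trans[trans["significant_raw"]], universe)

    gmt = io.read_gmt(cfg["layers"]["gene_sets"]["gmt"])
    sets = [FeatureSet(sid, "pathway", members) for sid, members in gmt.items()]
    ep, et = _enrich(prot, sets, cfg), _enrich(trans, sets, cfg)
    uni_sets = sorted(set(ep.index) & set(et.index))
    pathways = crossomics.concordance(
        ep[ep["p_value"] < 0.05].assign(logFC=lambda d: d["ES"]),
        et[et["p_value"] < 0.05].assign(logFC=lambda d: d["ES"]), uni_sets)

    summaries = {"genes": genes.as_dict(), "pathways": pathways.as_dict()}
    (out / "concordance.json").write_text(json.dumps(summaries, indent=2) + "\n")
    plots.plot_concordance_bars(
        {"genes": genes.as_dict(), "pathways": pathways.as_dict()},
        out / "concordance_bars.png")
    for level, s in summaries.items():
        print(f"{level}: {s['n_sig_A']} significant in proteomics, "
              f"{s['n_overlap']} also in transcriptomics "
              f"({s['n_same_direction']} same direction); "
              f"overlap p={s['p_overlap']:.3g}, "
              f"direction p={s['p_direction']:.3g}")


if __name__ == "__main__":
    main()
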