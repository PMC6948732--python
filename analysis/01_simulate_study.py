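"""Generate the synthetic multi-omics study bundle.

Writes, under results/data/: a targeted lipidomics panel (4 relapsed vs 5
newly diagnosed patients, PCs planted 2-fold down on the log2 scale in the
relapsed group), an untargeted feature matrix (1500 features with
intensity-censored and random missingness), a protein-group table in the
transcriptome's gene space (15 genes planted up in both layers), a
probe-level expression GCT over a toy lipid-metabolism network (30 vs 30
samples, two active reaction chains per condition, planted correlation
0.9), the probe map, a pathway GMT and the network JSON — plus the
pipeline configuration pointing at them.
"""

import json

from common import CONFIG_PATH, DATA, SEED

from mmomics.synthetic import write_synthetic_study


def main() -> None:
    bundle = write_synthetic_study(DATA, seed=SEED)
    CONFIG_PATH.write_text(json.dumps(bundle["config"], indent=2) + "\n")
    truth = bundle["truth"]
    print(f"wrote study bundle to {DATA}")
    print(f"  targeted lipids: {len(truth['targeted']['features'])} "
          f"(PC planted at logFC -2 in RRMM)")
    print(f"  untargeted features: {len(truth['untargeted']['features'])}")
    print(f"  proteins: {len(truth['proteomics']['features'])} "
          f"({len(truth['shared_up_genes'])} planted up, shared with "
          "transcriptome)")
    print(f"  planted network chains: {list(truth['planted_paths'])} "
          f"(active: {truth['active_paths']})")


if __name__ == "__main__":
    main()
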