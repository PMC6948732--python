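"""Preprocess every omics layer.

Targeted lipidomics: probabilistic quotient normalization then log2.
Untargeted lipidomics: presence filter (>= 75% in one group), minimum
imputation, quantile normalization, log2. Proteomics: identification
filters (>= 2 unique peptides, score > 5), presence filter, quantile
normalization, log2, then two-branch imputation (localized least squares
for proteins missing in < 25% of samples, censored-normal draws
otherwise). Writes processed matrices under results/preprocessed/.
"""

from common import OUT, load_config

from mmomics import io, preprocess


def main() -> None:
    cfg = load_config()
    out = OUT / "preprocessed"
    pcfg = preprocess.PreprocessConfig(seed=cfg["seed"])
    layers = cfg["layers"]

    m = io.read_feature_matrix(layers["targeted_lipidomics"]["path"],
                               layers["targeted_lipidomics"]["groups"])
    t = preprocess.preprocess_targeted_lipidomics(m, pcfg)
    io.write_feature_matrix(t, out / "targeted_lipidomics.tsv")
    print(f"targeted lipidomics: {len(m.feature_ids)} detected -> "
          f"{len(t.feature_ids)} after PQN + log2")

    m = io.read_feature_matrix(layers["untargeted_lipidomics"]["path"],
                               layers["untargeted_lipidomics"]["groups"])
    u = preprocess.preprocess_untargeted_lipidomics(m, pcfg)
    io.write_feature_matrix(u, out / "untargeted_lipidomics.tsv")
    print(f"untargeted lipidomics: {len(m.feature_ids)} detected -> "
          f"{len(u.feature_ids)} after presence filter")

    table = io.read_protein_table(layers["proteomics"]["path"],
                                  layers["proteomics"]["groups"])
    p = preprocess.preprocess_proteomics(table, pcfg)
    io.write_protein_table(p, out / "proteomics.tsv")
    part = p.meta["imputation_partition"]
    print(f"proteomics: {len(table.protein_ids)} detected -> "
          f"{len(p.protein_ids)} after filters "
          f"(imputed: {len(part['mar'])} MAR by LLS, "
          f"{len(part['mnar'])} MNAR by censored normal)")


if __name__ == "__main__":
    main()
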