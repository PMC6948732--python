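"""Synthetic cohorts with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration and seed and
returns, next to the data, a *truth table* recording what was planted
(effects, dilution factors, missingness partitions, active paths), so
that downstream stages can be tested by parameter recovery:

* two-group lipidomics cohorts with class-level log2 fold changes,
  per-sample multiplicative dilution, intensity-censored (MNAR) plus
  uniform random (MAR) missingness;
* proteomics cohorts that additionally carry unique-peptide counts and
  identification scores straddling the filter thresholds;
* toy metabolic networks guaranteeing long reaction chains;
* expression matrices with group-specific correlation planted along
  designated network paths.

The intensity model is log-normal: log2 intensity = feature baseline +
planted group effect + N(0, feature_sd), multiplied on the raw scale by a
log-normal per-sample dilution factor. MNAR is left-censoring at a global
raw-intensity quantile, applied after dilution; MAR removes a uniform
fraction of the remaining observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, ProteinTable
from .lipids import parse_lipid_name
from .netpath import MetabolicNetwork, build_reaction_graph

__all__ = [
    "CohortDesign", "PlantedEffect", "NoiseModel",
    "generate_lipidomics_cohort", "generate_proteomics_cohort",
    "generate_toy_network", "generate_expression_for_paths",
    "default_lipid_catalog", "expanded_lipid_catalog",
    "write_synthetic_study",
]


# ------------------------------------------------------------------ designs
@dataclass
class CohortDesign:
    """Two-group sample layout."""

    sample_ids: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        labels = sorted(set(self.group_of.values()))
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {labels}")
        for g in labels:
            n = sum(1 for s in self.sample_ids if self.group_of[s] == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} samples; need >= 2")

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "CohortDesign":
        """e.g. ``CohortDesign.from_counts({"RRMM": 2, "NDMM": 7})``."""
        ids, group_of = [], {}
        for g, n in counts.items():
            for i in range(n):
                s = f"{g}_{i + 1:02d}"
                ids.append(s)
                group_of[s] = g
        return cls(sample_ids=ids, group_of=group_of)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass
class PlantedEffect:
    """A log2 fold change applied to selected features in one group.

    ``target_selector`` is a lipid-class name, an explicit collection of
    feature ids, or a path id (for expression generators).
    """

    target_selector: str | list[str] | set[str]
    log2_fold_change: float
    affected_group: str


@dataclass
class NoiseModel:
    """Intensity / missingness model shared by the matrix generators.

    ``base_log2_mean`` — grand mean of log2 intensities (default 20, the
    scale of LC-MS peak areas); ``feature_mean_sd`` — spread of per-feature
    baselines around it; ``feature_sd`` — within-feature residual SD on
    the log2 scale; ``sample_dilution_sd`` — SD of the log2 per-sample
    dilution offset; ``mnar_threshold_quantile`` — raw intensities strictly
    below this global quantile are censored; ``mar_rate`` — uniform
    missingness among the surviving cells.
    """

    base_log2_mean: float = 20.0
    feature_sd: float = 1.0
    sample_dilution_sd: float = 0.25
    mnar_threshold_quantile: float = 0.05
    mar_rate: float = 0.02
    seed: int = 0
    feature_mean_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mnar_threshold_quantile", "mar_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("feature_sd", "sample_dilution_sd", "feature_mean_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# The targeted panel's lipid classes, with a plausible species spread each.
_CATALOG_SPEC = {
    "PC": [(30, 0), (30, 1), (32, 1), (32, 2), (34, 1), (34, 2), (34, 4),
           (36, 2), (36, 4), (38, 0), (38, 1), (38, 4), (40, 0), (40, 1),
           (40, 2), (40, 4), (40, 6)],
    "PE": [(34, 1), (34, 2), (36, 2), (36, 4), (38, 4), (38, 6), (40, 6)],
    "PI": [(34, 1), (36, 2), (38, 4), (40, 6)],
    "PG": [(34, 1), (36, 2)],
    "SM": [(34, 1), (36, 1), (38, 1), (40, 1), (42, 2)],
    "Cer": [(34, 1), (34, 2), (36, 1), (40, 1), (42, 1), (42, 2)],
    "HexCer": [(34, 1), (40, 1), (42, 2)],
    "LPC": [(16, 0), (18, 0), (18, 1), (20, 4)],
    "LPE": [(16, 0), (18, 0), (18, 1)],
    "PC-O": [(34, 1), (36, 4), (38, 6), (40, 7)],
    "PC-P": [(34, 0), (36, 3), (38, 5)],
    "PE-O": [(36, 4), (38, 5)],
    "PE-P": [(38, 4), (40, 6)],
}


def expanded_lipid_catalog(n: int) -> list[str]:
    """A large untargeted-scale catalog of sum-composition names.

    Cycles deterministically through the panel's classes and a realistic
    carbon/double-bond grid until ``n`` distinct names are produced.
    """
    classes = [c for c in _CATALOG_SPEC if "-" not in c]
    names: list[str] = []
    seen = set()
    for carbons in range(20, 57):
        for db in range(0, 8):
            for cls in classes:
                name = f"{cls} {carbons}:{db}"
                if name not in seen:
                    seen.add(name)
                    names.append(name)
                if len(names) == n:
                    return names
    raise ValueError(f"cannot produce {n} distinct names from the grid")


def default_lipid_catalog() -> list[str]:
    """A targeted-panel-like lipid catalog (~60 species, 13 classes)."""
    names = []
    for cls, specs in _CATALOG_SPEC.items():
        for c, db in specs:
            if cls.endswith("-O") or cls.endswith("-P"):
                base, link = cls.split("-")
                names.append(f"{base}({link}-{c}:{db})")
            else:
                names.append(f"{cls} {c}:{db}")
    return names


# ------------------------------------------------------------------ helpers
def _resolve_selector(selector, feature_ids: list[str],
                      classes: dict[str, str] | None) -> list[str]:
    if isinstance(selector, str):
        if classes is None:
            raise ValueError(f"selector {selector!r} needs a lipid catalog")
        hits = [f for f in feature_ids if classes.get(f) == selector]
    else:
        sel = set(selector)
        hits = [f for f in feature_ids if f in sel]
    if not hits:
        raise ValueError(f"planted-effect selector {selector!r} matched no feature")
    return hits


def _apply_missingness(raw: np.ndarray, noise: NoiseModel,
                       rng: np.random.Generator):
    """Left-censor below the global raw quantile (MNAR), then remove a
    uniform fraction of surviving cells (MAR). Masks partition exactly."""
    mnar = np.zeros(raw.shape, bool)
    if noise.mnar_threshold_quantile > 0:
        threshold = np.quantile(raw, noise.mnar_threshold_quantile)
        mnar = raw < threshold
    mar = np.zeros(raw.shape, bool)
    if noise.mar_rate > 0:
        mar = (rng.random(raw.shape) < noise.mar_rate) & ~mnar
    out = raw.copy()
    out[mnar | mar] = np.nan
    return out, mnar, mar


def _intensity_matrix(design: CohortDesign, feature_ids: list[str],
                      effects: list[PlantedEffect], noise: NoiseModel,
                      rng: np.random.Generator,
                      classes: dict[str, str] | None):
    n_feat, n_samp = len(feature_ids), len(design.sample_ids)
    baseline = noise.base_log2_mean + rng.normal(0, noise.feature_mean_sd, n_feat)
    log2_mean = np.tile(baseline[:, None], (1, n_samp))

    planted = pd.Series(0.0, index=feature_ids, name="planted_log2fc")
    group_cols = {g: [design.sample_ids.index(s) for s in design.samples_in(g)]
                  for g in design.groups}
    for eff in effects:
        hits = _resolve_selector(eff.target_selector, feature_ids, classes)
        if eff.affected_group not in group_cols:
            raise ValueError(f"unknown affected_group {eff.affected_group!r}")
        cols = group_cols[eff.affected_group]
        for f in hits:
            i = feature_ids.index(f)
            log2_mean[i, cols] += eff.log2_fold_change
            planted[f] += eff.log2_fold_change

    log2_vals = log2_mean + rng.normal(0, noise.feature_sd, (n_feat, n_samp))
    dilution_log2 = rng.normal(0, noise.sample_dilution_sd, n_samp)
    raw = 2.0 ** (log2_vals + dilution_log2[None, :])
    dilution = pd.Series(2.0 ** dilution_log2, index=design.sample_ids,
                         name="dilution_factor")
    return raw, dilution, planted, baseline


# --------------------------------------------------------------- lipidomics
def generate_lipidomics_cohort(design: CohortDesign, effects: list[PlantedEffect],
                               noise: NoiseModel,
                               lipid_catalog: list[str] | None = None
                               ) -> tuple[FeatureMatrix, dict]:
    """Raw-scale lipid feature matrix plus its generating truth table.

    The truth table records per-feature lipid class and planted log2
    effect, the per-sample dilution factors, and the exact MNAR/MAR
    missingness partition.
    """
    catalog = lipid_catalog if lipid_catalog is not None else default_lipid_catalog()
    species = [parse_lipid_name(n) for n in catalog]
    classes = {sp.raw_name: sp.lipid_class for sp in species}
    feature_ids = [sp.raw_name for sp in species]

    rng = np.random.default_rng(noise.seed)
    raw, dilution, planted, baseline = _intensity_matrix(
        design, feature_ids, effects, noise, rng, classes)
    observed, mnar, mar = _apply_missingness(raw, noise, rng)

    values = pd.DataFrame(observed, index=feature_ids, columns=design.sample_ids)
    matrix = FeatureMatrix(values=values, groups=dict(design.group_of), scale="raw")
    truth = {
        "features": pd.DataFrame({
            "lipid_class": [classes[f] for f in feature_ids],
            "planted_log2fc": planted.to_numpy(),
            "baseline_log2_mean": baseline,
        }, index=pd.Index(feature_ids, name="feature_id")),
        "dilution_factors": dilution,
        "mnar_mask": pd.DataFrame(mnar, index=feature_ids, columns=design.sample_ids),
        "mar_mask": pd.DataFrame(mar, index=feature_ids, columns=design.sample_ids),
    }
    return matrix, truth


# --------------------------------------------------------------- proteomics
def generate_proteomics_cohort(design: CohortDesign, effects: list[PlantedEffect],
                               noise: NoiseModel, n_proteins: int = 200,
                               protein_ids: list[str] | None = None
                               ) -> tuple[ProteinTable, dict]:
    """Protein-group table with peptide counts and scores straddling the
    identification filters, plus MAR/MNAR truth partitions.

    About 10% of proteins carry < 2 unique peptides and about 10% a score
    <= 5, so the identification filters have something to remove. Pass
    ``protein_ids`` (e.g. gene ids from a toy network) to place the
    proteins in a shared id space for cross-omics analyses.
    """
    if protein_ids is not None:
        n_proteins = len(protein_ids)
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if protein_ids is None:
        protein_ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    rng = np.random.default_rng(noise.seed)

    raw, dilution, planted, baseline = _intensity_matrix(
        design, protein_ids, effects, noise, rng, classes=None)
    observed, mnar, mar = _apply_missingness(raw, noise, rng)

    unique_peptides = rng.poisson(6, n_proteins) + 2
    low_pep = rng.random(n_proteins) < 0.10
    unique_peptides[low_pep] = rng.integers(0, 2, low_pep.sum())
    score = rng.gamma(2.0, 20.0, n_proteins) + 5.0
    low_score = rng.random(n_proteins) < 0.10
    score[low_score] = rng.uniform(0.0, 5.0, low_score.sum())

    proteins = pd.DataFrame({"unique_peptides": unique_peptides, "score": score},
                            index=pd.Index(protein_ids, name="protein_id"))
    intensities = pd.DataFrame(observed, index=proteins.index,
                               columns=design.sample_ids)
    table = ProteinTable(proteins=proteins, intensities=intensities,
                         groups=dict(design.group_of))
    truth = {
        "features": pd.DataFrame({
            "planted_log2fc": planted.to_numpy(),
            "baseline_log2_mean": baseline,
            "passes_id_filter": (unique_peptides >= 2) & (score > 5),
        }, index=proteins.index),
        "dilution_factors": dilution,
        "mnar_mask": pd.DataFrame(mnar, index=proteins.index,
                                  columns=design.sample_ids),
        "mar_mask": pd.DataFrame(mar, index=proteins.index,
                                 columns=design.sample_ids),
    }
    return table, truth


# ------------------------------------------------------------------ network
def generate_toy_network(n_reactions: int = 40, n_metabolites: int = 80,
                         n_genes: int = 50, ubiquitous_fraction: float = 0.2,
                         seed: int = 0, n_chains: int = 2,
                         chain_length: int = 9
                         ) -> tuple[MetabolicNetwork, dict[str, list[str]]]:
    """A bipartite toy metabolic network with guaranteed long chains.

    ``n_chains`` disjoint linear chains of ``chain_length`` reactions each
    are wired through dedicated connector metabolites, with a dedicated
    boundary substrate/product at each end (so every chain head is
    source-like and every tail sink-like) and bypass connectors skipping
    every other interior reaction (so each chain supports several distinct
    simple routes of >= 6 edges). The remaining reactions are wired
    randomly through a side-metabolite pool, a ``ubiquitous_fraction`` of
    which is flagged ubiquitous. Each reaction carries one dedicated gene
    (cycling through the pool if n_genes < n_reactions).

    Returns the network and the planted chain paths
    ``{path_id: [reaction ids]}``.
    """
    if min(n_reactions, n_metabolites, n_genes) <= 0:
        raise ValueError("counts must be positive")
    if not 0 <= ubiquitous_fraction <= 1:
        raise ValueError("ubiquitous_fraction must be in [0, 1]")
    need = n_chains * chain_length
    if n_reactions < need or chain_length < 7:
        raise ValueError(
            f"parameters admit no reaction path of >= 6 edges; need "
            f"n_reactions >= {max(need, 7)} and chain_length >= 7 "
            f"(got n_reactions={n_reactions}, chain_length={chain_length})")
    n_bypass = max(0, (chain_length - 3) // 2)
    n_structural = n_chains * (chain_length - 1 + n_bypass + 2)
    if n_metabolites < n_structural + 4:
        raise ValueError(f"n_metabolites must be >= {n_structural + 4} for "
                         f"these chain parameters")

    rng = np.random.default_rng(seed)
    reaction_ids = [f"R{i + 1:03d}" for i in range(n_reactions)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_of = {r: [genes[i % n_genes]] for i, r in enumerate(reaction_ids)}

    metabolites = []
    reactions = {r: {"id": r, "substrates": [], "products": [],
                     "genes": gene_of[r]} for r in reaction_ids}
    mid = 0

    def new_metabolite(ubiquitous: bool = False) -> str:
        nonlocal mid
        mid += 1
        m = f"M{mid:03d}"
        metabolites.append({"id": m, "ubiquitous": ubiquitous})
        return m

    # chain backbones through dedicated (never ubiquitous) connectors
    planted_paths: dict[str, list[str]] = {}
    used = 0
    for c in range(n_chains):
        chain = reaction_ids[used:used + chain_length]
        used += chain_length
        planted_paths[f"path_{c + 1}"] = chain
        reactions[chain[0]]["substrates"].append(new_metabolite())
        reactions[chain[-1]]["products"].append(new_metabolite())
        for a, b in zip(chain[:-1], chain[1:]):
            m = new_metabolite()
            reactions[a]["products"].append(m)
            reactions[b]["substrates"].append(m)
        # bypass connectors R_i -> R_{i+2}: alternative simple routes
        for i in range(1, chain_length - 2, 2):
            m = new_metabolite()
            reactions[chain[i]]["products"].append(m)
            reactions[chain[i + 2]]["substrates"].append(m)

    # side metabolite pool, a fraction flagged ubiquitous
    n_side = n_metabolites - mid
    n_ubiq = int(round(ubiquitous_fraction * n_side))
    side = [new_metabolite(ubiquitous=i < n_ubiq) for i in range(n_side)]

    # random wiring among the non-chain reactions only, so chain
    # boundaries stay source-/sink-like
    noise_reactions = reaction_ids[used:]
    for r in noise_reactions:
        extra_s = rng.choice(side, size=rng.integers(1, 3), replace=False)
        extra_p = rng.choice(side, size=rng.integers(1, 3), replace=False)
        reactions[r]["substrates"].extend(m for m in extra_s
                                          if m not in reactions[r]["products"])
        reactions[r]["products"].extend(m for m in extra_p
                                        if m not in reactions[r]["substrates"])

    net = MetabolicNetwork(reactions=[reactions[r] for r in reaction_ids],
                           metabolites=metabolites)
    # sanity: the built reaction graph must contain a >= 6-edge simple path
    graph = build_reaction_graph(net)
    first = planted_paths["path_1"]
    if not all(graph.has_edge(a, b) for a, b in zip(first[:-1], first[1:])):
        raise RuntimeError("internal error: planted chain not present in graph")
    return net, planted_paths


def generate_expression_for_paths(network: MetabolicNetwork,
                                  paths: dict[str, list[str]],
                                  design: CohortDesign,
                                  active_paths: dict[str, list[str]],
                                  correlation: float = 0.9, seed: int = 0,
                                  n_background_genes: int = 0
                                  ) -> tuple[pd.DataFrame, dict]:
    """Expression matrix with path-wise correlation planted per group.

    Genes annotated along a group's active paths are drawn equicorrelated
    at ``correlation`` within that group's samples (via a shared latent
    factor: x = sqrt(rho) z_path + sqrt(1-rho) eps) and independently in
    the other group; all other genes are independent noise. Rows are
    median-centered, matching the log2 median-centered convention of
    public expression matrices.
    """
    if not 0 <= correlation < 1:
        raise ValueError("correlation must be in [0, 1) (the implied "
                         "equicorrelation matrix is not PSD otherwise)")
    for g, pids in active_paths.items():
        if g not in design.groups:
            raise ValueError(f"unknown group {g!r} in active_paths")
        for pid in pids:
            if pid not in paths:
                raise ValueError(f"unknown path id {pid!r}")

    gene_of = {r["id"]: list(r.get("genes", [])) for r in network.reactions}
    all_genes = sorted({g for gs in gene_of.values() for g in gs})
    all_genes += [f"BG{i + 1:04d}" for i in range(n_background_genes)]

    rng = np.random.default_rng(seed)
    n_samp = len(design.sample_ids)
    expr = rng.normal(0.0, 1.0, (len(all_genes), n_samp))
    row_of = {g: i for i, g in enumerate(all_genes)}
    col_of = {s: j for j, s in enumerate(design.sample_ids)}

    truth_genes: dict[str, dict[str, list[str]]] = {}
    for group, pids in active_paths.items():
        cols = [col_of[s] for s in design.samples_in(group)]
        truth_genes[group] = {}
        for pid in pids:
            path_genes = []
            for r in paths[pid]:
                path_genes.extend(gene_of.get(r, []))
            path_genes = list(dict.fromkeys(path_genes))
            truth_genes[group][pid] = path_genes
            z = rng.normal(0.0, 1.0, len(cols))
            for gname in path_genes:
                eps = rng.normal(0.0, 1.0, len(cols))
                expr[row_of[gname], cols] = (np.sqrt(correlation) * z
                                             + np.sqrt(1 - correlation) * eps)
    expr -= np.median(expr, axis=1, keepdims=True)
    df = pd.DataFrame(expr, index=all_genes, columns=design.sample_ids)
    truth = {"active_path_genes": truth_genes, "reaction_genes": gene_of}
    return df, truth


# -------------------------------------------------------------- study bundle
def write_synthetic_study(outdir, seed: int = 0) -> dict:
    """Write a complete synthetic study to ``outdir`` and return a pipeline
    configuration dict pointing at it.

    The bundle mirrors the real study's shape at desk scale: a targeted
    lipidomics panel (7 patients, relapsed vs newly diagnosed, PCs planted
    down 2-fold on the log2 scale), an untargeted feature matrix (~1500
    features), a protein-group table sharing the transcriptomics gene
    space (some shared genes planted up in the relapsed group in both
    layers), a probe-level expression matrix over a toy lipid-metabolism
    network (n = 30 per group, two active chains per condition at
    correlation 0.9) with a probe-to-gene map, a pathway GMT over the gene
    space, and the network JSON.
    """
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # -- clinical-scale lipidomics cohorts (2 RRMM vs 7... kept 4 vs 5 for
    #    estimable within-group variance at desk scale)
    lip_design = CohortDesign.from_counts({"RRMM": 4, "NDMM": 5})
    lip_noise = NoiseModel(seed=seed)
    targeted, targeted_truth = generate_lipidomics_cohort(
        lip_design, [PlantedEffect("PC", -2.0, "RRMM")], lip_noise)
    _io.write_feature_matrix(targeted, outdir / "targeted_lipidomics.tsv")

    unt_noise = NoiseModel(seed=seed + 1, mnar_threshold_quantile=0.1,
                           mar_rate=0.05)
    untargeted, untargeted_truth = generate_lipidomics_cohort(
        lip_design, [PlantedEffect("PC", -2.0, "RRMM")], unt_noise,
        lipid_catalog=expanded_lipid_catalog(1500))
    _io.write_feature_matrix(untargeted, outdir / "untargeted_lipidomics.tsv")

    # -- toy metabolic network + transcriptomics with active paths
    net, paths = generate_toy_network(n_reactions=50, n_metabolites=90,
                                      n_genes=60, ubiquitous_fraction=0.2,
                                      seed=seed + 2, n_chains=4,
                                      chain_length=9)
    net.to_json(outdir / "network.json")
    expr_design = CohortDesign.from_counts({"RRMM": 30, "NDMM": 30})
    active = {"RRMM": ["path_1", "path_2"], "NDMM": ["path_3", "path_4"]}
    expr, expr_truth = generate_expression_for_paths(
        net, paths, expr_design, active, correlation=0.9, seed=seed + 3,
        n_background_genes=60)
    genes = list(expr.index)

    # genes differential in BOTH transcriptome and proteome (drawn from the
    # background pool so the planted path correlations stay untouched)
    background = [g for g in genes if g.startswith("BG")]
    shared_up = sorted(rng.choice(background, 15, replace=False))
    expr.loc[shared_up, expr_design.samples_in("RRMM")] += 2.5

    # probe-level matrix: every gene one probe, first 10 genes a second,
    # dimmer probe (exercises max-mean collapapse)
    probe_rows, mapping = [], {}
    for gname in genes:
        probe_rows.append((f"pr_{gname}_1", expr.loc[gname]))
        mapping[f"pr_{gname}_1"] = gname
    for gname in genes[:10]:
        probe_rows.append((f"pr_{gname}_2", expr.loc[gname] - 1.0))
        mapping[f"pr_{gname}_2"] = gname
    probe_df = pd.DataFrame({pid: row for pid, row in probe_rows}).T
    probe_df.columns = expr.columns
    _io.write_gct(probe_df, outdir / "transcriptomics.gct")
    with open(outdir / "probe_map.tsv", "w") as fh:
        fh.write("probe\ttarget\n")
        for pid, gname in mapping.items():
            fh.write(f"{pid}\t{gname}\n")

    # -- proteomics in the shared gene space: effects shared with the
    #    transcriptome (concordance signal) plus up-regulated enzymes of an
    #    RRMM-active chain (signal for the subnetwork projection)
    gene_of = expr_truth["reaction_genes"]
    chain_genes = sorted({g for r in paths["path_1"] for g in gene_of[r]})
    prot_noise = NoiseModel(seed=seed + 4)
    proteins, protein_truth = generate_proteomics_cohort(
        lip_design, [PlantedEffect(shared_up, 2.5, "RRMM"),
                     PlantedEffect(chain_genes, 2.0, "RRMM")], prot_noise,
        protein_ids=genes)
    _io.write_protein_table(proteins, outdir / "proteomics.tsv")

    # -- pathway gene sets: one set per planted chain plus random sets
    sets = {}
    for pid, chain in paths.items():
        sets[f"PATHWAY_{pid}"] = sorted({g for r in chain for g in gene_of[r]})
    for i in range(12):
        sets[f"PATHWAY_random_{i}"] = sorted(
            rng.choice(genes, 8, replace=False))
    sets["PATHWAY_shared_up"] = sorted(shared_up)
    _io.write_gmt(sets, outdir / "pathways.gmt")

    config = {
        "seed": seed,
        "output_dir": str(outdir / "pipeline"),
        "comparisons": [{"name": "RRMM.NDMM", "numerator": "RRMM",
                         "denominator": "NDMM"}],
        "enrichment": {"n_perm": 2000},
        "network": {"k": 10, "max_length": 10},
        "layers": {
            "targeted_lipidomics": {
                "path": str(outdir / "targeted_lipidomics.tsv"),
                "groups": dict(lip_design.group_of)},
            "untargeted_lipidomics": {
                "path": str(outdir / "untargeted_lipidomics.tsv"),
                "groups": dict(lip_design.group_of)},
            "proteomics": {"path": str(outdir / "proteomics.tsv"),
                           "groups": dict(lip_design.group_of)},
            "transcriptomics": {"gct": str(outdir / "transcriptomics.gct"),
                                "groups": dict(expr_design.group_of),
                                "probe_map": str(outdir / "probe_map.tsv")},
            "network": {"json": str(outdir / "network.json")},
            "gene_sets": {"gmt": str(outdir / "pathways.gmt")},
        },
    }
    truth = {"targeted": targeted_truth, "untargeted": untargeted_truth,
             "proteomics": protein_truth, "expression": expr_truth,
             "planted_paths": paths, "active_paths": active,
             "shared_up_genes": shared_up}
    return {"config": config, "truth": truth}
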