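# Methods

`mmomics` re-implements, as a tested pipeline over synthetic data, a
concurrent lipidomics–proteomics–transcriptomics analysis of multiple
myeloma (MM) plasma cells: two-group comparisons (relapsed/refractory
RRMM vs newly diagnosed NDMM; high vs low R-ISS risk), lipid-set and
pathway enrichment, cross-omics concordance, and correlation-weighted
metabolic-network path mining. This note records the models, the
parameters that matter, and the choices made where the procedure left
room.

## Preprocessing

**Presence filtering.** A feature is kept iff its non-missing fraction is
≥ `presence_threshold` (default 0.75, inclusive) within *at least one*
comparison group. The filter is idempotent and order-preserving.

**Quantile normalization** equalizes each sample's intensity
distribution to the mean quantile profile. With missing values, ranks
are computed per column over the observed values only and mapped onto
the mean of the per-column empirical quantile functions evaluated on a
common grid; for complete columns this reduces exactly to classical
quantile normalization (sorted columns identical to ≤1e-12). Ties take
average ranks.

**Probabilistic quotient normalization (PQN)** divides each sample by
the median of its feature-wise quotients to a reference spectrum —
the feature-wise *median* across samples by default (`mean` available).
It runs on the raw intensity scale, before log transformation, and
removes per-sample dilution / injection-volume variation. Its precision
is limited by residual feature noise: the quotient median estimates the
dilution factor with a log-scale standard error of roughly
1.25·`feature_sd`/√(n features), so percent-level recovery needs an
untargeted-scale matrix (the tests use 2 000 features at feature SD
0.25 log2 units, where planted factors are recovered within 2%).

**log2 transformation** requires strictly positive values; zeros raise
an error rather than being patched with a pseudo-count.

**Minimum-value imputation** (untargeted chain) replaces every missing
cell by the matrix-wide minimum observed value. The untargeted chain
order is filter → minimum imputation → quantile → log2; imputing after
normalization is available via `impute_first=False`. The targeted chain
is PQN → log2, leaving missing values missing for the downstream
moderated fit.

**Proteomics.** Protein groups are kept when unique peptides ≥ 2
(inclusive) and identification score > 5 (strict), then presence-
filtered, quantile-normalized and log2-transformed. Imputation is
two-branch, by each protein's overall missing fraction:

* **< 25% missing (MAR):** localized least-squares (LLS) regression —
  the `lls_neighbors` (default 10) complete proteins most correlated
  (Pearson, on the target's observed samples) with the target are used
  as regressors in an ordinary least-squares fit with intercept, and
  the fitted model predicts the missing entries. If fewer complete
  proteins than neighbors exist, the imputation falls back to the row
  mean with a warning.
* **≥ 25% missing (MNAR):** draws from
  Normal(matrix minimum, (`mnar_sd_factor`·global SD)²) with
  `mnar_sd_factor` = 0.3 by default, seeded. The boundary case of
  exactly 25% goes to the censored branch — the conservative,
  low-information choice.

Observed cells are never altered, and the MAR/MNAR partition is
recorded in the output metadata.

## Moderated differential analysis

Per feature, a two-group fit gives logFC = mean(numerator) −
mean(denominator) on the log2 scale, pooled residual variance s² and
residual df d = n₁+n₂−2 (features with fewer than two observations in a
group are flagged with missing statistics rather than dropped).
Variances are shrunk under the standard empirical-Bayes hierarchy
(scaled-χ² likelihood, scaled inverse-χ² prior); the prior df d₀ and
prior variance s₀² are fitted by method of moments on log s², using the
digamma/trigamma identities of log-χ² variates and a Newton inversion of
the trigamma function. The moderated statistic

    t = logFC / (s̃ √(1/n₁ + 1/n₂)),   s̃² = (d₀s₀² + d s²)/(d₀ + d)

is referred to t with d₀+d df; p-values are two-sided and BH-adjusted
across features. Setting `prior_df=0` reproduces the ordinary pooled t
exactly (tested to 1e-8); if the spread of log-variances is no larger
than sampling noise, d₀ = ∞ and every variance shrinks to s₀².

Significance is two-tier, matching the study's reporting: a raw flag
(p < 0.05), an adjusted flag (BH p < 0.05), and up/down tallies that
additionally require |logFC| strictly > 1.5. The tallies use the raw
rule by default because the reported up/down counts are nonzero even
where adjusted-significant counts are zero.

## Lipid nomenclature and set enrichment

The parser accepts sum-composition shorthand (`PC 34:4`), per-chain
names with sphingoid markers (`Cer[NS](d18:1/16:0)`), semicolon-joined
annotation variants with adduct suffixes (`; [M+H]+`) stripped,
`Plasmenyl-`/`Plasmanyl-` prefixes (mapped to the `-P`/`-O` class
suffixes) and unresolved ether alternatives
(`PC(O-38:6) / PC(P-38:5)`; the O- form, listed first, is primary and
the rest go to `ambiguous_alternatives`). Anything else raises an error
naming the offending token — never a silent guess. Every species feeds
three sets: its class, its total carbon count and its total double-bond
count; ambiguous species contribute through the primary identity only.

**Preranked enrichment** ranks features by logFC (descending; ties
broken by feature id for determinism) and computes the weighted
Kolmogorov–Smirnov running-sum enrichment score (hit increment
|logFC|^w normalized over hits, w = 1 by default; miss decrement
1/(N−N_hits); ES = extremum of the running sum, the positive extremum
winning an exact magnitude tie). The null redraws member labels
uniformly from the ranked universe — preranked mode, since only a
ranking is available. When C(N, k) ≤ `n_perm` the null is enumerated
exhaustively and the p-value is exact (matching a brute-force oracle to
1e-12); otherwise it is Monte-Carlo with the +1 correction. p-values
are sign-matched tail probabilities; NES divides ES by the mean
magnitude of same-sign null scores; BH adjustment runs across sets.
Defaults: `n_perm` 10 000, `min_size` 3.

## Cross-omics concordance

Probe-level expression is collapsed to UniProt/gene ids by keeping the
probe with the highest mean expression (a `mean` rule is available).
Concordance of two significant lists over the shared tested universe
uses the upper-tail hypergeometric probability of at least the observed
overlap, and a one-sided binomial sign test at ½ on the number of
direction-concordant overlapping ids. Both match exhaustive enumeration
on small universes to 1e-9.

## Network path mining

**Reaction graph.** From reactions/metabolites JSON, ubiquitous
compounds (flagged in the network, plus any caller-supplied list) are
excluded from edge formation; an edge r₁→r₂ exists iff a non-ubiquitous
product of r₁ is a substrate of r₂ (no self-edges). Reversible
reactions must be explicit directed duplicates.

**Edge weighting.** Per group and edge, the weight is the maximum
Pearson correlation over all gene pairs (genes of r₁) × (genes of r₂)
on that group's samples (`mean` aggregation available); edges touching
a reaction with no measured gene receive the group's median weight and
an `unmeasured` flag, preserving connectivity. Groups need ≥ 3 samples.

**Path extraction.** Candidate paths run from source-like (in-degree 0)
to sink-like (out-degree 0) reactions; when a side has no degree-0 node
(cyclic region) every node is a candidate on that side. Paths are
simple, must have ≥ `min_length` edges (default 6 — i.e. at least seven
reactions; the alternative node-count reading is configurable), and are
scored by mean edge weight. The search enumerates exhaustively up to
`max_length` edges (default 12) rather than using a k-best shortest-path
heuristic: mean-weight ranking is not additive, exhaustive enumeration
is exact (it matches the brute-force oracle by construction), and the
sparse networks this pipeline targets keep it cheap. Order is
deterministic: score descending, then lexicographic node sequence.

**Path classifier.** A two-component mixture of first-order Markov
chains over reaction sequences, with one catch-all state for reactions
unseen in training. Because training paths carry condition labels, the
mixture is conditional: the component indicator of a path is its label
observed through a flip-noise channel, fixing the mixing weights at
pi(label) = (1−ε, ε) with ε = 0.05. This anchors each component to one
condition — an unanchored mixture provably drifts, under Laplace
smoothing, to a degenerate one-sharp-component solution on
label-uninformative data, which would make held-out posteriors extreme
even when the conditions are indistinguishable. EM fits the component
chains (Laplace α = 1 on initial and transition counts each M-step,
≤ 200 iterations, tolerance 1e-6) and is monotone in its penalized
(MAP, Dirichlet-prior) objective, which the model records next to the
raw log likelihood; the fit is a deterministic function of the input
paths. Components map to conditions by majority posterior. ROC curves
come from threshold sweeps over per-path posteriors (trapezoid AUC),
overall and per component — the component tied to the other condition
shows AUC < 0.5 by construction.

**Subnetwork and projection.** The union of top-path edges is labeled
exclusive-A / exclusive-B / shared (a partition, by construction), and
reaction nodes take the direction of their best-covered significant
protein (max |logFC|), else `undetected`, with the covered fraction
reported.

## Synthetic data: what it emulates, and what it does not

Intensities are log-normal: log2 value = feature baseline
(Normal(`base_log2_mean` = 20, `feature_mean_sd` = 2) — the scale and
spread of LC-MS peak areas) + planted group effect + Normal(0,
`feature_sd` = 1), times a log-normal per-sample dilution factor
(`sample_dilution_sd` = 0.25 log2 units) applied on the raw scale —
which is exactly the variation PQN is meant to remove. Missingness is
left-censoring below a global raw-intensity quantile
(`mnar_threshold_quantile` = 0.05) followed by uniform random removal
(`mar_rate` = 0.02); the truth tables record the exact MNAR/MAR
partition, the dilution factors and the planted effects. Proteomics
additionally draws unique-peptide counts and scores with ~10% of rows
below each identification threshold. The toy metabolic network plants
disjoint reaction chains (default length 9) with dedicated boundary
metabolites (so chain heads are source-like and tails sink-like) and
bypass connectors (so each chain supports several qualifying simple
routes), wires the remaining reactions randomly through a side pool
with a configurable ubiquitous fraction, and gives each reaction a
dedicated gene. Path-active expression draws a path's genes
equicorrelated (shared latent factor) at the requested correlation
within the active group only, then median-centers rows.

What passing these tests shows is that every stage recovers what its
own generating model plants at the stated sizes. What it does not show:
robustness to real LC-MS artifacts (batch effects, retention-time
drift, isotope interference, nonlinear saturation), to misannotated
network structure, or to missingness mechanisms other than
censoring-plus-uniform — the real study's missingness mechanism is
unknown, and MNAR-by-censoring is an explicit assumption of this
package.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so
each check is statistically decisive: 2 000 features for normalization
and null-calibration checks; 20 samples/group and 10 seeds for power;
20 seeds and 5 000 permutations for the planted PC-class enrichment;
50-reaction networks with 60 samples/group and 10 seeds for path mining
and classification; universes ≤ 25 for exact-enumeration oracles. The
bundled end-to-end study uses 4 + 5 patients for the MS layers
(estimable within-group variance at the study's cohort scale) and
30 + 30 for the transcriptome. Other fixed choices: BH for all multiple
testing; two-sided tests throughout; quantile-normalization grid equal
to the row count; trigamma inversion by Newton iteration to 1e-10;
untargeted ionization modes would be processed as separate matrices
(they are separate acquisitions).

## Known limitations

* The conditional (label-anchored) mixture makes the classifier
  supervised; it cannot discover sub-structure within a condition
  beyond its two components.
* LLS imputation assumes approximately linear co-expression among
  correlated proteins; with few complete proteins it degrades to
  row-mean imputation.
* Exhaustive path enumeration is exponential in `max_length`; dense
  graphs need a lower cap or a pre-filtered edge set.
* The enrichment p-value floor is 1/(same-sign permutations + 1);
  deeply significant sets need `n_perm` raised accordingly.
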