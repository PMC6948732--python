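"""Filtering, normalization, transformation and imputation.

The untargeted-lipidomics chain is presence filter -> quantile
normalization -> log2 -> minimum-value imputation; the targeted chain is
probabilistic quotient normalization (PQN) -> log2; proteomics is
peptide/score filter -> presence filter -> quantile normalization -> log2 ->
two-branch imputation (localized least squares for sporadically missing
proteins, left-censored normal draws for heavily missing ones).

All operations are pure: they return new containers and never mutate their
input. Observed cells are never altered by imputation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, ProteinTable, LOG2, RAW

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "filter_by_presence", "quantile_normalize", "pqn_normalize",
    "log2_transform", "impute_minimum",
    "filter_proteins", "impute_proteomics",
    "preprocess_untargeted_lipidomics", "preprocess_targeted_lipidomics",
    "preprocess_proteomics",
]


@dataclass
class PreprocessConfig:
    """Tunable thresholds of the preprocessing chain.

    ``presence_threshold`` — fraction of a group's samples in which a
    feature must be observed to survive filtering (default 0.75, inclusive).
    ``min_unique_peptides`` / ``min_score`` — protein identification
    filters (>=2 unique peptides, score strictly > 5).
    ``mar_cutoff`` — proteins missing in less than this fraction of all
    samples are treated as missing-at-random and imputed by regression;
    the rest are treated as left-censored.
    ``lls_neighbors`` — number of most-correlated complete proteins used
    by the localized least-squares regression.
    ``mnar_sd_factor`` — the censored-normal imputation draws from
    Normal(matrix minimum, (mnar_sd_factor x global sd)^2).
    """

    presence_threshold: float = 0.75
    min_unique_peptides: int = 2
    min_score: float = 5.0
    mar_cutoff: float = 0.25
    lls_neighbors: int = 10
    mnar_sd_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_threshold", "mar_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.lls_neighbors < 1:
            raise ValueError("lls_neighbors must be positive")
        if self.mnar_sd_factor <= 0:
            raise ValueError("mnar_sd_factor must be positive")


# ------------------------------------------------------------------ filters
def filter_by_presence(m: FeatureMatrix, cfg: PreprocessConfig | None = None) -> FeatureMatrix:
    """Keep features observed in >= threshold of samples of >=1 group.

    The comparison is inclusive: a feature present in exactly 75% of one
    group's samples survives at the default threshold.
    """
    cfg = cfg or PreprocessConfig()
    groups = m.group_labels
    for g in groups:
        if not m.samples_in(g):
            raise ValueError(f"group {g!r} has no samples")
    observed = m.values.notna()
    keep = pd.Series(False, index=m.values.index)
    for g in groups:
        cols = m.samples_in(g)
        frac = observed[cols].sum(axis=1) / len(cols)
        keep |= frac >= cfg.presence_threshold
    return m.with_values(m.values.loc[keep],
                         step=f"filter_by_presence(threshold={cfg.presence_threshold})")


def filter_proteins(t: ProteinTable, cfg: PreprocessConfig | None = None) -> ProteinTable:
    """Identification filter: unique peptides >= 2 AND score > 5, then presence.

    The peptide bound is inclusive and the score bound strict, matching the
    printed symbols of the filtering rule.
    """
    cfg = cfg or PreprocessConfig()
    for col in ("unique_peptides", "score"):
        if col not in t.proteins.columns:
            raise ValueError(f"protein table missing required column: {col}")
    keep = ((t.proteins["unique_peptides"] >= cfg.min_unique_peptides)
            & (t.proteins["score"] > cfg.min_score))
    kept_ids = list(t.proteins.index[keep])
    fm = FeatureMatrix(values=t.intensities.loc[kept_ids], groups=dict(t.groups),
                       scale=t.scale)
    fm = filter_by_presence(fm, cfg)
    return t.with_intensities(fm.values, keep=list(fm.values.index),
                              id_filter={"min_unique_peptides": cfg.min_unique_peptides,
                                         "min_score": cfg.min_score})


# ------------------------------------------------------------- normalization
def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns, tolerating missing values.

    Per-column ranks over observed values are mapped onto the mean quantile
    profile; the profile is the across-column mean of each column's
    empirical quantile function evaluated on a common grid. For complete
    columns this is exactly classical quantile normalization (sorted values
    replaced by cross-column row means of sorted values).
    """
    arr = values.to_numpy(float)
    n_rows, n_cols = arr.shape
    if n_cols < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    for j, col in enumerate(values.columns):
        if np.isnan(arr[:, j]).all():
            raise ValueError(f"sample {col!r} has no observed values")
    grid = np.linspace(0.0, 1.0, max(n_rows, 2))
    profiles = np.empty((len(grid), n_cols))
    for j in range(n_cols):
        obs = arr[~np.isnan(arr[:, j]), j]
        profiles[:, j] = np.quantile(obs, grid)
    reference = profiles.mean(axis=1)

    out = np.full_like(arr, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(arr[:, j])
        obs = arr[mask, j]
        n_obs = obs.size
        # average ranks for ties, scaled to [0, 1]
        order = np.argsort(obs, kind="stable")
        ranks = np.empty(n_obs)
        ranks[order] = np.arange(n_obs, dtype=float)
        # tie groups -> average rank
        sorted_obs = obs[order]
        uniq, inv, counts = np.unique(sorted_obs, return_inverse=True, return_counts=True)
        if len(uniq) < n_obs:
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            avg = starts + (counts - 1) / 2.0
            ranks[order] = avg[inv]
        pos = ranks / (n_obs - 1) if n_obs > 1 else np.full(n_obs, 0.5)
        out[mask, j] = np.interp(pos, grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(m: FeatureMatrix) -> FeatureMatrix:
    return m.with_values(_quantile_normalize_frame(m.values), step="quantile_normalize")


def pqn_normalize(m: FeatureMatrix, reference: str = "median",
                  min_shared: int = 3) -> FeatureMatrix:
    """Probabilistic quotient normalization on the raw intensity scale.

    Each sample is divided by the median of its feature-wise quotients to a
    reference spectrum (feature-wise median across samples by default),
    removing per-sample dilution/injection-volume variation.
    """
    if m.scale != RAW:
        raise ValueError("PQN is computed on the raw intensity scale")
    if reference not in ("median", "mean"):
        raise ValueError("reference must be 'median' or 'mean'")
    vals = m.values
    ref = vals.median(axis=1) if reference == "median" else vals.mean(axis=1)
    ref = ref.replace(0.0, np.nan)
    out = vals.copy()
    factors = {}
    for s in vals.columns:
        quot = vals[s] / ref
        quot = quot.dropna()
        if len(quot) < min_shared:
            raise ValueError(
                f"sample {s!r} shares only {len(quot)} non-missing features "
                f"with the reference spectrum (need >= {min_shared})")
        f = float(np.median(quot))
        factors[s] = f
        out[s] = vals[s] / f
    res = m.with_values(out, step=f"pqn_normalize(reference={reference})")
    res.provenance.append({"pqn_factors": factors})
    return res


def pqn_factors(m: FeatureMatrix, reference: str = "median") -> dict[str, float]:
    """The per-sample quotient factors PQN would divide out."""
    vals = m.values
    ref = vals.median(axis=1) if reference == "median" else vals.mean(axis=1)
    ref = ref.replace(0.0, np.nan)
    return {s: float(np.median((vals[s] / ref).dropna())) for s in vals.columns}


# ------------------------------------------------------------ transformation
def log2_transform(m: FeatureMatrix) -> FeatureMatrix:
    """log2-transform a raw matrix; zero/negative values are an error."""
    if m.scale != RAW:
        raise ValueError("input is already log2 scale")
    vals = m.values.to_numpy(float)
    bad = np.nansum(vals <= 0)
    if bad:
        raise ValueError(f"{int(bad)} non-positive values cannot be log2 transformed "
                         "(no silent pseudo-count is applied)")
    return m.with_values(np.log2(m.values), scale=LOG2, step="log2_transform")


def impute_minimum(m: FeatureMatrix) -> FeatureMatrix:
    """Replace every missing cell with the matrix-wide minimum observed value."""
    vals = m.values
    if vals.notna().to_numpy().sum() == 0:
        raise ValueError("matrix has no observed values to impute from")
    global_min = float(np.nanmin(vals.to_numpy(float)))
    return m.with_values(vals.fillna(global_min), step="impute_minimum")


# ---------------------------------------------------------------- proteomics
def _lls_impute_row(target: np.ndarray, complete: np.ndarray, k: int) -> np.ndarray:
    """Localized least squares: regress target on its k most-correlated
    complete rows over the target's observed samples, predict the missing."""
    obs = ~np.isnan(target)
    y = target[obs]
    with np.errstate(invalid="ignore", divide="ignore"):
        centred = complete[:, obs] - complete[:, obs].mean(axis=1, keepdims=True)
        yc = y - y.mean()
        denom = np.sqrt((centred ** 2).sum(axis=1) * (yc ** 2).sum())
        corr = np.where(denom > 0, centred @ yc / denom, 0.0)
    idx = np.argsort(-np.abs(corr), kind="stable")[:k]
    X = complete[idx]
    design = np.column_stack([np.ones(obs.sum()), X[:, obs].T])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred_design = np.column_stack([np.ones((~obs).sum()), X[:, ~obs].T])
    filled = target.copy()
    filled[~obs] = pred_design @ beta
    return filled


def impute_proteomics(t: ProteinTable, cfg: PreprocessConfig | None = None) -> ProteinTable:
    """Two-branch imputation for a log2, quantile-normalized protein matrix.

    Proteins missing in < ``mar_cutoff`` of all samples are regarded as
    missing at random and imputed by localized least-squares regression on
    their most-correlated complete proteins. Proteins missing in >= the
    cutoff are regarded as left-censored and imputed by seeded draws from a
    normal centred at the matrix minimum. The MAR/MNAR partition is
    recorded in the output metadata.
    """
    cfg = cfg or PreprocessConfig()
    if t.scale != LOG2:
        raise ValueError("impute_proteomics expects log2-transformed intensities")
    vals = t.intensities.to_numpy(float).copy()
    n_samples = vals.shape[1]
    miss_frac = np.isnan(vals).sum(axis=1) / n_samples
    complete_mask = miss_frac == 0
    mar_mask = (miss_frac > 0) & (miss_frac < cfg.mar_cutoff)
    mnar_mask = miss_frac >= cfg.mar_cutoff

    rng = np.random.default_rng(cfg.seed)
    global_min = float(np.nanmin(vals))
    global_sd = float(np.nanstd(vals))
    complete = vals[complete_mask]

    out = vals.copy()
    use_lls = complete.shape[0] >= cfg.lls_neighbors
    if not use_lls and mar_mask.any():
        warnings.warn(
            f"only {complete.shape[0]} complete proteins < lls_neighbors="
            f"{cfg.lls_neighbors}; falling back to row-mean imputation",
            stacklevel=2)
        log.warning("LLS fallback to row-mean imputation")
    for i in np.where(mar_mask)[0]:
        if use_lls:
            out[i] = _lls_impute_row(vals[i], complete, cfg.lls_neighbors)
        else:
            row = vals[i]
            filled = row.copy()
            filled[np.isnan(row)] = np.nanmean(row)
            out[i] = filled
    for i in np.where(mnar_mask)[0]:
        row = out[i]
        nan_idx = np.isnan(row)
        row[nan_idx] = rng.normal(global_min, cfg.mnar_sd_factor * global_sd,
                                  nan_idx.sum())
    ids = t.intensities.index
    partition = {"mar": list(ids[mar_mask]), "mnar": list(ids[mnar_mask])}
    filled = pd.DataFrame(out, index=ids, columns=t.intensities.columns)
    return t.with_intensities(filled, imputation_partition=partition,
                              imputation_seed=cfg.seed)


# ------------------------------------------------------------------- chains
def preprocess_untargeted_lipidomics(m: FeatureMatrix,
                                     cfg: PreprocessConfig | None = None,
                                     *, impute_first: bool = True) -> FeatureMatrix:
    """Presence filter, then impute/normalize in the stated order.

    The printed order (minimum-value imputation before quantile
    normalization and log2) is the default; ``impute_first=False`` imputes
    after normalization instead.
    """
    cfg = cfg or PreprocessConfig()
    m = filter_by_presence(m, cfg)
    if impute_first:
        m = impute_minimum(m)
        m = quantile_normalize(m)
        m = log2_transform(m)
    else:
        m = quantile_normalize(m)
        m = log2_transform(m)
        m = impute_minimum(m)
    return m


def preprocess_targeted_lipidomics(m: FeatureMatrix,
                                   cfg: PreprocessConfig | None = None) -> FeatureMatrix:
    """PQN on the raw scale, then log2. Missing values are left missing."""
    m = pqn_normalize(m)
    return log2_transform(m)


def preprocess_proteomics(t: ProteinTable, cfg: PreprocessConfig | None = None) -> ProteinTable:
    """Identification + presence filters, quantile normalize, log2, impute."""
    cfg = cfg or PreprocessConfig()
    t = filter_proteins(t, cfg)
    fm = FeatureMatrix(values=t.intensities, groups=dict(t.groups), scale=t.scale)
    fm = quantile_normalize(fm)
    fm = log2_transform(fm)
    t = t.with_intensities(fm.values, scale=LOG2)
    return impute_proteomics(t, cfg)
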