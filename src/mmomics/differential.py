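"""Two-group moderated differential analysis.

The model is the standard empirical-Bayes moderated t: per-feature ordinary
least squares on a two-group design gives a log2 fold change, a pooled
residual variance ``s^2`` and residual degrees of freedom ``d``; the
variances are then shrunk towards a common prior by assuming

    s^2 | sigma^2  ~  sigma^2 * chi^2_d / d,
    1 / sigma^2    ~  (1 / (d0 * s0^2)) * chi^2_d0,

whose hyperparameters (prior df ``d0``, prior variance ``s0^2``) are
estimated by method of moments on the log variances (the scaled-F fit used
by the classical moderated-t method). The moderated statistic

    t_mod = logFC / (s_tilde * sqrt(1/n1 + 1/n2)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

is referred to a t distribution with ``d0 + d`` degrees of freedom, and
p-values are adjusted across features by Benjamini-Hochberg.

Significance follows the study's two-tier rule: a raw flag (p < 0.05), an
adjusted flag (BH p < 0.05), and up/down tallies that additionally require
|logFC| > 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix, LOG2

__all__ = [
    "DesignSpec", "TwoGroupFit", "fit_two_group", "ebayes_moderate",
    "call_significant", "run_differential", "write_results",
]


@dataclass
class DesignSpec:
    """Contrast definition and significance thresholds.

    ``contrast`` is (numerator, denominator); logFC = mean(numerator) -
    mean(denominator), so negative values mean lower in the first-named
    group.
    """

    contrast: tuple[str, str]
    use_adjusted: bool = False
    p_threshold: float = 0.05
    lfc_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def name(self) -> str:
        return f"{self.contrast[0]}.{self.contrast[1]}"


@dataclass
class TwoGroupFit:
    """Per-feature OLS summaries prior to moderation."""

    feature_ids: list
    logFC: np.ndarray
    s2: np.ndarray        # pooled residual variance
    df: np.ndarray        # residual degrees of freedom (n1 + n2 - 2)
    n1: np.ndarray
    n2: np.ndarray
    design: DesignSpec = None
    flagged: list = field(default_factory=list)  # <2 observations in a group


def fit_two_group(m: FeatureMatrix, design: DesignSpec) -> TwoGroupFit:
    """Per-feature group-mean difference and pooled residual variance.

    Features with fewer than 2 observed values in either group are flagged
    and carry NaN statistics rather than being dropped silently.
    """
    if m.scale != LOG2:
        raise ValueError("differential analysis expects a log2-scale matrix")
    num, den = design.contrast
    for g in (num, den):
        if g not in m.group_labels:
            raise ValueError(f"group {g!r} absent from matrix")
    a = m.values[m.samples_in(num)].to_numpy(float)
    b = m.values[m.samples_in(den)].to_numpy(float)
    n1 = (~np.isnan(a)).sum(axis=1).astype(float)
    n2 = (~np.isnan(b)).sum(axis=1).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        rss = (np.nansum((a - mean_a[:, None]) ** 2, axis=1)
               + np.nansum((b - mean_b[:, None]) ** 2, axis=1))
    df = n1 + n2 - 2
    logfc = mean_a - mean_b
    s2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
    logfc[~ok] = np.nan
    s2[~ok] = np.nan
    df_out = np.where(ok, df, np.nan)
    flagged = [f for f, good in zip(m.feature_ids, ok) if not good]
    return TwoGroupFit(feature_ids=m.feature_ids, logFC=logfc, s2=s2, df=df_out,
                       n1=n1, n2=n2, design=design, flagged=flagged)


# ----------------------------------------------------------- hyperparameters
def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from log residual variances.

    Uses the identities E[log s^2] = log sigma^2 + psi(d/2) - log(d/2) for
    scaled chi^2 variates, matching mean and variance of
    z = log s^2 - psi(d/2) + log(d/2) against the scaled inverse chi^2
    prior. Returns (inf, geometric-mean variance) when the observed spread
    of log variances is no larger than sampling noise.
    """
    mask = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    s2u, dfu = s2[mask], df[mask]
    if s2u.size < 2:
        raise ValueError("need >=2 positive finite variances to fit the prior")
    z = np.log(s2u)
    e = z - special.digamma(dfu / 2.0) + np.log(dfu / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, dfu / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def ebayes_moderate(fit: TwoGroupFit, *, prior_df: float | None = None,
                    prior_var: float | None = None,
                    min_features: int = 10) -> pd.DataFrame:
    """Moderate the per-feature variances and return a results table.

    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` reproduces the ordinary pooled t exactly). With fewer
    than ``min_features`` usable features, hyperparameter estimation is
    unstable and the function falls back to the ordinary t with a warning.
    """
    s2, df = fit.s2, fit.df
    usable = np.isfinite(s2) & np.isfinite(df)
    if usable.any() and np.all(s2[usable] == 0):
        raise ValueError("all residual variances are zero; degenerate input")

    if prior_df is None:
        if usable.sum() < min_features:
            warnings.warn(f"only {int(usable.sum())} features; falling back to "
                          "ordinary t (no variance moderation)", stacklevel=2)
            d0, s0_sq = 0.0, 1.0
        else:
            d0, s0_sq = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_var) if prior_var is not None else 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.where(usable, s0_sq, np.nan)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = d0 + df
        se = np.sqrt(s2_post * (1.0 / fit.n1 + 1.0 / fit.n2))
        t_mod = fit.logFC / se
        p = 2.0 * stats.t.sf(np.abs(t_mod), np.minimum(df_total, 1e8))

    p_adj = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        p_adj[finite] = multipletests(p[finite], method="fdr_bh")[1]

    res = pd.DataFrame({
        "feature_id": fit.feature_ids,
        "logFC": fit.logFC,
        "t": t_mod,
        "p_value": p,
        "adj_p_value": p_adj,
        "s2_post": s2_post,
        "df_total": df_total,
    }).set_index("feature_id")
    res.attrs["prior_df"] = d0
    res.attrs["prior_var"] = s0_sq
    res.attrs["comparison"] = fit.design.name if fit.design else None
    return res


def call_significant(results: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Attach significance flags and direction; return augmented table.

    ``significant_raw``: p < threshold; ``significant_adj``: BH p <
    threshold. Up/down regulation (used for summary tallies) additionally
    requires |logFC| strictly > the fold-change threshold.
    """
    out = results.copy()
    out["significant_raw"] = out["p_value"] < design.p_threshold
    out["significant_adj"] = out["adj_p_value"] < design.p_threshold
    out["direction"] = np.where(out["logFC"] > 0, "up",
                                np.where(out["logFC"] < 0, "down", "none"))
    sig = out["significant_adj"] if design.use_adjusted else out["significant_raw"]
    big = out["logFC"].abs() > design.lfc_threshold
    out["regulated"] = np.where(sig & big & (out["logFC"] > 0), "up",
                                np.where(sig & big & (out["logFC"] < 0), "down", "ns"))
    return out


def summarize_counts(results: pd.DataFrame) -> dict:
    """Per-comparison tallies in the detected/filtered/significant shape."""
    return {
        "tested": int(results["p_value"].notna().sum()),
        "significant_raw": int(results.get("significant_raw", pd.Series(dtype=bool)).sum()),
        "significant_adj": int(results.get("significant_adj", pd.Series(dtype=bool)).sum()),
        "up_regulated": int((results.get("regulated") == "up").sum()),
        "down_regulated": int((results.get("regulated") == "down").sum()),
    }


def run_differential(m: FeatureMatrix, design: DesignSpec, **ebayes_kw) -> pd.DataFrame:
    """fit -> moderate -> flag, in one call."""
    fit = fit_two_group(m, design)
    res = ebayes_moderate(fit, **ebayes_kw)
    return call_significant(res, design)


def write_results(results: pd.DataFrame, path) -> None:
    cols = ["logFC", "t", "p_value", "adj_p_value",
            "significant_raw", "significant_adj", "direction"]
    out = results[[c for c in cols if c in results.columns]].copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")
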