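"""Preranked set-enrichment analysis (weighted Kolmogorov-Smirnov).

Features are ranked by log2 fold change; for each feature set the running
sum increments by ``|logFC|^w / sum(|logFC|^w over hits)`` at member
positions and decrements by ``1 / (N - N_hits)`` elsewhere; the enrichment
score (ES) is the extremum of the running sum. The null distribution is
obtained by redrawing the member labels uniformly from the ranked universe
(preranked mode: only the ranking is available, so labels — not samples —
are permuted). When the number of distinct member subsets is no larger
than ``n_perm`` the null is enumerated exhaustively and the p-value is
exact; otherwise it is a Monte-Carlo estimate with the +1 correction.

NES is ES divided by the mean magnitude of same-sign null scores, and
p-values are sign-matched tail probabilities, BH-adjusted across sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .lipids import FeatureSet

log = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "enrichment_score", "preranked_enrichment"]


@dataclass
class EnrichmentResult:
    set_id: str
    kind: str
    size: int
    ES: float
    NES: float
    p_value: float
    adj_p_value: float
    leading_edge: list[str]


def _order_ranking(ranking: dict[str, float]) -> tuple[list[str], np.ndarray]:
    """Descending logFC; ties broken by feature id for determinism."""
    items = sorted(ranking.items(), key=lambda kv: (-kv[1], kv[0]))
    ids = [k for k, _ in items]
    values = np.array([v for _, v in items], float)
    if np.isnan(values).any():
        bad = [ids[i] for i in np.where(np.isnan(values))[0][:5]]
        raise ValueError(f"ranking contains missing values, e.g. {bad}")
    return ids, values


def _es_from_positions(weights: np.ndarray, positions: np.ndarray,
                       n: int) -> tuple[float, int]:
    """ES and extremum index given |logFC|^w weights and 0-based hit positions."""
    n_hits = positions.size
    hit_w = weights[positions]
    denom = hit_w.sum()
    miss_pen = 1.0 / (n - n_hits)
    step = np.full(n, -miss_pen)
    if denom > 0:
        step[positions] = hit_w / denom
    else:                                   # all-zero weights: unweighted KS
        step[positions] = 1.0 / n_hits
    running = np.cumsum(step)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if abs(running[imax]) >= abs(running[imin]):
        return float(running[imax]), imax
    return float(running[imin]), imin


def enrichment_score(ranking: dict[str, float], members: set[str],
                     weight_exponent: float = 1.0) -> tuple[float, list[str]]:
    """ES and leading-edge members for one set against a ranking."""
    ids, values = _order_ranking(ranking)
    n = len(ids)
    positions = np.array([i for i, f in enumerate(ids) if f in members], int)
    if positions.size == 0 or positions.size == n:
        raise ValueError("set must be a proper non-empty subset of the universe")
    weights = np.abs(values) ** weight_exponent
    es, iext = _es_from_positions(weights, positions, n)
    if es >= 0:
        leading = [ids[i] for i in positions if i <= iext]
    else:
        leading = [ids[i] for i in positions if i >= iext]
    return es, leading


def _es_batch(weights: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for a batch of hit-position sets, shape (B, k)."""
    b, k = positions.shape
    miss_pen = 1.0 / (n - k)
    steps = np.full((b, n), -miss_pen)
    hit_w = weights[positions]                       # (B, k)
    denom = hit_w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        incr = np.where(denom > 0, hit_w / denom, 1.0 / k)
    np.put_along_axis(steps, positions, incr, axis=1)
    running = np.cumsum(steps, axis=1)
    imax = running.argmax(axis=1)
    imin = running.argmin(axis=1)
    vmax = running[np.arange(b), imax]
    vmin = running[np.arange(b), imin]
    return np.where(np.abs(vmax) >= np.abs(vmin), vmax, vmin)


def _null_scores_exhaustive(weights: np.ndarray, n: int, k: int) -> np.ndarray:
    positions = np.array(list(combinations(range(n), k)), int)
    return _es_batch(weights, positions, n)


def _null_scores_sampled(weights: np.ndarray, n: int, k: int, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    positions = np.empty((n_perm, k), int)
    for i in range(n_perm):
        positions[i] = np.sort(rng.choice(n, size=k, replace=False))
    return _es_batch(weights, positions, n)


def _tail_p(es: float, null: np.ndarray, exact: bool) -> tuple[float, float]:
    """Sign-matched tail p and the same-sign null mean magnitude (for NES)."""
    same = null >= 0 if es >= 0 else null < 0
    null_same = null[same]
    if null_same.size == 0:
        return (1.0 / (null.size + 1), np.abs(null).mean() or 1.0)
    extreme = int((np.abs(null_same) >= abs(es) - 1e-15).sum())
    if exact:
        p = extreme / null_same.size
    else:
        p = (extreme + 1) / (null_same.size + 1)
    denom = np.abs(null_same).mean()
    return p, denom if denom > 0 else 1.0


def preranked_enrichment(ranking: dict[str, float], sets: list[FeatureSet],
                         n_perm: int = 10000, weight_exponent: float = 1.0,
                         seed: int = 0, min_size: int = 3) -> pd.DataFrame:
    """Permutation-based preranked enrichment over a list of feature sets.

    Returns a DataFrame indexed by ``set_id`` with columns
    ``kind, size, ES, NES, p_value, adj_p_value, leading_edge``. Sets with
    fewer than ``min_size`` members in the ranking universe, or covering
    the whole universe, are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids, values = _order_ranking(ranking)
    n = len(ids)
    universe = set(ids)
    weights = np.abs(values) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, tuple[np.ndarray, bool]] = {}
    for fs in sets:
        members = set(fs.members) & universe
        k = len(members)
        if k < min_size:
            warnings.warn(f"set {fs.set_id!r}: only {k} members in universe "
                          f"(< {min_size}); skipped", stacklevel=2)
            continue
        if k == n:
            warnings.warn(f"set {fs.set_id!r} covers the whole universe; skipped",
                          stacklevel=2)
            continue
        es, leading = enrichment_score(ranking, members, weight_exponent)
        if k not in null_cache:
            if comb(n, k) <= n_perm:
                null_cache[k] = (_null_scores_exhaustive(weights, n, k), True)
            else:
                null_cache[k] = (_null_scores_sampled(weights, n, k, n_perm, rng),
                                 False)
        null, exact = null_cache[k]
        p, denom = _tail_p(es, null, exact)
        rows.append({"set_id": fs.set_id, "kind": fs.kind, "size": k,
                     "ES": es, "NES": es / denom, "p_value": p,
                     "leading_edge": leading})
    if not rows:
        return pd.DataFrame(columns=["kind", "size", "ES", "NES", "p_value",
                                     "adj_p_value", "leading_edge"])
    df = pd.DataFrame(rows).set_index("set_id")
    df["adj_p_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df[["kind", "size", "ES", "NES", "p_value", "adj_p_value", "leading_edge"]]


def write_enrichment(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["leading_edge"] = out["leading_edge"].map(lambda xs: "|".join(xs))
    out.index.name = "set_id"
    out.to_csv(path, sep="\t")
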