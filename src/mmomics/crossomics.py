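"""Gene- and pathway-level concordance between two differential analyses.

The comparison asks two questions about the significant lists of analyses
A (e.g. proteomics) and B (e.g. transcriptomics) over a shared tested
universe:

* is the overlap larger than chance? — upper-tail hypergeometric
  probability of observing at least the overlap when drawing |A| ids from
  a universe containing |B| successes;
* do the overlapping ids move the same way? — one-sided binomial sign
  test at probability 1/2 on the number of direction-concordant ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["ConcordanceSummary", "collapse_probes", "concordance"]


@dataclass
class ConcordanceSummary:
    n_universe: int
    n_sig_A: int
    n_sig_B: int
    n_overlap: int
    n_same_direction: int
    p_overlap: float
    p_direction: float

    def __post_init__(self) -> None:
        if not (self.n_same_direction <= self.n_overlap
                <= min(self.n_sig_A, self.n_sig_B)):
            raise ValueError("inconsistent concordance counts")

    def as_dict(self) -> dict:
        return asdict(self)


def collapse_probes(expr: pd.DataFrame, mapping: dict[str, str],
                    rule: str = "max_mean") -> pd.DataFrame:
    """Collapse a probe-level matrix to target (UniProt) ids.

    ``rule='max_mean'`` keeps, per target, the probe with highest mean
    expression (the common microarray convention); ``rule='mean'``
    averages probes. Unmapped probes are dropped and their count logged.
    """
    if not mapping:
        raise ValueError("empty probe mapping")
    if rule not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    mapped = [p for p in expr.index if p in mapping]
    dropped = expr.shape[0] - len(mapped)
    if not mapped:
        raise ValueError("no probe in the matrix maps to a target id")
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    sub = expr.loc[mapped]
    targets = pd.Series([mapping[p] for p in mapped], index=sub.index, name="target")
    if rule == "mean":
        out = sub.groupby(targets).mean()
    else:
        means = sub.mean(axis=1)
        best = (pd.DataFrame({"target": targets, "mean": means})
                .groupby("target")["mean"].idxmax())
        out = sub.loc[best.to_numpy()]
        out.index = best.index
    out.index.name = "target_id"
    return out.sort_index()


def concordance(sig_a: pd.DataFrame | list, sig_b: pd.DataFrame | list,
                universe: list[str]) -> ConcordanceSummary:
    """Overlap and direction concordance of two significant lists.

    ``sig_a``/``sig_b`` may be differential-result DataFrames (indexed by
    feature id, restricted by the caller to significant rows, with a
    ``logFC`` column used for direction) or plain id lists (direction
    concordance then counts 0).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")

    def ids_and_sign(x):
        if isinstance(x, pd.DataFrame):
            ids = set(map(str, x.index)) & uni
            sign = {str(i): (1 if lfc > 0 else -1 if lfc < 0 else 0)
                    for i, lfc in x["logFC"].items() if str(i) in uni}
            return ids, sign
        ids = set(map(str, x)) & uni
        return ids, {}

    a_ids, a_sign = ids_and_sign(sig_a)
    b_ids, b_sign = ids_and_sign(sig_b)
    overlap = a_ids & b_ids
    n_overlap = len(overlap)
    same = sum(1 for i in overlap
               if a_sign.get(i, 0) != 0 and a_sign.get(i) == b_sign.get(i))

    # P(X >= n_overlap), X ~ Hypergeom(N=|U|, K=|B|, n=|A|)
    p_overlap = float(stats.hypergeom.sf(n_overlap - 1, len(uni), len(b_ids),
                                         len(a_ids)))
    # one-sided sign test on direction agreement among overlapping ids
    p_direction = (float(stats.binom.sf(same - 1, n_overlap, 0.5))
                   if n_overlap > 0 else 1.0)
    return ConcordanceSummary(n_universe=len(uni), n_sig_A=len(a_ids),
                              n_sig_B=len(b_ids), n_overlap=n_overlap,
                              n_same_direction=same, p_overlap=p_overlap,
                              p_direction=p_direction)
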