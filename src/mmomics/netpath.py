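"""Metabolic reaction-graph construction, correlation weighting, path
mining and path classification.

Starting from a lipid-metabolism network of reactions and metabolites,
ubiquitous compounds (water, co-factors, ...) are removed to prevent
over-connectivity, metabolite nodes are contracted away to give a directed
reaction graph (edge r1 -> r2 whenever a non-ubiquitous product of r1 is a
substrate of r2), and each edge is weighted per sample group by the
correlation of the adjacent reactions' gene expression. High-scoring
simple paths are extracted per group, their association with group
membership is quantified by a two-component mixture of first-order Markov
chains fitted by EM (with ROC/AUC readout), and group-exclusive
subnetworks are extracted and annotated with proteomics fold changes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

log = logging.getLogger(__name__)

__all__ = [
    "MetabolicNetwork", "MetabolicPath", "PathClassifierModel",
    "build_reaction_graph", "weight_edges", "extract_top_paths",
    "train_path_classifier", "classify_paths",
    "extract_subnetwork", "project_differential",
    "write_paths_tsv", "write_sif",
]

OTHER_STATE = "<other>"


# ------------------------------------------------------------------ network
@dataclass
class MetabolicNetwork:
    """Reactions + metabolites with substrate/product roles and gene
    annotations. Reversible reactions are represented as explicit directed
    duplicates; there is no implicit reversibility."""

    reactions: list[dict]       # {id, substrates: [...], products: [...], genes: [...]}
    metabolites: list[dict]     # {id, ubiquitous: bool}

    def __post_init__(self) -> None:
        rids = [r["id"] for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("reaction ids must be unique")
        known = {m["id"] for m in self.metabolites}
        for r in self.reactions:
            unknown = (set(r["substrates"]) | set(r["products"])) - known
            if unknown:
                raise ValueError(f"reaction {r['id']!r} references unknown "
                                 f"metabolites: {sorted(unknown)}")

    @property
    def ubiquitous(self) -> set[str]:
        return {m["id"] for m in self.metabolites if m.get("ubiquitous", False)}

    @classmethod
    def from_json(cls, path) -> "MetabolicNetwork":
        data = json.loads(Path(path).read_text())
        return cls(reactions=data["reactions"], metabolites=data["metabolites"])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"metabolites": self.metabolites, "reactions": self.reactions},
            indent=1) + "\n")


def build_reaction_graph(net: MetabolicNetwork,
                         extra_ubiquitous: list[str] | None = None) -> nx.DiGraph:
    """Directed reaction graph after ubiquitous-compound removal.

    Edge r1 -> r2 iff some non-ubiquitous product of r1 is a substrate of
    r2 (r1 != r2); the shared metabolites are recorded on the edge. Gene
    annotations become node attributes.
    """
    ubiq = net.ubiquitous | set(extra_ubiquitous or [])
    g = nx.DiGraph()
    for r in net.reactions:
        g.add_node(r["id"], genes=list(r.get("genes", [])))
    consumers: dict[str, list[str]] = {}
    for r in net.reactions:
        for m in r["substrates"]:
            if m not in ubiq:
                consumers.setdefault(m, []).append(r["id"])
    for r in net.reactions:
        for m in r["products"]:
            if m in ubiq:
                continue
            for r2 in consumers.get(m, []):
                if r2 == r["id"]:
                    continue
                if g.has_edge(r["id"], r2):
                    g[r["id"]][r2]["metabolites"].append(m)
                else:
                    g.add_edge(r["id"], r2, metabolites=[m], weights={},
                               unmeasured={})
    return g


# ------------------------------------------------------------------ weights
def weight_edges(g: nx.DiGraph, expr: pd.DataFrame,
                 groups: dict[str, str], aggregate: str = "max") -> nx.DiGraph:
    """Per-group edge weights from adjacent pairwise gene correlation.

    For each group and edge (r1, r2) the weight is the maximum (or mean)
    Pearson correlation over all gene pairs (gene of r1) x (gene of r2)
    computed on that group's samples. Edges where either reaction has no
    measured gene receive the group's median weight and an ``unmeasured``
    flag, preserving connectivity.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    labels = sorted(set(groups.values()))
    cols = [s for s in expr.columns if s in groups]
    for lab in labels:
        n = sum(1 for s in cols if groups[s] == lab)
        if n < 3:
            raise ValueError(f"group {lab!r} has {n} samples; need >= 3")
    g = g.copy()
    measured = set(expr.index)
    for lab in labels:
        sub = expr[[s for s in cols if groups[s] == lab]]
        arr = sub.to_numpy(float)
        # centre/scale once; correlation = scaled dot product
        centred = arr - arr.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(norms[:, None] > 0, centred / norms[:, None], 0.0)
        row_of = {gene: i for i, gene in enumerate(sub.index)}

        pending = []
        known = []
        for u, v, data in g.edges(data=True):
            gu = [x for x in g.nodes[u]["genes"] if x in measured]
            gv = [x for x in g.nodes[v]["genes"] if x in measured]
            if not gu or not gv:
                pending.append((u, v))
                continue
            block = scaled[[row_of[x] for x in gu]] @ scaled[[row_of[x] for x in gv]].T
            w = float(block.max()) if aggregate == "max" else float(block.mean())
            data["weights"][lab] = w
            data["unmeasured"][lab] = False
            known.append(w)
        median = float(np.median(known)) if known else 0.0
        for u, v in pending:
            g[u][v]["weights"][lab] = median
            g[u][v]["unmeasured"][lab] = True
    return g


# -------------------------------------------------------------------- paths
@dataclass
class MetabolicPath:
    """A simple reaction path with its mean-edge-weight score."""

    reactions: list[str]
    score: float
    condition: str

    def __post_init__(self) -> None:
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("path must be simple (no repeated reactions)")

    @property
    def length(self) -> int:
        return len(self.reactions) - 1     # edge count

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.reactions[:-1], self.reactions[1:]))


def _candidate_endpoints(g: nx.DiGraph) -> tuple[list, list]:
    # source-like / sink-like boundary nodes; when one side has no
    # degree-0 node (cyclic region), every node is a candidate on that side
    sources = [n for n in g.nodes if g.in_degree(n) == 0] or list(g.nodes)
    sinks = [n for n in g.nodes if g.out_degree(n) == 0] or list(g.nodes)
    return sources, sinks


def extract_top_paths(g: nx.DiGraph, group: str, k: int = 50,
                      min_length: int = 6, max_length: int = 12) -> list[MetabolicPath]:
    """The k best-scoring simple paths of >= ``min_length`` edges.

    Paths run from source-like (zero in-degree) to sink-like (zero
    out-degree) reactions — every node when the graph has no boundary
    nodes — and are scored by mean edge weight for ``group``. Enumeration
    is exhaustive up to ``max_length`` edges, so the returned set is exact
    on the sparse networks this pipeline targets. Order is deterministic:
    score descending, then lexicographic node sequence.
    """
    for _, _, data in g.edges(data=True):
        if group not in data["weights"]:
            raise ValueError(f"edges carry no weights for group {group!r}")
        break
    sources, sinks = _candidate_endpoints(g)
    sink_set = set(sinks)

    found: list[tuple[float, list[str]]] = []

    def dfs(node: str, path: list[str], weight_sum: float, on_path: set) -> None:
        n_edges = len(path) - 1
        if n_edges >= min_length and node in sink_set:
            found.append((weight_sum / n_edges, list(path)))
        if n_edges >= max_length:
            return
        for nxt in g.successors(node):
            if nxt in on_path:
                continue
            on_path.add(nxt)
            path.append(nxt)
            dfs(nxt, path, weight_sum + g[node][nxt]["weights"][group], on_path)
            path.pop()
            on_path.remove(nxt)

    for s in sources:
        dfs(s, [s], 0.0, {s})

    if not found:
        warnings.warn(f"no simple path with >= {min_length} edges found for "
                      f"group {group!r}", stacklevel=2)
        return []
    found.sort(key=lambda sp: (-sp[0], sp[1]))
    return [MetabolicPath(reactions=nodes, score=score, condition=group)
            for score, nodes in found[:k]]


# --------------------------------------------------------------- classifier
@dataclass
class PathClassifierModel:
    """Two-component mixture of first-order Markov chains over reaction
    sequences. ``states`` fixes the alphabet (with a catch-all state for
    unseen reactions); rows of each transition matrix sum to 1."""

    states: list[str]
    initial: np.ndarray          # (2, S)
    transition: np.ndarray       # (2, S, S)
    mixture: np.ndarray          # (2,)
    component_condition: dict[int, str] = field(default_factory=dict)
    loglik_trajectory: list[float] = field(default_factory=list)
    objective_trajectory: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.transition.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.mixture.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")

    def _encode(self, reactions: list[str]) -> list[int]:
        idx = {s: i for i, s in enumerate(self.states)}
        other = idx[OTHER_STATE]
        return [idx.get(r, other) for r in reactions]

    def log_likelihood(self, reactions: list[str]) -> np.ndarray:
        """Per-component log p(sequence | component), shape (2,)."""
        seq = self._encode(reactions)
        ll = np.log(self.initial[:, seq[0]])
        for a, b in zip(seq[:-1], seq[1:]):
            ll = ll + np.log(self.transition[:, a, b])
        return ll

    def posterior(self, reactions: list[str]) -> np.ndarray:
        ll = self.log_likelihood(reactions) + np.log(self.mixture)
        ll -= ll.max()
        w = np.exp(ll)
        return w / w.sum()


def train_path_classifier(paths_by_condition: dict[str, list[MetabolicPath]],
                          seed: int = 0, alpha: float = 1.0,
                          max_iter: int = 200, tol: float = 1e-6,
                          min_paths: int = 5,
                          label_noise: float = 0.05) -> PathClassifierModel:
    """Fit the Markov-chain mixture by EM on the pooled path sequences.

    Because the training paths carry condition labels, the mixture is
    conditional: the component indicator of path i is its condition label
    observed through a flip-noise channel, so the mixing weights are
    fixed at pi[label] = (1 - label_noise, label_noise), anchoring each
    component to one condition; EM fits the component parameters (Laplace
    smoothing ``alpha`` on initial/transition counts at every M-step).
    When the conditions separate, each component captures one condition's
    path structure; when they carry the same distribution the two
    components converge to similar chains and held-out posteriors hover
    around 0.5. The fit is a deterministic function of the input paths
    (label-informed initialization; the seed is kept in the signature for
    API stability). Iteration stops after ``max_iter`` rounds or when the
    log likelihood improves by less than ``tol``. Components are mapped
    to conditions by majority posterior.
    """
    conditions = sorted(paths_by_condition)
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    for c in conditions:
        if len(paths_by_condition[c]) < min_paths:
            raise ValueError(f"condition {c!r} has {len(paths_by_condition[c])} "
                             f"paths; need >= {min_paths}")
    paths = [p for c in conditions for p in paths_by_condition[c]]
    labels = [c for c in conditions for _ in paths_by_condition[c]]

    states = sorted({r for p in paths for r in p.reactions}) + [OTHER_STATE]
    idx = {s: i for i, s in enumerate(states)}
    S = len(states)
    seqs = [[idx[r] for r in p.reactions] for p in paths]
    n = len(seqs)

    del seed
    if not 0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    eps = label_noise
    label_idx = np.array([conditions.index(lab) for lab in labels])
    resp = np.full((n, 2), eps)
    resp[np.arange(n), label_idx] = 1.0 - eps
    pi = np.array([[1.0 - eps, eps], [eps, 1.0 - eps]])
    if eps == 0.0:                      # avoid log(0); indicator fully observed
        pi = np.array([[1.0 - 1e-12, 1e-12], [1e-12, 1.0 - 1e-12]])

    def m_step(resp_: np.ndarray):
        init = np.full((2, S), alpha)
        trans = np.full((2, S, S), alpha)
        for i, seq in enumerate(seqs):
            for c in range(2):
                r = resp_[i, c]
                init[c, seq[0]] += r
                for a, b in zip(seq[:-1], seq[1:]):
                    trans[c, a, b] += r
        init /= init.sum(axis=1, keepdims=True)
        trans /= trans.sum(axis=2, keepdims=True)
        return init, trans

    def seq_loglik(init, trans, seq) -> np.ndarray:
        ll = np.log(init[:, seq[0]]).copy()
        for a, b in zip(seq[:-1], seq[1:]):
            ll += np.log(trans[:, a, b])
        return ll

    trajectory: list[float] = []
    objective: list[float] = []
    init, trans = m_step(resp)
    for _ in range(max_iter):
        comp_ll = np.array([seq_loglik(init, trans, s) for s in seqs])  # (n, 2)
        joint = comp_ll + np.log(pi[label_idx])
        mx = joint.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(joint - mx).sum(axis=1))
        trajectory.append(float(lse.sum()))
        # the quantity EM ascends under Dirichlet(alpha+1) smoothing is the
        # log posterior: log likelihood + alpha * sum(log parameters)
        penalty = alpha * (np.log(init).sum() + np.log(trans).sum())
        objective.append(float(lse.sum() + penalty))
        resp = np.exp(joint - lse[:, None])
        init, trans = m_step(resp)
        if len(objective) >= 2 and abs(objective[-1] - objective[-2]) < tol:
            break

    label_freq = np.bincount(label_idx, minlength=2) / n
    mixture = label_freq @ pi                     # marginal component weights
    model = PathClassifierModel(states=states, initial=init, transition=trans,
                                mixture=mixture, loglik_trajectory=trajectory,
                                objective_trajectory=objective)
    # majority-posterior component-condition assignment
    post = np.vstack([model.posterior(p.reactions) for p in paths])
    mean_c0 = {c: post[np.array(labels) == c, 0].mean() for c in conditions}
    if mean_c0[conditions[0]] >= mean_c0[conditions[1]]:
        model.component_condition = {0: conditions[0], 1: conditions[1]}
    else:
        model.component_condition = {0: conditions[1], 1: conditions[0]}
    return model


def classify_paths(model: PathClassifierModel, paths: list[MetabolicPath],
                   labels: list[str]) -> dict:
    """ROC analysis of per-path component posteriors against true labels.

    The score of a path is the posterior of the component assigned to the
    positive condition (the condition of component 0). Per-component ROC
    curves are reported as well — the component associated with the other
    condition yields an AUC below 0.5 by construction.
    """
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {uniq}")
    pos = model.component_condition[0]
    y = np.array([1 if lab == pos else 0 for lab in labels])
    post = np.vstack([model.posterior(p.reactions) for p in paths])

    fpr, tpr, thr = roc_curve(y, post[:, 0])
    out = {
        "positive_condition": pos,
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                "thresholds": thr.tolist()},
        "components": {},
    }
    for c, name in ((0, "M1"), (1, "M2")):
        f, t, _ = roc_curve(y, post[:, c])
        out["components"][name] = {
            "condition": model.component_condition[c],
            "auc": float(_trapezoid_auc(f, t)),
        }
    return out


# ---------------------------------------------------------------- subnetwork
def extract_subnetwork(paths_a: list[MetabolicPath],
                       paths_b: list[MetabolicPath]) -> nx.DiGraph:
    """Union of path edges, labeled exclusive-A / exclusive-B / shared.

    Conditions are taken from the paths themselves; node and edge counts
    are stored in ``graph.graph['counts']``.
    """
    def edge_set(paths):
        return {e for p in paths for e in p.edges}

    cond_a = paths_a[0].condition if paths_a else "A"
    cond_b = paths_b[0].condition if paths_b else "B"
    ea, eb = edge_set(paths_a), edge_set(paths_b)
    g = nx.DiGraph()
    for u, v in ea | eb:
        if (u, v) in ea and (u, v) in eb:
            lab = "shared"
        elif (u, v) in ea:
            lab = f"exclusive-{cond_a}"
        else:
            lab = f"exclusive-{cond_b}"
        g.add_edge(u, v, label=lab)
    counts = {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        f"exclusive_{cond_a}": sum(1 for *_, d in g.edges(data=True)
                                   if d["label"] == f"exclusive-{cond_a}"),
        f"exclusive_{cond_b}": sum(1 for *_, d in g.edges(data=True)
                                   if d["label"] == f"exclusive-{cond_b}"),
        "shared": sum(1 for *_, d in g.edges(data=True) if d["label"] == "shared"),
        "shared_nodes": len({n for e in (ea & eb) for n in e}),
    }
    g.graph["counts"] = counts
    g.graph["conditions"] = (cond_a, cond_b)
    return g


def project_differential(subnetwork: nx.DiGraph, diff: pd.DataFrame,
                         gene_map: dict[str, list[str]]) -> nx.DiGraph:
    """Annotate reaction nodes with protein-level regulation.

    ``gene_map`` maps reaction id -> gene ids; genes map into the
    differential table's index. Each node takes the direction of its
    best-covered significant feature (maximum |logFC| among significant
    mapped features), else ``undetected``. The covered-node fraction is
    stored in ``graph.graph['coverage']``.
    """
    g = subnetwork.copy()
    sig_col = "significant_raw" if "significant_raw" in diff.columns else None
    covered = 0
    for node in g.nodes:
        feats = [f for f in gene_map.get(node, []) if f in diff.index]
        status, best = "undetected", 0.0
        for f in feats:
            row = diff.loc[f]
            significant = bool(row[sig_col]) if sig_col else True
            lfc = float(row["logFC"])
            if significant and abs(lfc) > abs(best):
                best = lfc
                status = "up" if lfc > 0 else "down"
        g.nodes[node]["regulation"] = status
        g.nodes[node]["logFC"] = best if status != "undetected" else None
        covered += status != "undetected"
    g.graph["coverage"] = covered / max(g.number_of_nodes(), 1)
    return g


# ------------------------------------------------------------------- export
def write_paths_tsv(paths: list[MetabolicPath], path) -> None:
    rows = [{"rank": i + 1, "condition": p.condition, "score": p.score,
             "length": p.length, "node_sequence": ">".join(p.reactions)}
            for i, p in enumerate(paths)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sif(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{data.get('label', 'rr')}\t{v}\n")


def write_graphml(g: nx.DiGraph, path) -> None:
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    for n, data in g.nodes(data=True):
        for k, v in data.items():
            if isinstance(v, (str, int, float, bool)):
                h.nodes[n][k] = v
    for u, v, data in g.edges(data=True):
        h.add_edge(u, v, **{k: v2 for k, v2 in data.items()
                            if isinstance(v2, (str, int, float, bool))})
    nx.write_graphml(h, path)
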