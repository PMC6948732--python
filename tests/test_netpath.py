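"""Reaction-graph construction, edge weighting, path mining and the
Markov-mixture path classifier."""

import numpy as np
import pandas as pd
import pytest

from mmomics.netpath import (MetabolicNetwork, MetabolicPath,
                             build_reaction_graph, classify_paths,
                             extract_subnetwork, extract_top_paths,
                             project_differential, train_path_classifier,
                             weight_edges)
from mmomics.synthetic import (CohortDesign, generate_expression_for_paths,
                               generate_toy_network)


def _net(reactions, ubiquitous=()):
    mets = sorted({m for r in reactions for m in r[1] + r[2]})
    return MetabolicNetwork(
        reactions=[{"id": rid, "substrates": list(s), "products": list(p),
                    "genes": [f"g_{rid}"]} for rid, s, p in reactions],
        metabolites=[{"id": m, "ubiquitous": m in ubiquitous} for m in mets])


def _chain_graph(n, weight=0.5, group="G"):
    """Reaction chain r1 -> ... -> rn with uniform weights."""
    reactions = []
    for i in range(n):
        subs = [f"m{i}"] if i > 0 else [f"start"]
        prods = [f"m{i + 1}"] if i < n - 1 else ["end"]
        reactions.append((f"r{i + 1}", subs, prods))
    g = build_reaction_graph(_net(reactions))
    for u, v, data in g.edges(data=True):
        data["weights"][group] = weight
        data["unmeasured"][group] = False
    return g


class TestBuildReactionGraph:
    def test_shared_metabolite_creates_directed_edge(self):
        g = build_reaction_graph(_net([("r1", ["a"], ["m"]), ("r2", ["m"], ["b"])]))
        assert list(g.edges) == [("r1", "r2")]

    def test_ubiquitous_metabolite_forms_no_edge(self):
        g = build_reaction_graph(
            _net([("r1", ["a"], ["m"]), ("r2", ["m"], ["b"])], ubiquitous={"m"}))
        assert list(g.edges) == []

    def test_extra_ubiquitous_list_respected(self):
        net = _net([("r1", ["a"], ["m"]), ("r2", ["m"], ["b"])])
        g = build_reaction_graph(net, extra_ubiquitous=["m"])
        assert list(g.edges) == []

    def test_no_self_edges(self):
        g = build_reaction_graph(_net([("r1", ["m"], ["m"])]))
        assert list(g.edges) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_adjacency(self, seed):
        net, _ = generate_toy_network(n_reactions=20, n_metabolites=40,
                                      n_genes=20, ubiquitous_fraction=0.3,
                                      seed=seed, n_chains=1, chain_length=9)
        g = build_reaction_graph(net)
        ubiq = net.ubiquitous
        expected = set()
        for r1 in net.reactions:             # quadratic re-statement of the rule
            for r2 in net.reactions:
                if r1["id"] == r2["id"]:
                    continue
                shared = (set(r1["products"]) - ubiq) & set(r2["substrates"])
                if shared:
                    expected.add((r1["id"], r2["id"]))
        assert set(g.edges) == expected

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ValueError, match="unknown metabolites"):
            MetabolicNetwork(
                reactions=[{"id": "r", "substrates": ["x"], "products": [],
                            "genes": []}],
                metabolites=[])


class TestWeightEdges:
    def test_identical_expression_gives_weight_one(self):
        net = _net([("r1", ["a"], ["m"]), ("r2", ["m"], ["b"])])
        g = build_reaction_graph(net)
        row = np.random.default_rng(0).normal(0, 1, 6)
        expr = pd.DataFrame([row, row], index=["g_r1", "g_r2"],
                            columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        g = weight_edges(g, expr, groups)
        assert g["r1"]["r2"]["weights"]["A"] == pytest.approx(1.0)
        assert g["r1"]["r2"]["weights"]["B"] == pytest.approx(1.0)

    def test_unmeasured_reaction_gets_group_median_and_flag(self):
        net = _net([("r1", ["a"], ["m"]), ("r2", ["m"], ["n"]),
                    ("r3", ["n"], ["b"])])
        g = build_reaction_graph(net)
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (2, 8)), index=["g_r1", "g_r2"],
                            columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        g = weight_edges(g, expr, groups)
        assert g["r2"]["r3"]["unmeasured"]["A"]
        assert g["r2"]["r3"]["weights"]["A"] == g["r1"]["r2"]["weights"]["A"]

    def test_small_group_rejected(self):
        net = _net([("r1", ["a"], ["m"]), ("r2", ["m"], ["b"])])
        g = build_reaction_graph(net)
        expr = pd.DataFrame(np.ones((2, 4)), index=["g_r1", "g_r2"],
                            columns=[f"s{i}" for i in range(4)])
        groups = {"s0": "A", "s1": "A", "s2": "A", "s3": "B"}
        with pytest.raises(ValueError, match="need >= 3"):
            weight_edges(g, expr, groups)

    def test_independent_noise_keeps_weights_small(self):
        rng = np.random.default_rng(2)
        reactions = [(f"r{i}", [f"m{i}"], [f"m{i + 1}"]) for i in range(10)]
        net = _net(reactions)
        g = build_reaction_graph(net)
        expr = pd.DataFrame(rng.normal(0, 1, (10, 120)),
                            index=[f"g_r{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(120)])
        groups = {f"s{i}": "A" if i < 60 else "B" for i in range(120)}
        g = weight_edges(g, expr, groups)
        weights = [abs(d["weights"]["A"]) for *_, d in g.edges(data=True)]
        assert np.mean([w < 0.5 for w in weights]) >= 0.95


class TestExtractTopPaths:
    def test_single_chain_of_seven_reactions_is_unique_path(self):
        g = _chain_graph(7)
        paths = extract_top_paths(g, "G", k=50, min_length=6)
        assert len(paths) == 1
        assert paths[0].reactions == [f"r{i}" for i in range(1, 8)]
        assert paths[0].length == 6
        assert paths[0].score == pytest.approx(0.5)

    def test_chain_of_six_reactions_excluded_by_min_length(self):
        g = _chain_graph(6)
        with pytest.warns(UserWarning, match="no simple path"):
            assert extract_top_paths(g, "G", min_length=6) == []

    def test_missing_group_weights_error(self):
        g = _chain_graph(7)
        with pytest.raises(ValueError, match="no weights"):
            extract_top_paths(g, "other")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        import networkx as nx
        g = nx.gnp_random_graph(12, 0.25, seed=seed, directed=True)
        g = nx.relabel_nodes(g, {i: f"r{i}" for i in range(12)})
        for u, v, data in g.edges(data=True):
            data["weights"] = {"G": float(rng.uniform(-1, 1))}
            data["unmeasured"] = {"G": False}
        k, min_len, max_len = 8, 3, 6
        got = extract_top_paths(g, "G", k=k, min_length=min_len,
                                max_length=max_len)
        # oracle: recursive enumeration with the same endpoint rule
        sources = [n for n in g if g.in_degree(n) == 0] or list(g)
        sinks = set(n for n in g if g.out_degree(n) == 0) or set(g)
        all_paths = []

        def recurse(path):
            if len(path) - 1 >= min_len and path[-1] in sinks:
                w = [g[a][b]["weights"]["G"]
                     for a, b in zip(path[:-1], path[1:])]
                all_paths.append((sum(w) / len(w), list(path)))
            if len(path) - 1 >= max_len:
                return
            for nxt in g.successors(path[-1]):
                if nxt not in path:
                    recurse(path + [nxt])

        for s in sources:
            recurse([s])
        all_paths.sort(key=lambda sp: (-sp[0], sp[1]))
        expected = [(pytest.approx(sc), nodes) for sc, nodes in all_paths[:k]]
        assert [(p.score, p.reactions) for p in got] == expected


def _mk_paths(seqs, condition):
    return [MetabolicPath(reactions=list(s), score=0.0, condition=condition)
            for s in seqs]


class TestPathClassifier:
    def _disjoint_training(self):
        a = _mk_paths([["a1", "a2", "a3", "a4"], ["a2", "a3", "a4", "a5"],
                       ["a1", "a3", "a4", "a5"], ["a1", "a2", "a4", "a5"],
                       ["a1", "a2", "a3", "a5"]], "A")
        b = _mk_paths([["b1", "b2", "b3", "b4"], ["b2", "b3", "b4", "b5"],
                       ["b1", "b3", "b4", "b5"], ["b1", "b2", "b4", "b5"],
                       ["b1", "b2", "b3", "b5"]], "B")
        return {"A": a, "B": b}

    def test_em_objective_monotone(self):
        model = train_path_classifier(self._disjoint_training(), seed=0)
        diffs = np.diff(model.objective_trajectory)
        assert (diffs >= -1e-7).all()

    def test_determinism(self):
        m1 = train_path_classifier(self._disjoint_training(), seed=0)
        m2 = train_path_classifier(self._disjoint_training(), seed=0)
        np.testing.assert_array_equal(m1.transition, m2.transition)
        np.testing.assert_array_equal(m1.initial, m2.initial)

    def test_transition_rows_and_mixture_normalized(self):
        model = train_path_classifier(self._disjoint_training(), seed=0)
        np.testing.assert_allclose(model.transition.sum(axis=2), 1.0, atol=1e-9)
        assert model.mixture.sum() == pytest.approx(1.0)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match="two conditions"):
            train_path_classifier({"A": self._disjoint_training()["A"]})

    def test_too_few_paths_rejected(self):
        tr = self._disjoint_training()
        with pytest.raises(ValueError, match="need >= 5"):
            train_path_classifier({"A": tr["A"][:2], "B": tr["B"]})

    def test_null_paths_give_posteriors_near_half(self):
        rng = np.random.default_rng(3)
        states = [f"s{i}" for i in range(12)]

        def walk():
            while True:
                seq = [int(rng.integers(0, 12))]
                for _ in range(7):
                    seq.append((seq[-1] + int(rng.integers(1, 3))) % 12)
                if len(set(seq)) == len(seq):
                    return [states[i] for i in seq]

        train = {"A": _mk_paths([walk() for _ in range(30)], "A"),
                 "B": _mk_paths([walk() for _ in range(30)], "B")}
        model = train_path_classifier(train, seed=0)
        held = [walk() for _ in range(60)]
        post = np.array([model.posterior(p)[0] for p in held])
        assert abs(post.mean() - 0.5) < 0.1

    def test_separated_conditions_give_perfect_auc(self):
        train = self._disjoint_training()
        model = train_path_classifier(train, seed=0)
        paths = train["A"] + train["B"]
        labels = ["A"] * 5 + ["B"] * 5
        roc = classify_paths(model, paths, labels)
        assert roc["auc"] == pytest.approx(1.0)
        # per-component readout: one component tracks each condition
        aucs = sorted(v["auc"] for v in roc["components"].values())
        assert aucs[0] == pytest.approx(0.0) and aucs[1] == pytest.approx(1.0)

    def test_label_shuffled_auc_near_half(self):
        rng = np.random.default_rng(5)
        train = self._disjoint_training()
        model = train_path_classifier(train, seed=0)
        paths = train["A"] + train["B"]
        aucs = []
        for _ in range(20):
            labels = list(rng.permutation(["A"] * 5 + ["B"] * 5))
            aucs.append(classify_paths(model, paths, labels)["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_labels_rejected(self):
        train = self._disjoint_training()
        model = train_path_classifier(train, seed=0)
        with pytest.raises(ValueError, match="two classes"):
            classify_paths(model, train["A"], ["A"] * 5)


class TestSubnetworkAndProjection:
    def test_edge_label_set_arithmetic(self):
        a = _mk_paths([["e1a", "e1b", "e2b"], ["e3a", "e3b"]], "A")
        # edges A: (e1a,e1b),(e1b,e2b),(e3a,e3b)
        b = _mk_paths([["e3a", "e3b"], ["e4a", "e4b"]], "B")
        g = extract_subnetwork(a, b)
        labels = {(u, v): d["label"] for u, v, d in g.edges(data=True)}
        assert labels[("e1a", "e1b")] == "exclusive-A"
        assert labels[("e1b", "e2b")] == "exclusive-A"
        assert labels[("e3a", "e3b")] == "shared"
        assert labels[("e4a", "e4b")] == "exclusive-B"
        counts = g.graph["counts"]
        assert counts["exclusive_A"] == 2 and counts["exclusive_B"] == 1
        assert counts["shared"] == 1

    def test_disjoint_paths_share_nothing(self):
        a = _mk_paths([["x1", "x2", "x3"]], "A")
        b = _mk_paths([["y1", "y2", "y3"]], "B")
        assert extract_subnetwork(a, b).graph["counts"]["shared"] == 0

    def test_identical_paths_all_shared(self):
        a = _mk_paths([["x1", "x2", "x3"]], "A")
        b = _mk_paths([["x1", "x2", "x3"]], "B")
        g = extract_subnetwork(a, b)
        assert all(d["label"] == "shared" for *_, d in g.edges(data=True))

    def test_labels_partition_edge_union(self):
        a = _mk_paths([["x1", "x2", "x3", "x4"]], "A")
        b = _mk_paths([["x2", "x3", "x4", "x5"]], "B")
        g = extract_subnetwork(a, b)
        n = g.graph["counts"]
        assert n["exclusive_A"] + n["exclusive_B"] + n["shared"] == n["edges"]

    def test_projection_annotates_up_down_undetected(self):
        a = _mk_paths([["r1", "r2", "r3"]], "A")
        g = extract_subnetwork(a, _mk_paths([["r1", "r2"]], "B"))
        diff = pd.DataFrame({"logFC": [2.0, -1.0], "significant_raw": [True, True]},
                            index=["gA", "gB"])
        out = project_differential(g, diff, {"r1": ["gA"], "r2": ["gB"]})
        assert out.nodes["r1"]["regulation"] == "up"
        assert out.nodes["r2"]["regulation"] == "down"
        assert out.nodes["r3"]["regulation"] == "undetected"
        assert out.graph["coverage"] == pytest.approx(2 / 3)

    def test_no_mapped_features_all_undetected(self):
        a = _mk_paths([["r1", "r2", "r3"]], "A")
        g = extract_subnetwork(a, _mk_paths([["r1", "r2"]], "B"))
        diff = pd.DataFrame({"logFC": [2.0], "significant_raw": [True]},
                            index=["gZ"])
        out = project_differential(g, diff, {})
        assert all(out.nodes[n]["regulation"] == "undetected" for n in out.nodes)


class TestPlantedPathRecovery:
    def test_group_exclusive_weights_and_classifier_auc(self):
        net, paths = generate_toy_network(n_reactions=50, n_metabolites=90,
                                          n_genes=60, ubiquitous_fraction=0.2,
                                          seed=7, n_chains=4, chain_length=9)
        design = CohortDesign.from_counts({"RRMM": 60, "NDMM": 60})
        active = {"RRMM": ["path_1", "path_2"], "NDMM": ["path_3", "path_4"]}
        expr, _ = generate_expression_for_paths(net, paths, design, active,
                                                correlation=0.9, seed=7)
        g = weight_edges(build_reaction_graph(net), expr, design.group_of)
        chain = paths["path_1"]
        on_path = [g[a][b]["weights"] for a, b in zip(chain[:-1], chain[1:])]
        diff = np.mean([w["RRMM"] - w["NDMM"] for w in on_path])
        assert diff > 0.5
        top = {lab: extract_top_paths(g, lab, k=10, min_length=6, max_length=10)
               for lab in ("RRMM", "NDMM")}
        for lab in top:
            planted = set().union(*[paths[p] for p in active[lab]])
            frac = np.mean([len(set(p.reactions) & planted) / len(p.reactions)
                            >= 0.5 for p in top[lab]])
            assert frac >= 0.8
        model = train_path_classifier(top, seed=7)
        all_paths = top["RRMM"] + top["NDMM"]
        labels = ["RRMM"] * len(top["RRMM"]) + ["NDMM"] * len(top["NDMM"])
        assert classify_paths(model, all_paths, labels)["auc"] >= 0.95
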