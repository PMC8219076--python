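"""Bipartite classification, Spearman edge filtering, graph metrics, modules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from _oracles import (
    oracle_betweenness,
    oracle_clustering,
    oracle_modularity,
    oracle_path_metrics,
    oracle_spearman,
    oracle_transitivity,
)

from otukit import (
    ENV_CLUSTERS,
    SynthConfig,
    assign_environment_labels,
    build_bipartite,
    build_conet,
    classify_env_clusters,
    detect_modules,
    filter_edges,
    generate_community,
    graph_metrics,
    habitat_sharing,
    hub_ranking,
    node_prefilter,
    planted_edge_set,
    relative_abundance,
    spearman_matrix,
    summarize_env_clusters,
)


def info_frame(habitats_modes):
    idx, hab, mode = [], [], []
    for i, (h, m) in enumerate(habitats_modes):
        idx.append(f"s{i}")
        hab.append(h)
        mode.append(m)
    return pd.DataFrame(
        {"habitat": hab, "mode": mode, "replicate": 1},
        index=pd.Index(idx, name="sample_id"),
    )


class TestBipartite:
    def six_group_setup(self):
        info = info_frame(
            [(h, m) for m in ("MC", "RC") for h in ("water", "sediment", "intestine")]
        )
        table = pd.DataFrame(
            {
                # gA everywhere, gB water only, gC below the read cutoff,
                # gD intestine+sediment, gE sediment only
                "s0": [10, 6, 2, 0, 0],
                "s1": [10, 0, 0, 3, 9],
                "s2": [10, 0, 1, 4, 0],
                "s3": [10, 7, 0, 0, 0],
                "s4": [10, 0, 1, 0, 2],
                "s5": [10, 0, 0, 5, 0],
            },
            index=["gA", "gB", "gC", "gD", "gE"],
        )
        return table, info

    def test_read_cutoff_excludes(self):
        table, info = self.six_group_setup()
        net = build_bipartite(table, info, min_total_reads=5)
        genera = {n for n, d in net.nodes(data=True) if d.get("bipartite") == 0}
        assert "gC" not in genera  # 4 total reads
        assert genera == {"gA", "gB", "gD", "gE"}

    def test_ubiquitous_genus_links_all_six_groups(self):
        table, info = self.six_group_setup()
        net = build_bipartite(table, info)
        assert net.degree("gA") == 6

    def test_edge_set_matches_manual_enumeration(self):
        table, info = self.six_group_setup()
        net = build_bipartite(table, info)
        expected = {
            ("gA", g) for g in
            ("MC-water", "MC-sediment", "MC-intestine", "RC-water", "RC-sediment", "RC-intestine")
        } | {
            ("gB", "MC-water"), ("gB", "RC-water"),
            ("gD", "MC-sediment"), ("gD", "MC-intestine"), ("gD", "RC-intestine"),
            ("gE", "MC-sediment"), ("gE", "RC-sediment"),
        }
        got = {tuple(sorted(e, key=lambda x: (x not in table.index, x))) for e in net.edges}
        got = {(g, grp) if g in table.index else (grp, g) for g, grp in got}
        assert got == expected

    def test_empty_after_filter(self):
        table, info = self.six_group_setup()
        with pytest.raises(ValueError):
            build_bipartite(table, info, min_total_reads=10_000)


class TestEnvClusters:
    def test_seven_way_mapping_is_total(self):
        habs = ["water", "sediment", "intestine"]
        sets = [frozenset(c) for n in (1, 2, 3) for c in itertools.combinations(habs, n)]
        assert sorted(ENV_CLUSTERS[s] for s in sets) == [1, 2, 3, 4, 5, 6, 7]

    def test_classification_from_graph(self):
        table, info = TestBipartite().six_group_setup()
        net = build_bipartite(table, info)
        assignment, summary = classify_env_clusters(net)
        assert assignment == {"gA": 3, "gB": 6, "gD": 4, "gE": 7}
        assert summary.one_env_count == 2
        assert summary.two_env_count == 1
        assert summary.three_env_count == 1
        assert summary.one_env_pct + summary.two_env_pct + summary.three_env_pct == 100.0

    def test_all_shared_is_all_cluster_three(self):
        info = info_frame(
            [(h, "MC") for h in ("water", "sediment", "intestine")]
        )
        table = pd.DataFrame(
            np.full((4, 3), 5), index=list("wxyz"), columns=info.index
        )
        _, summary = classify_env_clusters(build_bipartite(table, info))
        assert summary.three_env_pct == 100.0 and summary.one_env_pct == 0.0

    def test_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(0)
        assignment = {f"g{i}": int(rng.integers(1, 8)) for i in range(337)}
        s = summarize_env_clusters(assignment)
        assert abs(s.one_env_pct + s.two_env_pct + s.three_env_pct - 100.0) <= 0.02

    def test_habitat_sharing_counts(self):
        # intestine set = clusters {1,2,3,4}
        assignment = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 6}
        out = habitat_sharing(assignment, "intestine")
        assert out["total"] == 4
        assert out["unique_count"] == 1
        assert out["shared_with_water_count"] == 2  # clusters 2 and 3
        assert out["shared_with_sediment_count"] == 2  # clusters 3 and 4
        assert out["shared_all_count"] == 1


class TestSpearman:
    def test_monotone_pairs(self):
        rel = pd.DataFrame(
            {"s1": [1, 9], "s2": [2, 6], "s3": [3, 4], "s4": [4, 2]},
            index=["up", "down"],
        ).pipe(lambda d: d / d.sum())
        rho, p, flagged = spearman_matrix(rel)
        assert rho.at["up", "down"] == pytest.approx(-1.0)
        assert p.at["up", "down"] == pytest.approx(0.0)
        assert not flagged

    def test_tied_data_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 3, 5], [1, 3, 2, 4, 4]
        rel = pd.DataFrame(
            np.array([x, y], dtype=float), index=["x", "y"],
            columns=[f"s{i}" for i in range(5)],
        )
        rho, _, _ = spearman_matrix(rel)
        assert rho.at["x", "y"] == pytest.approx(oracle_spearman(x, y))

    def test_constant_taxon_flagged_and_excluded(self):
        rel = pd.DataFrame(
            {"s1": [1, 2, 3], "s2": [1, 3, 2], "s3": [1, 4, 5], "s4": [1, 5, 4]},
            index=["const", "a", "b"], dtype=float,
        )
        rho, _, flagged = spearman_matrix(rel)
        assert flagged == ["const"]
        assert list(rho.index) == ["a", "b"]

    def test_too_few_samples(self):
        rel = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0], "s3": [3.0, 0.5]})
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(rel)


class TestFilterEdges:
    def frames(self, rho_vals, p_vals):
        taxa = [f"t{i}" for i in range(len(rho_vals))]
        return (
            pd.DataFrame(rho_vals, index=taxa, columns=taxa),
            pd.DataFrame(p_vals, index=taxa, columns=taxa),
        )

    def test_threshold_inclusive_rho_strict_p(self):
        rho, p = self.frames(
            [[1.0, 0.75, 0.80], [0.75, 1.0, 0.5], [0.80, 0.5, 1.0]],
            [[0.0, 0.04, 0.06], [0.04, 0.0, 0.2], [0.06, 0.2, 0.0]],
        )
        edges = filter_edges(rho, p)
        assert [(u, v) for u, v, *_ in edges] == [("t0", "t1")]  # 0.80/p=0.06 dropped

    def test_absolute_mode_keeps_negative(self):
        rho, p = self.frames([[1.0, -0.9], [-0.9, 1.0]], [[0.0, 0.01], [0.01, 0.0]])
        assert filter_edges(rho, p, mode="positive") == []
        assert len(filter_edges(rho, p, mode="absolute")) == 1

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(7)
        rel = pd.DataFrame(
            rng.dirichlet(np.ones(12), size=10).T,
            index=[f"t{i}" for i in range(12)],
        )
        rho, p, _ = spearman_matrix(rel)
        loose = {(u, v) for u, v, *_ in filter_edges(rho, p, rho_min=0.2, alpha=0.5)}
        strict = {(u, v) for u, v, *_ in filter_edges(rho, p, rho_min=0.2, alpha=0.05)}
        assert strict <= loose


def nx_graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


class TestGraphMetrics:
    def test_triangle(self):
        g = nx_graph([("a", "b"), ("b", "c"), ("a", "c")])
        m = graph_metrics(g)
        assert m.transitivity == 1.0 and m.avg_clustering == 1.0
        assert m.diameter == 1 and all(g.nodes[n]["betweenness"] == 0 for n in g)

    def test_path(self):
        g = nx_graph([("a", "b"), ("b", "c")])
        m = graph_metrics(g)
        assert g.nodes["b"]["betweenness"] == 1.0
        assert m.transitivity == 0.0 and m.diameter == 2
        assert m.avg_path_length == pytest.approx(4 / 3)

    def test_star_center_betweenness(self):
        g = nx_graph([("c", f"l{i}") for i in range(4)])
        graph_metrics(g)
        assert g.nodes["c"]["betweenness"] == 6.0  # C(4,2)

    def test_random_graphs_match_oracles(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            m = graph_metrics(g)
            nodes, edges = list(g.nodes), list(g.edges)
            bc = oracle_betweenness(nodes, edges)
            cl = oracle_clustering(nodes, edges)
            for n in nodes:
                assert g.nodes[n]["betweenness"] == pytest.approx(bc[n])
                assert g.nodes[n]["clustering"] == pytest.approx(cl[n])
            assert m.transitivity == pytest.approx(oracle_transitivity(nodes, edges))
            diam, apl = oracle_path_metrics(nodes, edges)
            assert m.diameter == diam
            assert m.avg_path_length == pytest.approx(apl)

    def test_edge_count_is_half_degree_sum(self, default_community):
        table, tax, info, _ = default_community
        rel = relative_abundance(table)
        rho, p, _ = spearman_matrix(rel, node_prefilter(table))
        g = build_conet(filter_edges(rho, p))
        m = graph_metrics(g)
        assert m.n_edges == sum(d for _, d in g.degree) / 2


class TestModules:
    def test_two_disconnected_triangles(self):
        g = nx_graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        partition, q = detect_modules(g, seed=0)
        assert len(set(partition.values())) == 2
        assert q == pytest.approx(0.5)
        assert q == pytest.approx(
            oracle_modularity(list(g.nodes), list(g.edges), partition)
        )

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        partition, q = detect_modules(g, seed=0)
        assert len(set(partition.values())) == 1
        assert q == pytest.approx(0.0)

    def test_q_beats_singletons(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = nx.gnp_random_graph(15, 0.2, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            partition, q = detect_modules(g, seed=1)
            singles = {n: i for i, n in enumerate(g.nodes)}
            q_single = oracle_modularity(list(g.nodes), list(g.edges), singles)
            assert q >= q_single - 1e-12

    def test_planted_modules_recovered(self):
        # the dedicated acceptance sweep runs 20 seeds; one seed here
        from sklearn.metrics import adjusted_rand_score

        cfg = SynthConfig(n_replicates_per_group=5, seed=3)
        table, _, info, truth = generate_community(cfg)
        rel = relative_abundance(table)
        rho, p, _ = spearman_matrix(rel, node_prefilter(table))
        g = build_conet(filter_edges(rho, p))
        partition, _ = detect_modules(g, seed=3)
        scored = [n for n in partition if truth.module_membership[n] >= 0]
        ari = adjusted_rand_score(
            [truth.module_membership[n] for n in scored],
            [partition[n] for n in scored],
        )
        assert ari >= 0.8


class TestEnvironmentLabels:
    def test_sediment_only_genus(self, default_community):
        table, _, info, truth = default_community
        g = nx.Graph()
        sig = [t for t, h in truth.signature_habitat.items() if h == "sediment"][:5]
        g.add_nodes_from(sig)
        node_env, _, ties = assign_environment_labels(g, table, info)
        assert all(node_env[t] == "sediment" for t in sig)

    def test_uniform_genus_tie_flagged_water(self):
        info = info_frame([(h, "MC") for h in ("water", "sediment", "intestine")])
        table = pd.DataFrame({"s0": [4, 1], "s1": [4, 1], "s2": [4, 1]}, index=["u", "v"])
        g = nx.Graph()
        g.add_edge("u", "v")
        node_env, _, ties = assign_environment_labels(g, table, info)
        assert node_env["u"] == "water" and "u" in ties

    def test_module_majority_vote(self, default_community):
        table, _, info, truth = default_community
        rel = relative_abundance(table)
        rho, p, _ = spearman_matrix(rel, node_prefilter(table))
        g = build_conet(filter_edges(rho, p))
        partition, _ = detect_modules(g, seed=0)
        node_env, module_env, _ = assign_environment_labels(g, table, info, partition)
        # signature taxa should carry their home habitat label
        sig_nodes = [n for n in g if truth.signature_habitat[n] != "shared"]
        hits = sum(node_env[n] == truth.signature_habitat[n] for n in sig_nodes)
        assert hits / len(sig_nodes) >= 0.95
        assert set(module_env.values()) <= {"water", "sediment", "intestine"}


class TestHubs:
    def test_star_center_first(self):
        g = nx_graph([("c", f"l{i}") for i in range(4)])
        graph_metrics(g)
        ranking = hub_ranking(g, 2)
        assert ranking[0][0] == "c" and ranking[0][3] == 6.0

    def test_cycle_falls_to_name_tiebreak(self):
        g = nx.cycle_graph(["d", "b", "a", "c"])
        graph_metrics(g)
        names = [n for n, *_ in hub_ranking(g, 4)]
        assert names == sorted(names)

    def test_k_larger_than_n(self):
        g = nx_graph([("a", "b")])
        graph_metrics(g)
        assert len(hub_ranking(g, 10)) == 2

    def test_metrics_required(self):
        g = nx_graph([("a", "b")])
        with pytest.raises(ValueError):
            hub_ranking(g, 1)


class TestPlantedEdges:
    def truth_for(self, sizes, shared, rho):
        cfg = SynthConfig(
            n_taxa_per_habitat_signature=sizes,
            n_shared_taxa=shared,
            within_module_latent_correlation=rho,
            seed=0,
        )
        return generate_community(cfg)[3]

    def test_three_blocks_of_five(self):
        truth = self.truth_for(5, 0, 0.9)
        assert len(planted_edge_set(truth, 0.75)) == 3 * 10  # 3 x C(5,2)

    def test_threshold_above_rho_gives_nothing(self):
        truth = self.truth_for(5, 0, 0.9)
        assert planted_edge_set(truth, 0.95) == []

    def test_single_block_exact_pairs(self):
        cfg = SynthConfig(
            n_taxa_per_habitat_signature={"water": 4, "sediment": 1, "intestine": 1},
            n_shared_taxa=4,
            n_modules=1,
            within_module_latent_correlation=0.8,
            seed=0,
        )
        truth = generate_community(cfg)[3]
        edges = planted_edge_set(truth, 0.75)
        assert len(edges) == 6
        members = {t for e in edges for t in e}
        assert all(truth.module_membership[t] == 0 for t in members)
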