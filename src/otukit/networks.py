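"""Genus-environment bipartite association and Spearman co-correlation networks.

Two complementary views of the community:

* a bipartite graph linking each genus to the sample groups it occurs in,
  summarised by a 7-way environment-cluster classification (one, two or all
  three of water / sediment / intestine);
* an undirected co-correlation graph over genera, with edges retained when
  the Spearman correlation of relative abundances is strong (rho >= 0.75 by
  default, positive mode) and significant (raw P < 0.05), plus graph-level
  metrics, Louvain modules and betweenness-centrality hubs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import HABITATS, relative_abundance

__all__ = [
    "build_bipartite",
    "ENV_CLUSTERS",
    "EnvClusterSummary",
    "summarize_env_clusters",
    "classify_env_clusters",
    "env_cluster_table",
    "habitat_sharing",
    "node_prefilter",
    "spearman_matrix",
    "filter_edges",
    "build_conet",
    "GraphMetrics",
    "graph_metrics",
    "detect_modules",
    "assign_environment_labels",
    "hub_ranking",
]


# ---------------------------------------------------------------------------
# bipartite genus-environment network
# ---------------------------------------------------------------------------

def build_bipartite(
    table: pd.DataFrame, info: pd.DataFrame, min_total_reads: int = 5
) -> nx.Graph:
    """Bipartite graph: genus nodes vs sample-group nodes (mode x habitat).

    Genera with fewer than ``min_total_reads`` total reads are dropped; an
    edge links a genus to a group when the genus has at least one read in at
    least one sample of that group.
    """
    totals = table.sum(axis=1)
    kept = totals.index[totals >= min_total_reads]
    if kept.empty:
        raise ValueError(
            f"no genus has >= {min_total_reads} total reads; nothing to build"
        )
    g = nx.Graph()
    groups = {}  # group id -> sample list
    for sid in table.columns:
        gid = f"{info.at[sid, 'mode']}-{info.at[sid, 'habitat']}"
        groups.setdefault(gid, []).append(sid)
    for gid, samples in groups.items():
        g.add_node(gid, bipartite=1, habitat=gid.split("-", 1)[1])
    for genus in kept:
        g.add_node(genus, bipartite=0, total_abundance=int(totals[genus]))
        row = table.loc[genus]
        for gid, samples in groups.items():
            if row[samples].sum() > 0:
                g.add_edge(genus, gid)
    isolated = [n for n, d in g.nodes(data=True) if d.get("bipartite") == 0 and g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    return g


#: fixed 7-way mapping from a genus's environment set to a cluster id
ENV_CLUSTERS: dict[frozenset[str], int] = {
    frozenset({"intestine"}): 1,
    frozenset({"intestine", "water"}): 2,
    frozenset({"water", "sediment", "intestine"}): 3,
    frozenset({"intestine", "sediment"}): 4,
    frozenset({"water", "sediment"}): 5,
    frozenset({"water"}): 6,
    frozenset({"sediment"}): 7,
}

#: clusters grouped by how many environments they span
ONE_ENV_CLUSTERS = (1, 6, 7)
TWO_ENV_CLUSTERS = (2, 4, 5)
THREE_ENV_CLUSTERS = (3,)


def _pct(x: float, total: float) -> float:
    return float(np.round(100.0 * x / total, 2))


@dataclass(frozen=True)
class EnvClusterSummary:
    n_genera: int
    cluster_counts: dict[int, int]
    one_env_count: int
    two_env_count: int
    three_env_count: int
    one_env_pct: float
    two_env_pct: float
    three_env_pct: float


def summarize_env_clusters(assignment: Mapping[str, int]) -> EnvClusterSummary:
    """Counts and percentages (2 decimals, round-half-even) of genera
    associated with one, two, or all three environments."""
    n = len(assignment)
    if n == 0:
        raise ValueError("empty cluster assignment")
    counts = {c: 0 for c in range(1, 8)}
    for c in assignment.values():
        counts[c] += 1
    one = sum(counts[c] for c in ONE_ENV_CLUSTERS)
    two = sum(counts[c] for c in TWO_ENV_CLUSTERS)
    three = sum(counts[c] for c in THREE_ENV_CLUSTERS)
    return EnvClusterSummary(
        n_genera=n,
        cluster_counts=counts,
        one_env_count=one,
        two_env_count=two,
        three_env_count=three,
        one_env_pct=_pct(one, n),
        two_env_pct=_pct(two, n),
        three_env_pct=_pct(three, n),
    )


def classify_env_clusters(
    net: nx.Graph, info: pd.DataFrame | None = None
) -> tuple[dict[str, int], EnvClusterSummary]:
    """Assign every genus node to its environment cluster (1..7).

    The environment set of a genus is the set of habitats of the group
    nodes it links to (MC/RC collapsed).  Returns the per-genus assignment
    and the :func:`summarize_env_clusters` summary.
    """
    assignment: dict[str, int] = {}
    for node, data in net.nodes(data=True):
        if data.get("bipartite") != 0:
            continue
        envs = frozenset(net.nodes[nb]["habitat"] for nb in net.neighbors(node))
        assignment[node] = ENV_CLUSTERS[envs]
    return assignment, summarize_env_clusters(assignment)


#: environment set realising each cluster id (inverse of ENV_CLUSTERS)
_CLUSTER_ENVS = {c: set(envs) for envs, c in ENV_CLUSTERS.items()}


def env_cluster_table(
    cluster_counts: Mapping[int, int], reads: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct a genus table + metadata realising given cluster counts.

    For each cluster id (1..7), ``cluster_counts[c]`` genera are created
    with ``reads`` reads in one sample of every habitat in that cluster's
    environment set.  Feeding the result through :func:`build_bipartite`
    and :func:`classify_env_clusters` reproduces the requested counts —
    used to turn published summary counts into a worked example.
    """
    info = pd.DataFrame(
        {
            "habitat": [h for h in HABITATS for _ in ("MC", "RC")],
            "mode": ["MC", "RC"] * len(HABITATS),
            "replicate": 1,
        },
        index=pd.Index([f"{m}-{h}" for h in HABITATS for m in ("MC", "RC")],
                       name="sample_id"),
    )
    rows, names = [], []
    for cluster, count in sorted(cluster_counts.items()):
        envs = _CLUSTER_ENVS[cluster]
        row = [reads if info.at[s, "habitat"] in envs and info.at[s, "mode"] == "MC" else 0
               for s in info.index]
        for i in range(count):
            names.append(f"c{cluster}_g{i:04d}")
            rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(names, name="taxon_id"),
                         columns=info.index, dtype=np.int64)
    return table, info


#: which clusters involve each habitat
_HABITAT_CLUSTERS = {
    "intestine": (1, 2, 3, 4),
    "water": (2, 3, 5, 6),
    "sediment": (3, 4, 5, 7),
}
_UNIQUE_CLUSTER = {"intestine": 1, "water": 6, "sediment": 7}


def habitat_sharing(assignment: Mapping[str, int], habitat: str) -> dict[str, float]:
    """Sharing profile of one habitat's genus set, as counts and percentages.

    E.g. for ``intestine``: how many of the intestine-associated genera are
    unique to the intestine, shared with water, shared with sediment, and
    shared among all three habitats.
    """
    if habitat not in HABITATS:
        raise ValueError(f"unknown habitat {habitat!r}")
    mine = [g for g, c in assignment.items() if c in _HABITAT_CLUSTERS[habitat]]
    total = len(mine)
    if total == 0:
        raise ValueError(f"no genera associated with {habitat!r}")
    out: dict[str, float] = {"total": total}
    unique = sum(1 for g in mine if assignment[g] == _UNIQUE_CLUSTER[habitat])
    out["unique_count"] = unique
    out["unique_pct"] = _pct(unique, total)
    for other in HABITATS:
        if other == habitat:
            continue
        shared_clusters = set(_HABITAT_CLUSTERS[habitat]) & set(_HABITAT_CLUSTERS[other])
        shared = sum(1 for g in mine if assignment[g] in shared_clusters)
        out[f"shared_with_{other}_count"] = shared
        out[f"shared_with_{other}_pct"] = _pct(shared, total)
    all_three = sum(1 for g in mine if assignment[g] == 3)
    out["shared_all_count"] = all_three
    out["shared_all_pct"] = _pct(all_three, total)
    return out


# ---------------------------------------------------------------------------
# Spearman co-correlation network
# ---------------------------------------------------------------------------

def node_prefilter(
    table: pd.DataFrame, top_n: int = 100, min_prevalence: int = 4
) -> list[str]:
    """Taxa eligible for the co-correlation network: the ``top_n`` most
    abundant (by total reads, ties by id) that occur in at least
    ``min_prevalence`` samples."""
    totals = table.sum(axis=1)
    prevalent = set(table.index[(table > 0).sum(axis=1) >= min_prevalence])
    ranked = sorted(table.index, key=lambda t: (-totals[t], t))
    return [t for t in ranked if t in prevalent][:top_n]


def spearman_matrix(
    rel: pd.DataFrame, taxa: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Spearman rho and two-sided p for a set of taxa.

    rho is Pearson on midranks (exact under ties); p comes from the
    t-approximation with n-2 df, with p = 0 at rho = +/-1.  Taxa with zero
    variance across samples have undefined rho; they are excluded and
    returned in the flagged list.
    """
    if taxa is None:
        taxa = list(rel.index)
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxa subset")
    data = rel.loc[taxa]
    if data.shape[1] < 4:
        raise ValueError("need at least 4 samples for Spearman correlations")
    constant = [t for t in taxa if data.loc[t].nunique() == 1]
    kept = [t for t in taxa if t not in constant]
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-constant taxa")
    sub = data.loc[kept].to_numpy()
    rho, p = stats.spearmanr(sub, axis=1)
    if np.isscalar(rho):  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    return (
        pd.DataFrame(rho, index=kept, columns=kept),
        pd.DataFrame(p, index=kept, columns=kept),
        constant,
    )


def filter_edges(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_min: float = 0.75,
    alpha: float = 0.05,
    mode: str = "positive",
) -> list[tuple[str, str, float, float]]:
    """Retain strong, significant correlations as undirected edges.

    ``mode="positive"`` keeps rho >= rho_min (inclusive); ``mode="absolute"``
    keeps |rho| >= rho_min.  Either way the p-filter is strict (p < alpha).
    Returns (u, v, rho, p) tuples with u < v.
    """
    if mode not in ("positive", "absolute"):
        raise ValueError(f"mode must be 'positive' or 'absolute', got {mode!r}")
    taxa = list(rho.index)
    edges = []
    r = rho.to_numpy()
    pv = p.to_numpy()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            val = r[i, j]
            strong = abs(val) >= rho_min if mode == "absolute" else val >= rho_min
            if strong and pv[i, j] < alpha:
                u, v = sorted((taxa[i], taxa[j]))
                edges.append((u, v, float(val), float(pv[i, j])))
    return edges


def build_conet(edges: Sequence[tuple[str, str, float, float]]) -> nx.Graph:
    """Co-correlation graph from filtered edges; isolated taxa are absent by
    construction (the node set is exactly the edge endpoints)."""
    g = nx.Graph()
    for u, v, rho, p in edges:
        g.add_edge(u, v, rho=rho, p=p)
    return g


@dataclass(frozen=True)
class GraphMetrics:
    n_nodes: int
    n_edges: int
    avg_clustering: float
    transitivity: float
    diameter: int
    avg_path_length: float


def graph_metrics(g: nx.Graph) -> GraphMetrics:
    """Global metrics; per-node degree/clustering/betweenness are stored as
    node attributes.

    Local clustering C_i = 2 T_i / (k_i (k_i - 1)), 0 for degree < 2;
    average clustering is the mean over all nodes.  Betweenness is Brandes,
    unnormalised, endpoints excluded.  Diameter and average path length are
    computed over the largest connected component.
    """
    if g.number_of_nodes() < 1:
        raise ValueError("empty graph")
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
        g.nodes[node]["clustering"] = clustering[node]
        g.nodes[node]["betweenness"] = betweenness[node]
    largest = max(nx.connected_components(g), key=len)
    sub = g.subgraph(largest)
    if sub.number_of_nodes() > 1:
        diameter = nx.diameter(sub)
        apl = nx.average_shortest_path_length(sub)
    else:
        diameter, apl = 0, 0.0
    return GraphMetrics(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        avg_clustering=float(np.mean(list(clustering.values()))),
        transitivity=float(nx.transitivity(g)),
        diameter=int(diameter),
        avg_path_length=float(apl),
    )


def detect_modules(
    g: nx.Graph, resolution: float = 1.0, seed: int | None = None
) -> tuple[dict[str, int], float]:
    """Louvain-style multilevel community detection with a fixed seed.

    Returns (node -> module id, modularity Q of the returned partition),
    Q = sum_c (e_c/m - (d_c/2m)^2).  Module ids are renumbered so that
    module 0 contains the lexicographically smallest node, etc.
    """
    if g.number_of_edges() < 1:
        raise ValueError("community detection needs at least one edge")
    comms = nx.algorithms.community.louvain_communities(
        g, resolution=resolution, seed=seed
    )
    q = nx.algorithms.community.modularity(g, comms)
    ordered = sorted(comms, key=lambda c: min(c))
    partition = {node: i for i, comm in enumerate(ordered) for node in comm}
    return partition, float(q)


def assign_environment_labels(
    g: nx.Graph,
    table: pd.DataFrame,
    info: pd.DataFrame,
    partition: Mapping[str, int] | None = None,
) -> tuple[dict[str, str], dict[int, str], list[str]]:
    """Label network nodes (and modules) with their dominant habitat.

    A node's label is the habitat where its mean relative abundance is
    maximal; exact ties fall back deterministically to the habitat order
    water < sediment < intestine and the node is flagged.  Module labels are
    the majority vote of member nodes (same tie order).  Results are stored
    as ``habitat`` (and ``module``) node attributes.
    """
    rel = relative_abundance(table)
    means = {}
    for hab in HABITATS:
        cols = info.index[info["habitat"] == hab].intersection(rel.columns)
        means[hab] = rel[cols].mean(axis=1)
    node_env: dict[str, str] = {}
    ties: list[str] = []
    for node in g.nodes:
        if node not in rel.index:
            raise KeyError(f"network node {node!r} absent from the count table")
        vals = {hab: means[hab][node] for hab in HABITATS}
        best = max(vals.values())
        winners = [hab for hab in HABITATS if vals[hab] == best]
        if len(winners) > 1:
            ties.append(node)
        node_env[node] = winners[0]
        g.nodes[node]["habitat"] = winners[0]
    module_env: dict[int, str] = {}
    if partition is not None:
        for mod in sorted(set(partition.values())):
            members = [n for n, m in partition.items() if m == mod]
            votes = {hab: sum(node_env[n] == hab for n in members) for hab in HABITATS}
            top = max(votes.values())
            module_env[mod] = next(hab for hab in HABITATS if votes[hab] == top)
        for node, mod in partition.items():
            g.nodes[node]["module"] = mod
    return node_env, module_env, ties


def hub_ranking(g: nx.Graph, k: int) -> list[tuple[str, int, float, float]]:
    """Top-k hubs by betweenness centrality (ties: degree, then name).

    Returns (node, degree, clustering, betweenness) tuples; requires
    :func:`graph_metrics` to have populated the node attributes.  ``k``
    larger than the node count returns the full ranking.
    """
    nodes = list(g.nodes)
    if not nodes:
        return []
    if "betweenness" not in g.nodes[nodes[0]]:
        raise ValueError("run graph_metrics first")
    ranked = sorted(
        nodes,
        key=lambda n: (-g.nodes[n]["betweenness"], -g.nodes[n]["degree"], n),
    )
    return [
        (
            n,
            int(g.nodes[n]["degree"]),
            float(g.nodes[n]["clustering"]),
            float(g.nodes[n]["betweenness"]),
        )
        for n in ranked[: min(k, len(ranked))]
    ]
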