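"""Brute-force reference implementations used only as test oracles.

Everything here is written from the defining formulas with plain Python
loops, deliberately independent of the implementation paths it checks
(networkx, scipy, and the package's own code).
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# graphs: adjacency-set based, no networkx
# ---------------------------------------------------------------------------

def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_paths(adj, s):
    """Distances and shortest-path counts from source s."""
    dist = {s: 0}
    sigma = {s: 1}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def oracle_betweenness(nodes, edges):
    """Unnormalised betweenness via the pair-sum definition:
    sum over unordered pairs {s,t} of sigma_st(v)/sigma_st."""
    adj = adjacency(nodes, edges)
    paths = {s: bfs_paths(adj, s) for s in nodes}
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sig_s = paths[s]
        if t not in dist_s:
            continue
        d = dist_s[t]
        total = sig_s[t]
        dist_t, sig_t = paths[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d:
                bc[v] += sig_s[v] * sig_t[v] / total
    return bc


def oracle_clustering(nodes, edges):
    adj = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        tri = sum(
            1 for a, b in itertools.combinations(sorted(adj[v]), 2) if b in adj[a]
        )
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def oracle_transitivity(nodes, edges):
    adj = adjacency(nodes, edges)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(sorted(nodes), 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes)
    return 3.0 * triangles / triples if triples else 0.0


def oracle_path_metrics(nodes, edges):
    """(diameter, average path length) over the largest connected component."""
    adj = adjacency(nodes, edges)
    seen, comps = set(), []
    for n in nodes:
        if n in seen:
            continue
        dist, _ = bfs_paths(adj, n)
        comps.append(sorted(dist))
        seen |= set(dist)
    comp = max(comps, key=len)
    if len(comp) == 1:
        return 0, 0.0
    dists = []
    for s, t in itertools.combinations(comp, 2):
        d, _ = bfs_paths(adj, s)
        dists.append(d[t])
    return max(dists), sum(dists) / len(dists)


def oracle_modularity(nodes, edges, partition):
    """Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = len(edges)
    deg = {n: 0 for n in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    comms = {}
    for n, c in partition.items():
        comms.setdefault(c, set()).add(n)
    q = 0.0
    for members in comms.values():
        e_c = sum(1 for u, v in edges if u in members and v in members)
        d_c = sum(deg[n] for n in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# alpha-diversity estimators from the defining formulas
# ---------------------------------------------------------------------------

def oracle_alpha(counts, rare_cutoff=10):
    c = [int(x) for x in counts if x > 0]
    n = sum(c)
    s_obs = len(c)
    f = {}
    for x in c:
        f[x] = f.get(x, 0) + 1
    f1, f2 = f.get(1, 0), f.get(2, 0)
    coverage = 1.0 - f1 / n
    chao1 = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    p = [x / n for x in c]
    shannon = -sum(pi * np.log(pi) for pi in p)
    simpson = sum(x * (x - 1) for x in c) / (n * (n - 1)) if n >= 2 else None
    rare = [x for x in c if x <= rare_cutoff]
    s_abund = s_obs - len(rare)
    if not rare:
        ace = float(s_abund)
        fallback = False
    else:
        n_rare = sum(rare)
        f1r = sum(1 for x in rare if x == 1)
        c_ace = 1 - f1r / n_rare
        if c_ace == 0:
            ace, fallback = chao1, True
        else:
            ssum = sum(i * (i - 1) * f.get(i, 0) for i in range(1, rare_cutoff + 1))
            gamma2 = max(len(rare) / c_ace * ssum / (n_rare * (n_rare - 1)) - 1, 0.0)
            ace = s_abund + len(rare) / c_ace + f1r / c_ace * gamma2
            fallback = False
    return {
        "observed": s_obs,
        "coverage": coverage,
        "chao1": chao1,
        "ace": ace,
        "ace_fallback": fallback,
        "shannon": shannon,
        "simpson": simpson,
    }


# ---------------------------------------------------------------------------
# ranks and rank statistics
# ---------------------------------------------------------------------------

def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    """Pearson correlation of midranks, from the covariance formula."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / np.sqrt(vx * vy)


def oracle_kruskal_h(groups):
    """Kruskal-Wallis H with midranks and tie correction."""
    pooled = [v for g in groups for v in g]
    ranks = midranks(pooled)
    n = len(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = sum(ranks[i : i + len(g)])
        h += r * r / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def oracle_anosim_r(dmat, labels):
    """R = (mean between rank - mean within rank) / (n(n-1)/4)."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = midranks([dmat[i][j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    return (sum(between) / len(between) - sum(within) / len(within)) / (n * (n - 1) / 4)


def oracle_adonis(dmat, labels):
    """(pseudo-F, R^2) from the sums-of-squares definition."""
    n = len(labels)
    ss_total = sum(dmat[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            dmat[i][j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    g = len(groups)
    if ss_within == 0:
        return float("inf"), ss_between / ss_total
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    return f, ss_between / ss_total


def exhaustive_perm_p(dmat, labels, statistic):
    """Exact one-sided p over all distinct label assignments.

    ``statistic`` maps a label sequence to the test statistic; the p-value
    is the share of assignments with statistic >= the observed one.
    """
    obs = statistic(labels)
    n = len(labels)
    hits = total = 0
    seen_positions = sorted(set(labels))
    for perm in set(itertools.permutations(labels)):
        total += 1
        if statistic(list(perm)) >= obs - 1e-12:
            hits += 1
    return hits / total, total
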