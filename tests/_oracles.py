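"""Independent brute-force oracles shared by unit and acceptance tests."""

from collections import deque

import networkx as nx
import numpy as np


def brute_force_betweenness(G):
    """Betweenness by explicit BFS geodesic counting (unordered pairs)."""
    nodes = list(G.nodes())
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = {s: 0}
        sigma = {s: 1.0}
        preds = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in G.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        for t in dist:
            if t == s or nodes.index(t) < i:
                continue
            stack = [(t, [t])]
            while stack:
                u, path = stack.pop()
                if u == s:
                    for v in path[1:-1]:
                        score[v] += 1.0 / sigma[t]
                    continue
                for p in preds[u]:
                    stack.append((p, path + [p]))
    return score


def dense_mean_cosine(G):
    """Mean cosine similarity via an explicit dense adjacency matrix."""
    nodes = list(G.nodes())
    A = nx.to_numpy_array(G, nodelist=nodes)
    deg = A.sum(axis=1)
    n = len(nodes)
    means = {}
    for i, v in enumerate(nodes):
        total = 0.0
        for j in range(n):
            if j == i:
                continue
            denom = np.sqrt(deg[i] * deg[j])
            total += (A[i] @ A[j]) / denom if denom > 0 else 0.0
        means[v] = total / (n - 1)
    return means
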