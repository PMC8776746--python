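"""Gene functional traits from the interaction network and copy counts.

Three per-gene traits proxy functional redundancy and multi-functionality:

* **betweenness centrality** — how often a gene lies on shortest paths between
  other genes; high values mark "bridge" genes linking sub-networks, whose
  removal would disconnect functions.
* **mean cosine similarity** — average cosine overlap between a gene's
  neighbourhood and every other gene's neighbourhood; high values mark genes
  with near-duplicate interaction profiles, i.e. putative functional
  redundancy.
* **duplication level** — mean copy number among strains carrying the gene;
  another redundancy proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp

from stresspan.pangenome import PangenomeMatrix


def build_network(
    edge_list: pd.DataFrame | list[tuple],
    isolated_genes: list[str] | None = None,
) -> nx.Graph:
    """Build an undirected simple graph from a two-column edge list.

    Duplicate edges (in either orientation) are merged and self-loops dropped;
    the number dropped is stored in ``G.graph["self_loops_dropped"]``.
    ``isolated_genes`` adds degree-0 vertices not mentioned in any edge.
    """
    if isinstance(edge_list, pd.DataFrame):
        if edge_list.shape[1] < 2:
            raise ValueError("edge list needs two identifier columns")
        pairs = list(zip(edge_list.iloc[:, 0], edge_list.iloc[:, 1]))
    else:
        pairs = list(edge_list)
    G = nx.Graph()
    dropped = 0
    for i, pair in enumerate(pairs):
        try:
            u, v = pair
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed edge at line {i}: {pair!r}") from exc
        if pd.isna(u) or pd.isna(v):
            raise ValueError(f"malformed edge at line {i}: {pair!r}")
        if u == v:
            dropped += 1
            continue
        G.add_edge(u, v)
    if isolated_genes:
        G.add_nodes_from(isolated_genes)
    G.graph["self_loops_dropped"] = dropped
    return G


def betweenness(G: nx.Graph, normalized: bool = False) -> pd.Series:
    """Shortest-path betweenness centrality per vertex (unnormalized default).

    Brandes' algorithm (each unordered vertex pair counted once; endpoints
    excluded).  Disconnected graphs are handled naturally: only
    within-component pairs contribute.  Scale is immaterial downstream
    (traits are standardized before regression); ``normalized=True`` divides
    by the number of vertex pairs.  Large unnormalized queries are delegated
    to igraph's C implementation of the same statistic when available.
    """
    if normalized:
        vals = nx.betweenness_centrality(G, normalized=True)
        return pd.Series(vals, name="betweenness").astype(float)
    if G.number_of_nodes() > 500:
        try:
            import igraph as ig

            nodes = list(G.nodes())
            idx = {v: i for i, v in enumerate(nodes)}
            g = ig.Graph(
                n=len(nodes), edges=[(idx[u], idx[v]) for u, v in G.edges()]
            )
            vals = g.betweenness(directed=False)
            return pd.Series(vals, index=nodes, name="betweenness").astype(float)
        except ImportError:
            pass
    vals = nx.betweenness_centrality(G, normalized=False)
    return pd.Series(vals, name="betweenness").astype(float)


def mean_cosine(G: nx.Graph, include_other_components: bool = True) -> pd.Series:
    """Mean pairwise cosine similarity of neighbourhoods, per vertex.

    cosine(u, v) = |N(u) ∩ N(v)| / sqrt(deg(u) · deg(v)) on binary adjacency
    rows (self excluded; 0 when either vertex is isolated).  The mean is taken
    over all *other* vertices in the network, zeros included — vertices in
    different components contribute 0 to each other's mean.  Computed with
    sparse products so memory scales with the number of nonzero similarities.

    With ``include_other_components=False`` the mean is restricted to the
    vertex's own connected component.
    """
    nodes = list(G.nodes())
    n = len(nodes)
    if n == 0:
        return pd.Series(dtype=float, name="mean_cosine")
    if n == 1:
        return pd.Series([0.0], index=nodes, name="mean_cosine")
    A = nx.to_scipy_sparse_array(G, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv_sqrt = np.zeros(n)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    D = sp.diags(inv_sqrt)
    An = D @ A  # rows scaled by 1/sqrt(deg)
    S = (An @ An.T).tocsr()  # S[u,v] = |N(u) n N(v)| / sqrt(deg u * deg v)
    row_sums = np.asarray(S.sum(axis=1)).ravel()
    diag = S.diagonal()
    if include_other_components:
        means = (row_sums - diag) / (n - 1)
    else:
        comp_size = np.empty(n, dtype=float)
        idx = {v: i for i, v in enumerate(nodes)}
        for comp in nx.connected_components(G):
            for v in comp:
                comp_size[idx[v]] = len(comp)
        means = np.zeros(n)
        multi = comp_size > 1
        means[multi] = (row_sums[multi] - diag[multi]) / (comp_size[multi] - 1)
    return pd.Series(means, index=nodes, name="mean_cosine")


def duplication_level(
    matrix: PangenomeMatrix, extra_copies: bool = False
) -> pd.Series:
    """Mean copy number among carrying strains, per gene.

    Genes absent from every strain get NaN (undefined).  With
    ``extra_copies=True`` the statistic is count − 1 (duplicates beyond the
    first copy) instead of the raw copy count.
    """
    counts = matrix.counts.astype(float)
    present = counts >= 1
    n_carriers = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        total = np.where(present, counts, 0.0).sum(axis=0)
        mean = np.where(n_carriers > 0, total / np.maximum(n_carriers, 1), np.nan)
    if extra_copies:
        mean = mean - 1.0
    return pd.Series(mean, index=matrix.genes, name="duplication")


def compute_gene_traits(
    G: nx.Graph,
    matrix: PangenomeMatrix,
    include_other_components: bool = True,
) -> pd.DataFrame:
    """Assemble the trait table for genes present in both network and matrix.

    Returns a DataFrame indexed by gene_id with columns ``betweenness``,
    ``mean_cosine`` and ``duplication``; only genes that appear in the network
    (the field analogue: genes with an interaction-database match) are kept.
    """
    btw = betweenness(G)
    cos = mean_cosine(G, include_other_components=include_other_components)
    dup = duplication_level(matrix)
    genes = [g for g in matrix.genes if g in G]
    out = pd.DataFrame(
        {
            "betweenness": btw.reindex(genes),
            "mean_cosine": cos.reindex(genes),
            "duplication": dup.reindex(genes),
        }
    )
    out.index.name = "gene_id"
    return out
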