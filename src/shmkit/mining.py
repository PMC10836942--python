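"""Large-scale mining: profile search, clustering, co-expression networks.

Workflow mirrored here: starting from a query gene shown in a spatial
heatmap, (1) rank all other genes by profile similarity and keep the
closest ones (fixed number, percentage, or threshold); (2) cluster the
subsetted matrix hierarchically and cut the tree to get the query's
cluster; (3) build an unsigned soft-threshold co-expression network
(adjacency |cor|^beta), partition it into modules, and compute per-gene
within-module connectivity; (4) test clusters/modules for gene-set
enrichment with the hypergeometric tail.

The agglomeration here is written out explicitly (Lance-Williams
updates) rather than delegated, so that tie-breaking is fully
deterministic: among equally close cluster pairs the pair whose
smallest original leaf indices sort first is merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


# ---------------------------------------------------------------------------
# similarity search
# ---------------------------------------------------------------------------

def _pearson_to_query(values: np.ndarray, qi: int) -> np.ndarray:
    v = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((v**2).sum(axis=1)) * np.sqrt((v[qi] ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v @ v[qi]) / denom
    return r


def similarity_search(
    values: pd.DataFrame,
    query_gene: str,
    metric: str = "pearson",
    top_n: int | None = None,
    top_pct: float | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Genes most similar to the query (query included, ranked first).

    Exactly one selector: ``top_n`` genes, ``top_pct`` percent
    (``ceil(pct/100 * n_genes)`` genes, counting the query), or a
    similarity ``threshold`` (correlation >= t, or euclidean distance
    <= t).  Correlations rank descending, euclidean distance ascending;
    ties break by gene id lexicographic order.
    """
    if query_gene not in values.index:
        raise ValidationError(f"unknown query gene {query_gene!r}")
    selectors = [s for s in (top_n, top_pct, threshold) if s is not None]
    if len(selectors) != 1:
        raise ValidationError("give exactly one of top_n, top_pct, threshold")
    if top_pct is not None and not 0 < top_pct <= 100:
        raise ValidationError(f"top_pct must be in (0, 100], got {top_pct}")
    mat = values.to_numpy(dtype=float)
    genes = list(values.index)
    qi = genes.index(query_gene)
    if metric in ("pearson", "spearman"):
        if mat.shape[1] < 3:
            raise ValidationError("correlation search needs >= 3 samples")
        m = (
            np.apply_along_axis(stats.rankdata, 1, mat)
            if metric == "spearman"
            else mat
        )
        score = _pearson_to_query(m, qi)
        score = np.where(np.isnan(score), -np.inf, score)
        order_key = -score
    elif metric == "euclidean":
        score = -np.sqrt(((mat - mat[qi]) ** 2).sum(axis=1))
        order_key = -score
    else:
        raise ValidationError(f"unknown metric {metric!r}")

    others = [i for i in range(len(genes)) if i != qi]
    others.sort(key=lambda i: (order_key[i], genes[i]))
    ranked = [query_gene] + [genes[i] for i in others]

    if top_n is not None:
        if top_n < 1:
            raise ValidationError("top_n must be >= 1")
        return ranked[:top_n]
    if top_pct is not None:
        n = math.ceil(top_pct / 100.0 * len(genes))
        return ranked[: max(n, 1)]
    keep = [query_gene] + [genes[i] for i in others if score[i] >= threshold]
    return keep


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge sequence over labeled leaves.

    ``merges[t]`` gives the pair of node ids joined at step t (leaves
    are 0..n-1, the cluster created at step t has id n+t);
    ``heights[t]`` the merge distance.  Convertible to a scipy linkage
    matrix via :meth:`to_linkage`.
    """

    merges: list[tuple[int, int]]
    heights: list[float]
    labels: list[str]
    sizes: list[int] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        Z = np.zeros((len(self.merges), 4))
        for t, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            Z[t] = (a, b, h, self.sizes[t])
        return Z

    def leaf_order(self) -> list[str]:
        """Leaves left-to-right as drawn: recursive traversal of merges."""
        n = self.n_leaves
        children = {n + t: ab for t, ab in enumerate(self.merges)}
        out: list[int] = []

        def rec(node: int) -> None:
            if node < n:
                out.append(node)
            else:
                a, b = children[node]
                rec(a)
                rec(b)

        rec(n + len(self.merges) - 1) if self.merges else out.extend(range(n))
        return [self.labels[i] for i in out]


def _pairwise_distance(mat: np.ndarray, distance: str, labels: list[str]) -> np.ndarray:
    if distance == "euclidean":
        sq = ((mat[:, None, :] - mat[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(sq)
    if distance == "correlation":
        sd = mat.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValidationError(
                f"constant row under correlation distance: {labels[flat[0]]!r}"
            )
        return 1.0 - np.corrcoef(mat)
    raise ValidationError(f"unknown distance {distance!r}")


def hcluster(
    values: pd.DataFrame,
    row_scaling: str = "none",
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of matrix rows.

    ``distance``: ``correlation`` (1 - Pearson) or ``euclidean``;
    ``linkage``: ``average`` | ``complete`` | ``single``;
    ``row_scaling='z'`` standardizes each row first.  The merge order
    is fully deterministic: equal-distance candidates resolve to the
    pair whose smallest member leaf indices sort first.
    """
    if values.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    labels = [str(i) for i in values.index]
    mat = values.to_numpy(dtype=float)
    if row_scaling == "z":
        sd = mat.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValidationError(
                f"constant row cannot be z-scaled: {labels[int(np.flatnonzero(sd == 0)[0])]!r}"
            )
        mat = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    elif row_scaling != "none":
        raise ValidationError(f"unknown row_scaling {row_scaling!r}")

    D = _pairwise_distance(mat, distance, labels)
    return _agglomerate(D, labels, linkage)


def cut_tree(
    dend: Dendrogram, h: float | None = None, k: int | None = None
) -> dict[str, int]:
    """Partition the leaves by cutting the dendrogram.

    Exactly one of ``h`` (cut height: merges at height <= h are kept)
    or ``k`` (number of clusters) must be given.  Cluster labels are
    1..m, ordered by each cluster's smallest leaf index.
    """
    if (h is None) == (k is None):
        raise ValidationError("give exactly one of h= or k=")
    n = dend.n_leaves
    if k is not None and not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    parent = list(range(n + len(dend.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_apply = (
        sum(1 for hh in dend.heights if hh <= h) if h is not None else n - k
    )
    for t in range(n_apply):
        a, b = dend.merges[t]
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda g: g[0])
    out: dict[str, int] = {}
    for lab, members in enumerate(ordered, start=1):
        for leaf in members:
            out[dend.labels[leaf]] = lab
    return out


# ---------------------------------------------------------------------------
# co-expression network
# ---------------------------------------------------------------------------

@dataclass
class ModuleGraph:
    """Unsigned soft-threshold co-expression network.

    ``adjacency[i, j] = |pearson(i, j)|**beta`` with unit diagonal;
    ``module_labels`` maps genes to modules (0 = unassigned);
    ``connectivity[i]`` is the sum of gene i's adjacencies to the other
    members of its module.
    """

    genes: list[str]
    adjacency: np.ndarray
    beta: float
    module_labels: np.ndarray | None = None
    connectivity: np.ndarray | None = None

    def module_of(self, gene: str) -> int:
        if self.module_labels is None:
            raise ValidationError("modules not detected yet")
        return int(self.module_labels[self.genes.index(gene)])

    def module_members(self, module: int) -> list[str]:
        if self.module_labels is None:
            raise ValidationError("modules not detected yet")
        return [g for g, m in zip(self.genes, self.module_labels) if m == module]


def adjacency(values: pd.DataFrame, beta: float = 6) -> ModuleGraph:
    """Soft-threshold adjacency a_ij = |cor_ij|^beta (unsigned network).

    ``beta`` >= 1 sharpens the correlation so that only strongly
    co-expressed gene pairs keep substantial edge weight; 6 is the
    common unsigned-network default.
    """
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    if values.shape[1] < 3:
        raise ValidationError("adjacency needs >= 3 samples")
    mat = values.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(f"constant row: {values.index[flat[0]]!r}")
    a = np.abs(np.corrcoef(mat)) ** beta
    np.fill_diagonal(a, 1.0)
    return ModuleGraph(genes=[str(g) for g in values.index], adjacency=a, beta=beta)


def detect_modules(
    graph: ModuleGraph, min_size: int = 5, cut_height: float = 0.8
) -> ModuleGraph:
    """Partition the network into modules and fill in connectivity.

    The dissimilarity 1 - adjacency is clustered (average linkage) and
    cut at ``cut_height``; clusters smaller than ``min_size`` become
    unassigned (label 0).  Surviving modules are renumbered 1.. in
    order of their first gene.  Connectivity is summed within modules
    only; unassigned genes get 0.
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    n = len(graph.genes)
    dend = _agglomerate(1.0 - graph.adjacency, graph.genes, "average")
    raw = cut_tree(dend, h=cut_height)
    labels = np.zeros(n, dtype=int)
    by_cluster: dict[int, list[int]] = {}
    for i, g in enumerate(graph.genes):
        by_cluster.setdefault(raw[g], []).append(i)
    next_label = 1
    for cl in sorted(by_cluster, key=lambda c: by_cluster[c][0]):
        members = by_cluster[cl]
        if len(members) >= min_size:
            labels[members] = next_label
            next_label += 1
    conn = np.zeros(n)
    for m in range(1, next_label):
        idx = np.flatnonzero(labels == m)
        sub = graph.adjacency[np.ix_(idx, idx)]
        conn[idx] = sub.sum(axis=1) - 1.0  # drop self-adjacency
    return ModuleGraph(
        genes=graph.genes,
        adjacency=graph.adjacency,
        beta=graph.beta,
        module_labels=labels,
        connectivity=conn,
    )


def _agglomerate(D: np.ndarray, labels: list[str], linkage: str) -> Dendrogram:
    """Agglomerate a precomputed symmetric distance matrix.

    Lance-Williams updates; ties resolve to the pair whose smallest
    original leaf indices sort first, making merge order deterministic.
    """
    n = D.shape[0]
    D = D.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))  # rows of D still holding live clusters
    node_id = {i: i for i in range(n)}  # D row -> dendrogram node id
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # smallest original leaf in cluster
    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    sizes: list[int] = []
    for step in range(n - 1):
        best = None
        for i in active:
            row = D[i, active]
            j = active[int(np.argmin(row))]
            if i == j:
                continue
            key = (D[i, j], *sorted((rep[i], rep[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        if rep[j] < rep[i]:
            i, j = j, i
        d = D[i, j]
        merges.append(tuple(sorted((node_id[i], node_id[j]))))
        heights.append(float(d))
        sizes.append(size[i] + size[j])
        ni, nj = size[i], size[j]
        for kk in active:
            if kk in (i, j):
                continue
            if linkage == "single":
                dnew = min(D[i, kk], D[j, kk])
            elif linkage == "complete":
                dnew = max(D[i, kk], D[j, kk])
            else:  # average
                dnew = (ni * D[i, kk] + nj * D[j, kk]) / (ni + nj)
            D[i, kk] = D[kk, i] = dnew
        D[j, :] = D[:, j] = np.inf
        active.remove(j)
        node_id[i] = n + step
        size[i] = ni + nj
        rep[i] = min(rep[i], rep[j])
    return Dendrogram(merges=merges, heights=heights, labels=list(labels), sizes=sizes)


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def hypergeom_enrich(
    cluster_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene cluster.

    For each set S (intersected with the universe): p = P(X >=
    |cluster & S|) drawing |cluster| genes from a universe containing
    |S| successes.  BH adjustment across sets.
    """
    if not universe:
        raise ValidationError("empty universe")
    extra = cluster_genes - universe
    if extra:
        raise ValidationError(f"cluster genes outside universe: {sorted(extra)[:5]}")
    M, N = len(universe), len(cluster_genes)
    rows = []
    for name in sorted(gene_sets):
        s = gene_sets[name] & universe
        overlap = len(cluster_genes & s)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(s), N))
        rows.append(
            {"set_id": name, "overlap": overlap, "set_size": len(s), "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size", "p"])
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["padj"] = []
    return df


def write_graphml(
    graph: ModuleGraph, path: str | Path, edge_threshold: float = 0.1
) -> None:
    """Export the module graph to GraphML via networkx.

    Nodes carry ``module`` and ``connectivity`` attributes; edges carry
    ``adjacency`` and are pruned below ``edge_threshold``.
    """
    import networkx as nx

    if graph.module_labels is None:
        raise ValidationError("detect modules before export")
    G = nx.Graph()
    for i, g in enumerate(graph.genes):
        G.add_node(
            g,
            module=int(graph.module_labels[i]),
            connectivity=float(graph.connectivity[i]),
        )
    n = len(graph.genes)
    for i in range(n):
        for j in range(i + 1, n):
            a = float(graph.adjacency[i, j])
            if a >= edge_threshold:
                G.add_edge(graph.genes[i], graph.genes[j], adjacency=a)
    nx.write_graphml(G, str(path))
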