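"""Downstream interpretation: routing networks, clustering metrics, context
enrichment, and the bimodal beta-value methylation threshold.

The capsule network's coupling matrix assigns each child capsule (gene) a
distribution over output classes; averaged over individuals it forms a
weighted bipartite gene-class graph. Projecting it to a gene-gene network
(correlating per-gene routing profiles across samples) and clustering with
Louvain modularity reveals modules of genes with a coordinated methylation
response. Fisher exact tests relate top-ranked CpG weights to genomic
contexts (island/shore/shelf, promoter), and a kernel-density local minimum
on the bimodal beta distribution operationalizes "methylated".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelmin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score, v_measure_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "BipartiteRouting",
    "ContingencyTable2x2",
    "average_routing",
    "bipartite_to_unipartite",
    "louvain_modules",
    "knn_modules",
    "hierarchical_cluster",
    "v_measure",
    "silhouette",
    "bootstrap_metric",
    "context_enrichment",
    "beta_bimodal_threshold",
]


@dataclass
class BipartiteRouting:
    """Capsule x class matrix of routing coefficients averaged over samples."""

    weights: pd.DataFrame  # rows: capsules, columns: classes; rows sum to 1
    n_samples: int


@dataclass
class ContingencyTable2x2:
    """Counts (a, b, c, d): top-set in/out of context, rest in/out of context."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def average_routing(
    C_stack: np.ndarray,
    capsule_names: list[str] | None = None,
    class_names: list[str] | None = None,
) -> BipartiteRouting:
    """Elementwise mean of per-sample coupling matrices (samples x caps x classes).

    Row-stochasticity is preserved by linearity of the mean.
    """
    C_stack = np.asarray(C_stack, dtype=float)
    if C_stack.ndim != 3:
        raise ValueError(f"expected samples x capsules x classes, got shape {C_stack.shape}")
    if not np.allclose(C_stack.sum(axis=2), 1.0, atol=1e-6):
        raise ValueError("routing rows must sum to 1 over classes")
    mean = C_stack.mean(axis=0)
    n_caps, n_classes = mean.shape
    idx = capsule_names or [f"capsule{i}" for i in range(n_caps)]
    cols = class_names or [f"class{j}" for j in range(n_classes)]
    return BipartiteRouting(pd.DataFrame(mean, index=idx, columns=cols), len(C_stack))


def bipartite_to_unipartite(
    C_stack: np.ndarray,
    capsule_names: list[str] | None = None,
    averaged: bool = False,
) -> pd.DataFrame:
    """Project gene-to-class routing into a gene-gene correlation network.

    Each gene's profile is its routing coefficients flattened across
    (samples x classes); the edge weight between two genes is the Pearson
    correlation of their profiles (signed; diagonal 1). With
    ``averaged=True``, profiles are the sample-averaged rows instead (the
    coarser variant). Zero-variance profiles get zero edge weights with a
    warning.
    """
    C_stack = np.asarray(C_stack, dtype=float)
    if C_stack.ndim != 3:
        raise ValueError(f"expected samples x capsules x classes, got {C_stack.shape}")
    if C_stack.shape[0] < 3 and not averaged:
        raise ValueError("need at least 3 samples to correlate routing profiles")
    n, n_caps, n_classes = C_stack.shape
    if averaged:
        profiles = C_stack.mean(axis=0)  # caps x classes
    else:
        profiles = C_stack.transpose(1, 0, 2).reshape(n_caps, n * n_classes)
    names = capsule_names or [f"capsule{i}" for i in range(n_caps)]
    sd = profiles.std(axis=1)
    flat = sd == 0
    cor = np.zeros((n_caps, n_caps))
    ok = ~flat
    if ok.sum() >= 2:
        cor[np.ix_(ok, ok)] = np.corrcoef(profiles[ok])
    if flat.any():
        warnings.warn(
            f"zero-variance routing profile(s) for {list(np.array(names)[flat])}; "
            "their edge weights set to 0"
        )
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=names, columns=names)


def louvain_modules(
    net: pd.DataFrame, resolution: float = 1.0, seed: int = 0
) -> pd.Series:
    """Louvain community detection on a weighted gene-gene network.

    Negative edge weights are clipped to 0 (modularity requires nonnegative
    weights); the signed matrix should be kept for reporting. Module labels
    are contiguous integers from 0, ordered by each module's first gene.
    Deterministic given seed.
    """
    if net.shape[0] == 0:
        raise ValueError("empty network")
    genes = list(net.index)
    W = np.maximum(net.to_numpy(dtype=float), 0.0)
    G = nx.Graph()
    G.add_nodes_from(genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if W[i, j] > 0:
                G.add_edge(genes[i], genes[j], weight=float(W[i, j]))
    communities = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    order = {g: i for i, g in enumerate(genes)}
    communities = sorted(communities, key=lambda c: min(order[g] for g in c))
    labels = {}
    for m, comm in enumerate(communities):
        for g in comm:
            labels[g] = m
    return pd.Series([labels[g] for g in genes], index=genes, name="module")


def knn_modules(
    gene_profiles: pd.DataFrame, k: int = 15, seed: int = 0, resolution: float = 1.0
) -> pd.Series:
    """Louvain modules on a union-of-neighbors kNN graph of gene profiles.

    ``gene_profiles`` is genes x samples (e.g. the transposed gene-embedding
    matrix); neighbors by Euclidean distance, edges unweighted.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = gene_profiles.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    X = gene_profiles.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, ind = nn.kneighbors(X)
    adj = np.zeros((n, n))
    for i in range(n):
        for j in ind[i, 1:]:
            adj[i, j] = adj[j, i] = 1.0
    net = pd.DataFrame(adj, index=gene_profiles.index, columns=gene_profiles.index)
    return louvain_modules(net, resolution=resolution, seed=seed)


def hierarchical_cluster(embeddings: np.ndarray, n_clusters: int = 14) -> np.ndarray:
    """Agglomerative clustering (Ward linkage, Euclidean) cut to n_clusters."""
    embeddings = np.asarray(embeddings, dtype=float)
    if n_clusters > embeddings.shape[0]:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds number of samples {embeddings.shape[0]}"
        )
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(embeddings)


def v_measure(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Harmonic mean of homogeneity and completeness, in [0, 1]."""
    return float(v_measure_score(truth, predicted))


def silhouette(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient over samples, in [-1, 1]."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(embeddings, float), labels))


def bootstrap_metric(
    metric,
    *arrays: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Nonparametric bootstrap (percentile CI) of a sample-wise metric.

    ``metric(*resampled_arrays)`` is evaluated on ``n_boot`` resamples of the
    samples (rows) with replacement; resamples on which the metric is
    undefined (e.g. a single cluster for the silhouette) are skipped.
    """
    rng = np.random.default_rng(seed)
    n = len(arrays[0])
    stats_ = []
    while len(stats_) < n_boot:
        idx = rng.integers(n, size=n)
        try:
            stats_.append(metric(*[np.asarray(a)[idx] for a in arrays]))
        except ValueError:
            continue
    lo, hi = np.quantile(stats_, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {
        "estimate": float(metric(*arrays)),
        "low": float(lo),
        "high": float(hi),
        "se": float(np.std(stats_, ddof=1)),
        "n_boot": n_boot,
    }


def context_enrichment(
    weights: pd.Series,
    context: pd.Series,
    top_k: int = 1000,
    direction: str = "positive",
) -> dict:
    """Fisher exact test of top-weighted CpGs against a genomic context.

    ``weights`` maps CpG -> learned weight; ``context`` maps CpG -> bool flag
    (e.g. promoter-island membership). The top set holds the ``top_k`` CpGs
    by descending weight ("positive"), ascending weight ("negative"), or
    descending absolute weight ("absolute"); ties break by CpG id. Returns
    the odds ratio (a*d)/(b*c) with the Haldane-Anscombe 0.5 correction when
    any cell is zero (flagged), the two-sided Fisher p-value, and the table.
    """
    if top_k >= len(weights):
        raise ValueError(f"top_k={top_k} must be smaller than the number of CpGs")
    missing = weights.index.difference(context.index)
    if len(missing):
        raise KeyError(f"context flag missing for CpGs: {list(missing[:5])}")
    tab = pd.DataFrame({"w": weights, "flag": context.reindex(weights.index).astype(bool)})
    if direction == "positive":
        order = sorted(tab.index, key=lambda c: (-tab.at[c, "w"], c))
    elif direction == "negative":
        order = sorted(tab.index, key=lambda c: (tab.at[c, "w"], c))
    elif direction == "absolute":
        order = sorted(tab.index, key=lambda c: (-abs(tab.at[c, "w"]), c))
    else:
        raise ValueError("direction must be 'positive', 'negative' or 'absolute'")
    top = set(order[:top_k])
    in_top = tab.index.isin(top)
    flag = tab["flag"].to_numpy()
    table = ContingencyTable2x2(
        a=int((in_top & flag).sum()),
        b=int((in_top & ~flag).sum()),
        c=int((~in_top & flag).sum()),
        d=int((~in_top & ~flag).sum()),
    )
    corrected = 0 in (table.a, table.b, table.c, table.d)
    if corrected:
        oa, ob, oc, od = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    else:
        oa, ob, oc, od = table.a, table.b, table.c, table.d
    odds_ratio = (oa * od) / (ob * oc)
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return {
        "odds_ratio": float(odds_ratio),
        "p_value": float(p),
        "table": table,
        "haldane_corrected": corrected,
        "direction": direction,
        "top_k": top_k,
    }


def beta_bimodal_threshold(
    values: np.ndarray,
    search_range: tuple[float, float] = (0.2, 0.8),
    grid_size: int = 512,
) -> float:
    """Methylation cutoff at the lowest-density local minimum of the beta KDE.

    A Gaussian kernel density estimate (Scott bandwidth) is evaluated on a
    grid over [0, 1]; the threshold is the grid location of the
    lowest-density local minimum inside ``search_range`` that actually
    separates two modes (a density peak at least twice the minimum's density
    on each side — this rejects spurious wiggles in a decaying tail). If no
    such valley exists (unimodal distribution), falls back to 0.5. A site or
    promoter with mean beta above the threshold is called methylated.
    Order-invariant; requires at least 50 values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < 50:
        raise ValueError(f"need >= 50 beta values, got {len(values)}")
    kde = stats.gaussian_kde(values)
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid)
    lo, hi = search_range
    valleys = [
        i
        for i in argrelmin(density)[0]
        if lo <= grid[i] <= hi
        and min(density[:i].max(), density[i + 1 :].max()) >= 2.0 * density[i]
    ]
    if not valleys:
        return 0.5
    best = min(valleys, key=lambda i: density[i])
    return float(grid[best])
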