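"""Weighted comethylation networks over gene-level embeddings.

The pipeline mirrors weighted correlation network analysis: Pearson
correlation between gene-level embeddings, an unsigned power adjacency
``a_ij = |cor_ij|^beta``, the topological overlap measure (TOM) that scores
how much two genes share neighbors, average-linkage hierarchical clustering
of ``1 - TOM`` into modules, per-module eigengenes (first principal
component), and intramodular hub genes. Modules or genes are related to a
two-group phenotype with an empirical-Bayes moderated t-test: residual
variances are shrunk toward a prior estimated by the method of moments on
log residual variances, and p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .spwnet import GeneEmbeddingMatrix

__all__ = [
    "gene_correlation",
    "power_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "intramodular_hubs",
    "moderated_two_group_test",
    "pick_soft_threshold",
]

UNASSIGNED = -1  # module label for singleton clusters


def _as_frame(embeddings: GeneEmbeddingMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(embeddings, GeneEmbeddingMatrix):
        return embeddings.values
    return embeddings


def gene_correlation(embeddings: GeneEmbeddingMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between gene columns (samples x genes input).

    Constant genes are dropped with a warning; requires >= 3 samples.
    """
    E = _as_frame(embeddings)
    if E.shape[0] < 3:
        raise ValueError(f"need >= 3 samples to correlate genes, got {E.shape[0]}")
    sd = E.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping constant gene(s): {list(constant[:5])}")
        E = E.drop(columns=constant)
    cor = np.corrcoef(E.to_numpy(dtype=float), rowvar=False)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=E.columns, columns=E.columns)


def power_adjacency(cor: pd.DataFrame, power: float = 6.0, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency ``a_ij = |cor_ij|^power`` (unsigned default).

    The signed option uses ``((1 + cor) / 2)^power``.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    C = cor.to_numpy(dtype=float)
    A = ((1.0 + C) / 2.0) ** power if signed else np.abs(C) ** power
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    """Per-gene connectivity ``k_i = sum_{j != i} a_ij`` (diagonal excluded)."""
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    return pd.Series(A.sum(axis=1), index=adjacency.index, name="k")


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with unit diagonal; entries lie in [0, 1] for adjacencies in [0, 1].
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # (i, j) entry includes u = i and u = j terms, both 0 off-diagonal
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    n_modules: int | None = None,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage hierarchical clustering of ``1 - TOM`` into modules.

    Cut either to a fixed module count or at a dissimilarity height.
    Singleton clusters are relabeled :data:`UNASSIGNED` (-1); real modules
    get contiguous labels from 0 ordered by first gene. Gene order does not
    affect the partition, only the labeling is order-dependent.
    """
    if (n_modules is None) == (cut_height is None):
        raise ValueError("specify exactly one of n_modules or cut_height")
    genes = list(tom.index)
    if n_modules is not None and n_modules > len(genes):
        raise ValueError(f"n_modules={n_modules} exceeds gene count {len(genes)}")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.maximum((diss + diss.T) / 2.0, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    if n_modules is not None:
        raw = fcluster(Z, t=n_modules, criterion="maxclust")
    else:
        raw = fcluster(Z, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    labels: dict[str, int] = {}
    next_label = 0
    seen: dict[int, int] = {}
    for g, r in zip(genes, raw):
        if counts[r] < 2:
            labels[g] = UNASSIGNED
        elif r in seen:
            labels[g] = seen[r]
        else:
            seen[r] = next_label
            labels[g] = next_label
            next_label += 1
    return pd.Series([labels[g] for g in genes], index=genes, name="module")


def module_eigengene(
    embeddings: GeneEmbeddingMatrix | pd.DataFrame,
    module_genes: list[str],
) -> tuple[pd.Series, float]:
    """First principal component of the standardized module submatrix.

    Returns the eigengene (one value per sample) and the fraction of the
    module's variance it explains. The sign is oriented so the eigengene
    correlates positively with the module's mean profile. A single-gene
    module returns that gene's standardized profile with a warning.
    """
    E = _as_frame(embeddings)
    sub = E.loc[:, module_genes].to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("module contains a constant gene; drop it first")
    stdized = (sub - sub.mean(axis=0)) / sd
    if len(module_genes) == 1:
        warnings.warn("module of one gene: returning its standardized profile")
        return pd.Series(stdized[:, 0], index=E.index, name="eigengene"), 1.0
    U, s, Vt = np.linalg.svd(stdized, full_matrices=False)
    eig = stdized @ Vt[0]  # loadings Vt[0] are unit norm
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = stdized.mean(axis=1)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=E.index, name="eigengene"), var_explained


def intramodular_hubs(
    adjacency: pd.DataFrame, modules: pd.Series, top_n: int = 10
) -> pd.DataFrame:
    """Rank genes inside each module by within-module connectivity.

    Hub score of gene i = sum of adjacency to other genes of its module;
    ties break by gene id. Unassigned genes (-1) are skipped.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    genes = list(adjacency.index)
    pos = {g: i for i, g in enumerate(genes)}
    rows = []
    for module in sorted(m for m in modules.unique() if m != UNASSIGNED):
        members = [g for g in genes if modules[g] == module]
        idx = [pos[g] for g in members]
        score = {g: float(A[pos[g], idx].sum()) for g in members}
        ranked = sorted(members, key=lambda g: (-score[g], g))[:top_n]
        for rank, g in enumerate(ranked, start=1):
            rows.append({"module": module, "rank": rank, "gene": g, "connectivity": score[g]})
    return pd.DataFrame(rows, columns=["module", "rank", "gene", "connectivity"])


def pick_soft_threshold(
    cor: pd.DataFrame,
    powers: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Smallest power whose connectivity distribution fits a scale-free law.

    Fits log10 p(k) ~ log10 k over connectivity bins and reports the model
    R^2 per candidate power; returns the smallest power reaching
    ``r2_target`` (or the best-fitting power if none does) and the fit table.
    """
    rows = []
    chosen = None
    for p in powers:
        k = connectivity(power_adjacency(cor, power=p)).to_numpy()
        k = k[k > 0]
        if len(k) < n_bins:
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = (edges[:-1] + edges[1:]) / 2
        ok = hist > 0
        if ok.sum() < 3:
            continue
        x, y = np.log10(centers[ok]), np.log10(hist[ok] / hist.sum())
        slope, intercept, r, _, _ = stats.linregress(x, y)
        r2 = float(r**2) if slope < 0 else 0.0
        rows.append({"power": p, "r2": r2, "slope": slope})
        if chosen is None and r2 >= r2_target:
            chosen = p
    table = pd.DataFrame(rows)
    if chosen is None:
        chosen = float(table.loc[table["r2"].idxmax(), "power"]) if len(table) else 6.0
    return float(chosen), table


# ---------------------------------------------------------------------------
# empirical-Bayes moderated two-group test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Uses the scaled-F model for sample variances: ``e = log s^2`` has mean
    ``log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)`` and variance
    ``psi'(d/2) + psi'(d0/2)``. An excess of observed variance over
    ``psi'(d/2)`` determines d0; no excess gives an infinite prior df.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_two_group_test(
    matrix: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per feature for a binary contrast.

    ``matrix`` is samples x features (gene embeddings or eigengene
    projections); ``groups`` is a binary label per sample. Per feature the
    least-squares effect is the group-mean difference; residual variances
    (df = n - 2) are shrunk toward the moment-estimated prior,
    ``s2_post = (d0 s0^2 + d s^2) / (d0 + d)``, and the moderated t uses
    d0 + d degrees of freedom. Returns effect, t, raw p, BH-adjusted p,
    and the prior (d0, s0^2) on every row. ``prior`` overrides the estimated
    (d0, s0^2); ``prior=(0, anything)`` recovers the ordinary equal-variance
    two-sample t-test.
    """
    groups = np.asarray(pd.Series(groups).values)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    mask1 = groups == levels[1]
    n0, n1 = int((~mask1).sum()), int(mask1.sum())
    if min(n0, n1) < 2:
        raise ValueError("both groups need >= 2 samples")
    X = matrix.to_numpy(dtype=float)
    m0 = X[~mask1].mean(axis=0)
    m1 = X[mask1].mean(axis=0)
    effect = m1 - m0
    rss = ((X[~mask1] - m0) ** 2).sum(axis=0) + ((X[mask1] - m1) ** 2).sum(axis=0)
    df = n0 + n1 - 2
    s2 = rss / df
    if np.all(s2 == 0):
        raise ValueError("zero residual variance for every feature")
    d0, s0_2 = prior if prior is not None else _fit_prior(s2, df)
    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(df)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p_value": p,
            "adj_p_value": adj,
            "prior_df": d0,
            "prior_var": s0_2,
        },
        index=matrix.columns,
    )
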