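"""Group-lasso sparse pathway network (MethylSPWNet).

Each gene (capsule) ``j`` owns a learnable weight vector ``w_j`` over its
CpGs; its gene-level summary is ``z_j = sigma(w_j . x_j)`` — a learnable
generalization of the per-gene mean beta, which corresponds to equal weights
``1/d_j`` with identity ``sigma``. The gene-level summaries feed an MLP head
with a softmax output. Training minimizes cross-entropy plus a group-L1
penalty ``lambda * sum_j sqrt(d_j) * |w_j|_2`` that drives whole genes
toward zero, performing gene selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import CapsuleMap, MethylationArray
from .nn import MLP, softmax

__all__ = [
    "SPWNetModel",
    "GeneEmbeddingMatrix",
    "gene_aggregate",
    "spwnet_forward",
    "cross_entropy",
    "group_l1",
    "gene_embeddings",
    "cpg_weight_ranking",
]

_CLAMP = 1e-12  # probability clamp inside the log of the cross-entropy
_NORM_EPS = 1e-8  # small-norm guard in the group-L1 gradient
#: genes with |w_j|_2 below this are reported as dropped out (exact zeros are
#: not claimed because the penalty is applied as a differentiable term)
ZERO_NORM_THRESHOLD = 1e-4

_SIGMAS: dict[str, tuple[Callable, Callable]] = {
    "identity": (lambda t: t, lambda t: np.ones_like(t)),
    "tanh": (np.tanh, lambda t: 1.0 - np.tanh(t) ** 2),
    "relu": (lambda t: np.maximum(t, 0.0), lambda t: (t > 0).astype(float)),
}


@dataclass
class GeneEmbeddingMatrix:
    """Samples x capsules matrix of gene-level summary values ``z``."""

    values: pd.DataFrame  # index: sample ids, columns: capsule names

    @property
    def capsule_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class SPWNetModel:
    """Parameters of the sparse pathway network.

    ``w`` is the concatenation of all per-gene weight vectors in capsule
    order, with ``group_slices`` delimiting gene ``j``'s segment (length
    ``d_j``); ``stack_idx`` maps each stacked position to its column in the
    model's input CpG order (a CpG in two capsules occupies two positions).
    """

    capsule_names: list[str]
    input_cpgs: list[str]
    classes: list[str]
    w: np.ndarray
    head: MLP
    group_slices: list[tuple[int, int]]
    stack_idx: np.ndarray
    stack_cpgs: list[str] = field(repr=False, default_factory=list)
    sigma: str = "identity"
    lambda_group: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_group < 0:
            raise ValueError("lambda_group must be >= 0")
        if self.sigma not in _SIGMAS:
            raise ValueError(f"unknown sigma {self.sigma!r}; options: {list(_SIGMAS)}")
        total = sum(b - a for a, b in self.group_slices)
        if total != len(self.w) or total != len(self.stack_idx):
            raise ValueError("group slices inconsistent with weight vector length")

    @classmethod
    def initialize(
        cls,
        cmap: CapsuleMap,
        classes: list[str],
        rng: np.random.Generator,
        hidden: tuple[int, ...] = (64, 32),
        sigma: str = "identity",
        lambda_group: float = 0.0,
    ) -> "SPWNetModel":
        names = cmap.names
        input_cpgs = cmap.all_cpgs()
        col = {c: i for i, c in enumerate(input_cpgs)}
        slices: list[tuple[int, int]] = []
        stack_idx: list[int] = []
        stack_cpgs: list[str] = []
        pos = 0
        for name in names:
            cpgs = cmap.capsules[name]
            slices.append((pos, pos + len(cpgs)))
            stack_idx.extend(col[c] for c in cpgs)
            stack_cpgs.extend(cpgs)
            pos += len(cpgs)
        # start near the mean-beta summary: weight ~ 1/d_j plus a small jitter
        w = np.empty(pos)
        for (a, b2) in slices:
            d = b2 - a
            w[a:b2] = 1.0 / d + rng.normal(0.0, 0.1 / np.sqrt(d), size=d)
        head = MLP([len(names), *hidden, len(classes)], rng)
        return cls(
            capsule_names=names,
            input_cpgs=input_cpgs,
            classes=list(classes),
            w=w,
            head=head,
            group_slices=slices,
            stack_idx=np.asarray(stack_idx),
            stack_cpgs=stack_cpgs,
            sigma=sigma,
            lambda_group=lambda_group,
        )

    @property
    def d(self) -> np.ndarray:
        """Per-gene CpG counts ``d_j``."""
        return np.array([b - a for a, b in self.group_slices])

    def group_norms(self) -> np.ndarray:
        """Euclidean norm ``|w_j|_2`` per gene."""
        return np.array([np.linalg.norm(self.w[a:b]) for a, b in self.group_slices])

    def gene_weight_vectors(self) -> dict[str, np.ndarray]:
        return {
            name: self.w[a:b]
            for name, (a, b) in zip(self.capsule_names, self.group_slices)
        }

    def params(self) -> list[np.ndarray]:
        return [self.w, *self.head.params]


def gene_aggregate(x_j: np.ndarray, w_j: np.ndarray, sigma: str = "identity") -> float:
    """Gene-level summary ``z_j = sigma(w_j . x_j)`` for one gene and sample."""
    x_j, w_j = np.asarray(x_j, float), np.asarray(w_j, float)
    if x_j.shape != w_j.shape:
        raise ValueError(f"length mismatch: x has {x_j.shape}, w has {w_j.shape}")
    fn, _ = _SIGMAS[sigma]
    return float(fn(np.dot(w_j, x_j)))


def _aggregate_batch(model: SPWNetModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Eq. z_j = sigma(w_j . x_j) over a batch; returns (z, pre-activation)."""
    stacked = X[:, model.stack_idx] * model.w[None, :]
    starts = np.array([a for a, _ in model.group_slices])
    pre = np.add.reduceat(stacked, starts, axis=1)
    fn, _ = _SIGMAS[model.sigma]
    return fn(pre), pre


def spwnet_forward(z: np.ndarray, model: SPWNetModel) -> np.ndarray:
    """Class probabilities ``softmax(f(z))`` for gene-summary rows ``z``."""
    z = np.atleast_2d(np.asarray(z, float))
    logits = model.head.forward(z)
    return softmax(logits, axis=1)


def cross_entropy(p_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood; probabilities clamped at 1e-12."""
    p_hat = np.atleast_2d(np.asarray(p_hat, float))
    y = np.atleast_1d(np.asarray(y))
    if y.ndim == 2:  # one-hot
        y = y.argmax(axis=1)
    p_true = p_hat[np.arange(len(y)), y.astype(int)]
    return float(-np.mean(np.log(np.maximum(p_true, _CLAMP))))


def group_l1(model: SPWNetModel) -> float:
    """Group-lasso penalty ``sum_j sqrt(d_j) |w_j|_2``."""
    return float(np.sum(np.sqrt(model.d) * model.group_norms()))


def _group_l1_grad(model: SPWNetModel) -> np.ndarray:
    """Gradient of the penalty: ``sqrt(d_j) w_j / |w_j|_2`` with a small-norm guard."""
    g = np.zeros_like(model.w)
    for (a, b), d in zip(model.group_slices, model.d):
        seg = model.w[a:b]
        g[a:b] = np.sqrt(d) * seg / (np.linalg.norm(seg) + _NORM_EPS)
    return g


def gene_embeddings(
    model: SPWNetModel, array: MethylationArray, cmap: CapsuleMap
) -> GeneEmbeddingMatrix:
    """Apply the trained aggregation to every sample: samples x capsules ``z``."""
    if list(cmap.names) != list(model.capsule_names):
        raise ValueError("capsule map does not match the one the model was built on")
    missing = [c for c in model.input_cpgs if c not in array.beta.columns]
    if missing:
        raise KeyError(f"array lacks CpGs required by the model: {missing[:5]}")
    X = array.beta.loc[:, model.input_cpgs].to_numpy(dtype=float)
    z, _ = _aggregate_batch(model, X)
    return GeneEmbeddingMatrix(
        pd.DataFrame(z, index=array.samples, columns=model.capsule_names)
    )


def cpg_weight_ranking(model: SPWNetModel) -> pd.DataFrame:
    """Rank CpGs by learned weight: ascending, descending, and by |weight|.

    Columns: cpg, gene, weight, rank (descending weight, 1 = largest),
    reverse_rank (ascending weight, 1 = most negative), abs_rank
    (descending absolute weight). Ties break by CpG id.
    """
    genes = [
        name
        for name, (a, b) in zip(model.capsule_names, model.group_slices)
        for _ in range(b - a)
    ]
    tab = pd.DataFrame({"cpg": model.stack_cpgs, "gene": genes, "weight": model.w})
    by_desc = tab.sort_values(["weight", "cpg"], ascending=[False, True]).index
    by_asc = tab.sort_values(["weight", "cpg"], ascending=[True, True]).index
    by_abs = (
        tab.assign(_a=tab.weight.abs())
        .sort_values(["_a", "cpg"], ascending=[False, True])
        .index
    )
    for col, order in (("rank", by_desc), ("reverse_rank", by_asc), ("abs_rank", by_abs)):
        r = np.empty(len(tab), dtype=int)
        r[np.asarray(order)] = np.arange(1, len(tab) + 1)
        tab[col] = r
    return tab.reset_index(drop=True)


def gene_importance(model: SPWNetModel) -> pd.DataFrame:
    """Per-gene importance: group norm and maximum absolute CpG weight."""
    ranking = cpg_weight_ranking(model)
    agg = ranking.groupby("gene")["weight"].agg(max_abs_weight=lambda s: s.abs().max())
    agg["group_norm"] = pd.Series(
        model.group_norms(), index=model.capsule_names, dtype=float
    )
    agg["dropped_out"] = agg["group_norm"] < ZERO_NORM_THRESHOLD
    return agg.sort_values("max_abs_weight", ascending=False)


# ---------------------------------------------------------------------------
# training-time loss + gradients
# ---------------------------------------------------------------------------

def loss_and_grads(
    model: SPWNetModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, list[np.ndarray], dict]:
    """Cross-entropy + lambda * group-L1 and gradients for one batch."""
    n = X.shape[0]
    z, pre = _aggregate_batch(model, X)
    logits = model.head.forward(z)
    p = softmax(logits, axis=1)
    ce = cross_entropy(p, y)
    penalty = group_l1(model)
    loss = ce + model.lambda_group * penalty

    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    dlogits = (p - onehot) / n
    model.head.zero_grad()
    dz = model.head.backward(dlogits)
    _, dfn = _SIGMAS[model.sigma]
    dpre = dz * dfn(pre)
    # d/dw of sum_n dpre[n, gene(k)] * x[n, stack k]
    gene_of_pos = np.repeat(
        np.arange(len(model.group_slices)), model.d
    )
    dw = np.einsum("nk,nk->k", dpre[:, gene_of_pos], X[:, model.stack_idx])
    dw += model.lambda_group * _group_l1_grad(model)

    grads = [dw, *model.head.grads]
    info = {"cross_entropy": ce, "group_l1": penalty, "p": p, "pred": p.argmax(axis=1)}
    return loss, grads, info
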