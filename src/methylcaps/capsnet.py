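"""Capsule network over CpG groupings with dynamic routing-by-agreement.

Each capsule (a named CpG group) gets its own multilayer perceptron encoder
``f_j`` mapping its beta values to an embedding of shared dimension. Per
(child capsule, output class) affine transforms produce prediction vectors
``u_hat[j|i] = W_ij z_i + b_ij``; dynamic routing then iteratively reweights
each child's contribution to the class-level output capsules by dot-product
agreement. The class whose output capsule has the largest L2 norm is the
prediction. Training minimizes a squared-hinge margin loss on the output
norms plus a weighted reconstruction loss from a decoder that rebuilds the
input beta vector from the true class's output capsule.

With a single transform shared across parents ("shared_transform"), every
parent receives identical predictions from each child, the agreement update
is symmetric across parents, and routing provably stays uniform — a
degenerate model kept available only for ablation; per-pair transforms are
the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CapsuleMap, MethylationArray
from .nn import MLP, softmax

__all__ = [
    "CapsNetModel",
    "CapsuleStack",
    "RoutingState",
    "squash",
    "primary_capsules",
    "transform_capsules",
    "dynamic_route",
    "margin_loss",
    "reconstruction_loss",
    "capsnet_forward",
]

_EPS = 1e-12


def squash(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Norm-compressing nonlinearity ``(|v|^2 / (1 + |v|^2)) * v / |v|``.

    Maps any vector into the open unit ball while preserving direction; the
    zero vector maps to the zero vector (limit convention). Output norm is
    strictly increasing in the input norm.
    """
    sq_norm = np.sum(np.square(v), axis=axis, keepdims=True)
    norm = np.sqrt(sq_norm)
    return (sq_norm / (1.0 + sq_norm)) * v / np.maximum(norm, _EPS)


def _squash_backward(s: np.ndarray, grad_y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector-Jacobian product of ``squash`` at pre-activation ``s``.

    With n = |s|, squash(s) = kappa(n) s where kappa = n / (1 + n^2), so
    J = kappa I + (kappa'(n)/n) s s^T and kappa' = (1 - n^2) / (1 + n^2)^2.
    """
    sq_norm = np.sum(np.square(s), axis=axis, keepdims=True)
    n = np.sqrt(sq_norm)
    kappa = n / (1.0 + sq_norm)
    dkappa = (1.0 - sq_norm) / np.square(1.0 + sq_norm)
    dot = np.sum(s * grad_y, axis=axis, keepdims=True)
    return kappa * grad_y + dkappa / np.maximum(n, _EPS) * dot * s


@dataclass
class CapsNetModel:
    """Parameters and hyperparameters of the capsule network.

    ``encoders[i]`` is the MLP ``f_i`` for capsule ``i``; ``W``/``b`` hold the
    per-(child, parent) affine transforms (shape ``caps x classes x emb x out``;
    the parent axis has length 1 when ``shared_transform``); ``decoder`` maps
    an output capsule back to the full input CpG vector.
    """

    capsule_names: list[str]
    input_cpgs: list[str]
    classes: list[str]
    encoders: list[MLP]
    W: np.ndarray
    b: np.ndarray
    decoder: MLP
    embedding_dim: int
    output_dim: int
    routing_iterations: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_margin: float = 0.5
    gamma: float = 0.005
    shared_transform: bool = False
    #: column indices of each capsule's CpGs within ``input_cpgs``
    _capsule_idx: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.m_minus < self.m_plus < 1.0):
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if self.embedding_dim < 1 or self.output_dim < 1:
            raise ValueError("embedding dimensions must be >= 1")

    @classmethod
    def initialize(
        cls,
        cmap: CapsuleMap,
        classes: list[str],
        rng: np.random.Generator,
        embedding_dim: int = 8,
        output_dim: int = 16,
        encoder_hidden: tuple[int, ...] = (32,),
        decoder_hidden: tuple[int, ...] = (64,),
        routing_iterations: int = 3,
        lambda_margin: float = 0.5,
        gamma: float = 0.005,
        shared_transform: bool = False,
    ) -> "CapsNetModel":
        names = cmap.names
        input_cpgs = cmap.all_cpgs()
        col = {c: i for i, c in enumerate(input_cpgs)}
        idx = [np.array([col[c] for c in cmap.capsules[n]]) for n in names]
        encoders = [
            MLP([len(ix), *encoder_hidden, embedding_dim], rng) for ix in idx
        ]
        n_parents = 1 if shared_transform else len(classes)
        scale = 1.0 / np.sqrt(embedding_dim)
        W = rng.normal(0.0, scale, size=(len(names), n_parents, embedding_dim, output_dim))
        b = np.zeros((len(names), n_parents, output_dim))
        decoder = MLP([output_dim, *decoder_hidden, len(input_cpgs)], rng)
        return cls(
            capsule_names=names,
            input_cpgs=input_cpgs,
            classes=list(classes),
            encoders=encoders,
            W=W,
            b=b,
            decoder=decoder,
            embedding_dim=embedding_dim,
            output_dim=output_dim,
            routing_iterations=routing_iterations,
            lambda_margin=lambda_margin,
            gamma=gamma,
            shared_transform=shared_transform,
            _capsule_idx=idx,
        )

    @property
    def n_capsules(self) -> int:
        return len(self.capsule_names)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for enc in self.encoders:
            out.extend(enc.params)
        out.extend([self.W, self.b])
        out.extend(self.decoder.params)
        return out


@dataclass
class CapsuleStack:
    """Per-sample child-capsule embeddings and their transformed predictions."""

    Z: np.ndarray  # samples x capsules x embedding_dim
    Z_star: np.ndarray | None = None  # samples x capsules x classes x output_dim


@dataclass
class RoutingState:
    """Final routing logits, coupling coefficients, and output capsules."""

    beta: np.ndarray  # samples x capsules x classes
    C: np.ndarray  # samples x capsules x classes; rows over classes sum to 1
    Y: np.ndarray  # samples x classes x output_dim; all norms < 1
    S: np.ndarray  # pre-squash weighted sums (cached for backprop)


def _batch_matrix(batch: MethylationArray | pd.DataFrame | np.ndarray, model: CapsNetModel) -> np.ndarray:
    if isinstance(batch, MethylationArray):
        beta = batch.beta
    elif isinstance(batch, pd.DataFrame):
        beta = batch
    else:
        return np.asarray(batch, dtype=float)
    missing = [c for c in model.input_cpgs if c not in beta.columns]
    if missing:
        raise KeyError(f"batch lacks CpGs required by the model: {missing[:5]}")
    return beta.loc[:, model.input_cpgs].to_numpy(dtype=float)


def primary_capsules(
    batch: MethylationArray | pd.DataFrame | np.ndarray,
    cmap: CapsuleMap,
    model: CapsNetModel,
) -> CapsuleStack:
    """Encode each capsule's CpGs through its own MLP ``f_j``.

    Returns a stack shaped samples x capsules x embedding_dim.
    """
    if isinstance(batch, (MethylationArray, pd.DataFrame)):
        cols = batch.beta.columns if isinstance(batch, MethylationArray) else batch.columns
        for name in model.capsule_names:
            for c in cmap.capsules[name]:
                if c not in cols:
                    raise KeyError(f"capsule {name!r} references missing CpG {c!r}")
    X = _batch_matrix(batch, model)
    Z = np.empty((X.shape[0], model.n_capsules, model.embedding_dim))
    for i, idx in enumerate(model._capsule_idx):
        Z[:, i, :] = model.encoders[i].forward(X[:, idx])
    return CapsuleStack(Z=Z)


def transform_capsules(stack: CapsuleStack, model: CapsNetModel) -> CapsuleStack:
    """Affine per-(child, parent) transforms: ``u_hat[j|i] = W_ij z_i + b_ij``."""
    Z = stack.Z
    if Z.shape[-1] != model.W.shape[2]:
        raise ValueError(
            f"embedding dim {Z.shape[-1]} does not match transform dim {model.W.shape[2]}"
        )
    u_hat = np.einsum("nie,ijeo->nijo", Z, model.W) + model.b[None]
    if model.shared_transform and u_hat.shape[2] == 1:
        u_hat = np.broadcast_to(
            u_hat, (Z.shape[0], model.n_capsules, model.n_classes, model.output_dim)
        ).copy()
    stack.Z_star = u_hat
    return stack


def dynamic_route(stack: CapsuleStack, r: int) -> RoutingState:
    """Routing-by-agreement over the transformed predictions.

    Logits start at zero; each iteration applies a softmax over parents,
    forms each parent's squashed weighted sum, and increments the logit of
    every (child, parent) pair by their dot-product agreement. Coupling rows
    (over parents) sum to 1 after every iteration.
    """
    if stack.Z_star is None:
        raise ValueError("transform_capsules must run before routing")
    if r < 1:
        raise ValueError("routing needs at least one iteration")
    u_hat = stack.Z_star
    n, n_caps, n_classes, _ = u_hat.shape
    beta = np.zeros((n, n_caps, n_classes))
    C = S = Y = None
    for _ in range(r):
        C = softmax(beta, axis=2)
        S = np.einsum("nij,nijo->njo", C, u_hat)
        Y = squash(S)
        beta = beta + np.einsum("njo,nijo->nij", Y, u_hat)
    return RoutingState(beta=beta, C=C, Y=Y, S=S)


def margin_loss(
    norms: np.ndarray,
    y: np.ndarray,
    model: CapsNetModel,
) -> float:
    """Squared-hinge margin loss on output-capsule norms, averaged over samples.

    Per sample: sum over classes of
    ``delta_yj * max(0, m+ - |Y_j|)^2 + lambda * (1 - delta_yj) * max(0, |Y_j| - m-)^2``.
    """
    norms = np.atleast_2d(norms)
    y = np.atleast_1d(y)
    onehot = np.zeros_like(norms)
    onehot[np.arange(len(y)), y] = 1.0
    pos = np.square(np.maximum(0.0, model.m_plus - norms))
    neg = np.square(np.maximum(0.0, norms - model.m_minus))
    per_sample = (onehot * pos + model.lambda_margin * (1.0 - onehot) * neg).sum(axis=1)
    return float(per_sample.mean())


def reconstruction_loss(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Mean squared error between reconstruction and input."""
    x_hat, x = np.asarray(x_hat, dtype=float), np.asarray(x, dtype=float)
    if x_hat.shape != x.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {x.shape}")
    return float(np.mean(np.square(x_hat - x)))


def capsnet_forward(
    batch: MethylationArray | pd.DataFrame | np.ndarray,
    cmap: CapsuleMap,
    model: CapsNetModel,
    y: np.ndarray | None = None,
) -> dict:
    """Full forward pass.

    Returns a dict with predicted label indices (argmax of output-capsule
    norms; ties resolve to the lowest class index), per-class norms, total
    loss (margin + gamma * reconstruction; reconstruction uses the true-class
    capsule when ``y`` is given, else the predicted-class capsule), the final
    coupling matrix ``C`` and the primary-capsule stack ``Z``.
    """
    X = _batch_matrix(batch, model)
    stack = primary_capsules(batch, cmap, model)
    stack = transform_capsules(stack, model)
    routing = dynamic_route(stack, model.routing_iterations)
    norms = np.linalg.norm(routing.Y, axis=-1)
    pred = norms.argmax(axis=1)
    target = pred if y is None else np.asarray(y)
    loss_m = margin_loss(norms, target, model)
    caps = routing.Y[np.arange(len(target)), target]
    x_hat = model.decoder.forward(caps)
    loss_r = reconstruction_loss(x_hat, X)
    return {
        "pred": pred,
        "norms": norms,
        "loss": loss_m + model.gamma * loss_r,
        "margin_loss": loss_m,
        "reconstruction_loss": loss_r,
        "C": routing.C,
        "Z": stack.Z,
        "routing": routing,
        "stack": stack,
        "x_hat": x_hat,
        "X": X,
    }


# ---------------------------------------------------------------------------
# training-time loss + gradients (coupling coefficients treated as constants)
# ---------------------------------------------------------------------------

def loss_and_grads(
    model: CapsNetModel,
    X: np.ndarray,
    y: np.ndarray,
    fixed_C: np.ndarray | None = None,
) -> tuple[float, list[np.ndarray], dict]:
    """Total loss and gradients for one batch.

    The routing coefficients are recomputed from zero-initialized logits on
    every pass and treated as constants in the backward sweep (gradients flow
    through the final weighted sum, the squash, the transforms, the encoders
    and the decoder). ``fixed_C`` overrides routing for gradient checking.
    """
    n = X.shape[0]
    # forward
    Z = np.empty((n, model.n_capsules, model.embedding_dim))
    for i, idx in enumerate(model._capsule_idx):
        Z[:, i, :] = model.encoders[i].forward(X[:, idx])
    stack = CapsuleStack(Z=Z)
    transform_capsules(stack, model)
    u_hat = stack.Z_star
    if fixed_C is None:
        routing = dynamic_route(stack, model.routing_iterations)
        C = routing.C
    else:
        C = fixed_C
    S = np.einsum("nij,nijo->njo", C, u_hat)
    Y = squash(S)
    norms = np.linalg.norm(Y, axis=-1)

    onehot = np.zeros_like(norms)
    onehot[np.arange(n), y] = 1.0
    pos_hinge = np.maximum(0.0, model.m_plus - norms)
    neg_hinge = np.maximum(0.0, norms - model.m_minus)
    loss_m = float(
        ((onehot * pos_hinge**2) + model.lambda_margin * (1 - onehot) * neg_hinge**2)
        .sum(axis=1)
        .mean()
    )
    caps_true = Y[np.arange(n), y]
    x_hat = model.decoder.forward(caps_true)
    loss_r = float(np.mean(np.square(x_hat - X)))
    loss = loss_m + model.gamma * loss_r

    # backward
    model.decoder.zero_grad()
    for enc in model.encoders:
        enc.zero_grad()

    d_norm = (
        onehot * (-2.0 * pos_hinge) + model.lambda_margin * (1 - onehot) * 2.0 * neg_hinge
    ) / n
    dY = d_norm[..., None] * Y / np.maximum(norms[..., None], _EPS)
    # reconstruction path: dL/dx_hat -> decoder -> true-class capsule
    d_xhat = model.gamma * 2.0 * (x_hat - X) / x_hat.size
    d_caps = model.decoder.backward(d_xhat)
    dY[np.arange(n), y] += d_caps

    dS = _squash_backward(S, dY)
    d_uhat = C[..., None] * dS[:, None, :, :]  # n x caps x classes x out
    if model.shared_transform:
        d_uhat_eff = d_uhat.sum(axis=2, keepdims=True)
    else:
        d_uhat_eff = d_uhat
    dW = np.einsum("nie,nijo->ijeo", Z, d_uhat_eff)
    db = d_uhat_eff.sum(axis=0)
    dZ = np.einsum("nijo,ijeo->nie", d_uhat_eff, model.W)

    grads: list[np.ndarray] = []
    for i, idx in enumerate(model._capsule_idx):
        model.encoders[i].backward(dZ[:, i, :])
        grads.extend(model.encoders[i].grads)
    grads.extend([dW, db])
    grads.extend(model.decoder.grads)

    info = {
        "margin_loss": loss_m,
        "reconstruction_loss": loss_r,
        "norms": norms,
        "C": C,
        "pred": norms.argmax(axis=1),
    }
    return loss, grads, info
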