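"""Data splitting, variance-based CpG selection, training loops, random search.

Splits are stratified by class label and deterministic given a seed; the
default fractions are 70%/10%/20% train/validation/test. CpG selection keeps
the k most variable loci, computed on training samples only — validation and
test arrays must be subset to the training-selected CpGs to avoid leakage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import capsnet as _capsnet
from . import spwnet as _spwnet
from .capsnet import CapsNetModel
from .core import CapsuleMap, MethylationArray, ValidationError
from .nn import MLP, Adam
from .spwnet import SPWNetModel

__all__ = [
    "TrainHistory",
    "SearchSpace",
    "split_train_val_test",
    "select_top_variable_cpgs",
    "train_model",
    "random_search",
    "save_checkpoint",
    "load_checkpoint",
]

#: number of most-variable CpG loci retained by default
DEFAULT_TOP_CPGS = 200_000


@dataclass
class TrainHistory:
    """Per-epoch loss/accuracy curves and the index of the best epoch."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class SearchSpace:
    """Hyperparameter ranges for the randomized search.

    ``choices`` maps a hyperparameter name to a list of candidate values;
    ``log_uniform`` maps a name to (low, high) bounds sampled on a log scale
    (e.g. learning rate); ``layer_sizes`` optionally gives, per possible
    depth, the candidate widths — the depth is drawn first and the widths
    conditionally on it.
    """

    choices: dict[str, list] = field(default_factory=dict)
    log_uniform: dict[str, tuple[float, float]] = field(default_factory=dict)
    layer_sizes: dict[int, list[int]] | None = None

    def __post_init__(self) -> None:
        if not (self.choices or self.log_uniform or self.layer_sizes):
            raise ValidationError("empty search space")
        for name, (lo, hi) in self.log_uniform.items():
            if not (0 < lo <= hi):
                raise ValidationError(f"bad bounds for {name!r}: ({lo}, {hi})")

    def sample(self, rng: np.random.Generator) -> dict:
        cfg: dict = {}
        for name, opts in self.choices.items():
            cfg[name] = opts[rng.integers(len(opts))]
        for name, (lo, hi) in self.log_uniform.items():
            cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if self.layer_sizes:
            depth = int(rng.choice(sorted(self.layer_sizes)))
            widths = self.layer_sizes[depth]
            cfg["hidden"] = tuple(int(widths[rng.integers(len(widths))]) for _ in range(depth))
        return cfg


# ---------------------------------------------------------------------------
# splitting and CpG selection
# ---------------------------------------------------------------------------

def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n samples to the fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most negative first
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_train_val_test(
    array: MethylationArray,
    fractions: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[MethylationArray, MethylationArray, MethylationArray]:
    """Stratified, disjoint, exhaustive split; deterministic given seed."""
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValidationError("fractions must be three values summing to 1")
    rng = np.random.default_rng(seed)
    labels = array.labels
    buckets: list[list[str]] = [[], [], []]
    for cls in sorted(labels.unique()):
        ids = [s for s in array.samples if labels[s] == cls]
        if len(ids) < 3:
            raise ValidationError(f"class {cls!r} has {len(ids)} samples; need >= 3 to stratify")
        perm = rng.permutation(len(ids))
        counts = _allocate(len(ids), fractions)
        start = 0
        for b, c in enumerate(counts):
            buckets[b].extend(ids[i] for i in perm[start : start + c])
            start += c
    # keep original sample order within each split
    order = {s: i for i, s in enumerate(array.samples)}
    return tuple(
        array.subset_samples(sorted(b, key=order.__getitem__)) for b in buckets
    )


def select_top_variable_cpgs(array: MethylationArray, k: int = DEFAULT_TOP_CPGS) -> MethylationArray:
    """Keep the k highest-variance CpGs of the given (training) array.

    Ties break by CpG id; if k >= the number of CpGs, all are retained.
    Compute this on training samples only, then subset validation/test arrays
    to the selected CpGs via :meth:`MethylationArray.subset_cpgs`.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= array.n_cpgs:
        return array
    var = array.beta.var(axis=0, ddof=1)
    order = sorted(array.cpgs, key=lambda c: (-var[c], c))
    pos = {c: i for i, c in enumerate(array.cpgs)}
    keep = sorted(order[:k], key=pos.__getitem__)
    return array.subset_cpgs(keep)


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _label_indices(array: MethylationArray, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in array.labels])


def _accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(pred == y))


def train_model(
    model_kind: str,
    train: MethylationArray,
    val: MethylationArray,
    cmap: CapsuleMap,
    config: Mapping | None = None,
    seed: int = 0,
) -> tuple[CapsNetModel | SPWNetModel, TrainHistory]:
    """Fit a capsule network ("capsnet") or sparse pathway network ("spwnet").

    Full-batch Adam by default (``batch_size`` in config enables minibatches).
    The parameters of the epoch with the best validation loss are retained.
    Deterministic given ``seed``. Raises on non-finite loss (divergence).
    """
    cfg = dict(config or {})
    rng = np.random.default_rng(seed)
    classes = sorted(train.labels.unique())
    epochs = int(cfg.pop("epochs", 100))
    lr = float(cfg.pop("lr", 1e-3))
    batch_size = cfg.pop("batch_size", None)
    selection_metric = cfg.pop("selection_metric", "val_loss")

    if model_kind == "capsnet":
        init_keys = (
            "embedding_dim output_dim encoder_hidden decoder_hidden "
            "routing_iterations lambda_margin gamma shared_transform".split()
        )
        model = CapsNetModel.initialize(
            cmap, classes, rng, **{k: cfg[k] for k in init_keys if k in cfg}
        )
        loss_and_grads = _capsnet.loss_and_grads
    elif model_kind == "spwnet":
        init_keys = ["hidden", "sigma", "lambda_group"]
        model = SPWNetModel.initialize(
            cmap, classes, rng, **{k: cfg[k] for k in init_keys if k in cfg}
        )
        loss_and_grads = _spwnet.loss_and_grads
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    Xtr = train.beta.loc[:, model.input_cpgs].to_numpy(dtype=float)
    ytr = _label_indices(train, classes)
    Xva = val.beta.loc[:, model.input_cpgs].to_numpy(dtype=float)
    yva = _label_indices(val, classes)

    params = model.params()
    opt = Adam(params, lr=lr)
    history = TrainHistory(seed=seed)
    best = None
    best_score = np.inf
    n = Xtr.shape[0]
    for epoch in range(epochs):
        if batch_size is None:
            order = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            order = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
        ep_loss = 0.0
        ep_correct = 0
        for idx in order:
            loss, grads, info = loss_and_grads(model, Xtr[idx], ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss!r}"
                )
            opt.step(grads)
            ep_loss += loss * len(idx)
            ep_correct += int((info["pred"] == ytr[idx]).sum())
        val_loss, _, vinfo = loss_and_grads(model, Xva, yva)
        history.train_loss.append(ep_loss / n)
        history.train_accuracy.append(ep_correct / n)
        history.val_loss.append(float(val_loss))
        history.val_accuracy.append(_accuracy(vinfo["pred"], yva))
        score = (
            history.val_loss[-1]
            if selection_metric == "val_loss"
            else -history.val_accuracy[-1]
        )
        if score < best_score:
            best_score = score
            best = [p.copy() for p in params]
            history.best_epoch = epoch
    if best is not None:
        for p, bp in zip(params, best):
            p[...] = bp
    return model, history


def predict(
    model: CapsNetModel | SPWNetModel,
    array: MethylationArray,
    cmap: CapsuleMap,
) -> pd.Series:
    """Predicted class labels for every sample of the array."""
    X = array.beta.loc[:, model.input_cpgs].to_numpy(dtype=float)
    if isinstance(model, CapsNetModel):
        out = _capsnet.capsnet_forward(array, cmap, model)
        idx = out["pred"]
    else:
        z, _ = _spwnet._aggregate_batch(model, X)
        idx = _spwnet.spwnet_forward(z, model).argmax(axis=1)
    return pd.Series([model.classes[i] for i in idx], index=array.samples, name="predicted")


def random_search(
    space: SearchSpace,
    n_trials: int,
    model_kind: str,
    train: MethylationArray,
    val: MethylationArray,
    cmap: CapsuleMap,
    seed: int = 0,
    base_config: Mapping | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Uniformly sample configs, train each, rank by validation loss.

    Returns the best config and a trial table (one row per trial with the
    sampled values and final metrics). Reproducible given seed. Trials whose
    training diverges are recorded with infinite loss; if all diverge an
    error carrying the trial table is raised.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    configs = []
    for t in range(n_trials):
        cfg = dict(base_config or {})
        cfg.update(space.sample(rng))
        trial_seed = int(rng.integers(2**31))
        row = {"trial": t, "seed": trial_seed, **{k: str(v) for k, v in cfg.items()}}
        try:
            _, hist = train_model(model_kind, train, val, cmap, cfg, seed=trial_seed)
            row["val_loss"] = min(hist.val_loss) if hist.val_loss else np.inf
            row["val_accuracy"] = (
                hist.val_accuracy[hist.best_epoch] if hist.val_loss else np.nan
            )
        except FloatingPointError:
            row["val_loss"] = np.inf
            row["val_accuracy"] = np.nan
        rows.append(row)
        configs.append(cfg)
    table = pd.DataFrame(rows)
    if not np.isfinite(table["val_loss"]).any():
        raise FloatingPointError(f"all {n_trials} trials diverged:\n{table}")
    best = int(table["val_loss"].idxmin())
    return configs[best], table


# ---------------------------------------------------------------------------
# checkpoints: weights as npz + config as json sidecar
# ---------------------------------------------------------------------------

def _map_hash(cmap: CapsuleMap) -> str:
    payload = json.dumps(cmap.capsules, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_checkpoint(
    model: CapsNetModel | SPWNetModel, cmap: CapsuleMap, path: str | Path
) -> None:
    """Serialize weights (npz) and config/capsule-map hash (json sidecar)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    if isinstance(model, CapsNetModel):
        meta = {
            "kind": "capsnet",
            "classes": model.classes,
            "embedding_dim": model.embedding_dim,
            "output_dim": model.output_dim,
            "encoder_hidden": [l.W.shape[1] for l in model.encoders[0].layers[:-1]],
            "decoder_hidden": [l.W.shape[1] for l in model.decoder.layers[:-1]],
            "routing_iterations": model.routing_iterations,
            "lambda_margin": model.lambda_margin,
            "gamma": model.gamma,
            "shared_transform": model.shared_transform,
        }
    else:
        meta = {
            "kind": "spwnet",
            "classes": model.classes,
            "hidden": [l.W.shape[1] for l in model.head.layers[:-1]],
            "sigma": model.sigma,
            "lambda_group": model.lambda_group,
        }
    meta["capsule_map_sha256"] = _map_hash(cmap)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(
    path: str | Path, cmap: CapsuleMap
) -> CapsNetModel | SPWNetModel:
    """Rebuild a model from a checkpoint; verifies the capsule-map hash."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["capsule_map_sha256"] != _map_hash(cmap):
        raise ValidationError("capsule map does not match the checkpointed model")
    rng = np.random.default_rng(0)  # weights are overwritten below
    if meta["kind"] == "capsnet":
        model: CapsNetModel | SPWNetModel = CapsNetModel.initialize(
            cmap,
            meta["classes"],
            rng,
            embedding_dim=meta["embedding_dim"],
            output_dim=meta["output_dim"],
            encoder_hidden=tuple(meta["encoder_hidden"]),
            decoder_hidden=tuple(meta["decoder_hidden"]),
            routing_iterations=meta["routing_iterations"],
            lambda_margin=meta["lambda_margin"],
            gamma=meta["gamma"],
            shared_transform=meta["shared_transform"],
        )
    else:
        model = SPWNetModel.initialize(
            cmap,
            meta["classes"],
            rng,
            hidden=tuple(meta["hidden"]),
            sigma=meta["sigma"],
            lambda_group=meta["lambda_group"],
        )
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model
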