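"""Training protocol: stratified splitting, AdamW with plateau-halved
learning rate, mini-batched weighted cross-entropy, and ablation variants.

The setting is transductive: one fixed graph, all node features visible,
label subsets disjoint across train/validation/test.  "Batch size 64"
therefore means each optimization step runs a full-graph forward pass but
restricts the loss to a shuffled batch of 64 training nodes.  The model
checkpoint returned is the one with the best validation AUROC.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np

from . import _autodiff as F
from ._autodiff import Tensor
from .evaluation import auc_score
from .graph import CorrelationGraph, build_neighborhoods
from .model import PARAM_FIELDS, ForwardResult, ModelParams, forward, init_params

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "DataSplit",
    "stratified_split",
    "train_model",
    "apply_ablation",
    "degree_matched_random_graph",
    "AdamW",
    "PlateauScheduler",
]

ABLATION_FLAGS = ("no_dynamic_threshold", "no_correlation_graph",
                  "no_second_order", "no_attention", "no_interaction_module")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    weight_decay: float = 1e-4
    epochs: int = 30
    scheduler_factor: float = 0.5
    scheduler_patience: int = 3
    seed: int = 0
    delta: float = 0.5
    tau: float = 0.6
    d: int = 64
    d_h: int = 128
    leaky_slope: float = 0.2
    loss: str = "weighted_bce"  # or "bce"
    no_dynamic_threshold: bool = False
    no_correlation_graph: bool = False
    no_second_order: bool = False
    no_attention: bool = False
    no_interaction_module: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ValueError("scheduler_factor must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def ablation(self) -> dict[str, bool]:
        return {f: getattr(self, f) for f in ABLATION_FLAGS}


@dataclasses.dataclass
class DataSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[float, float, float] = (0.70, 0.10, 0.20)


def _apportion(n: int, ratios) -> np.ndarray:
    """Largest-remainder allocation of n items to the ratio buckets."""
    exact = n * np.asarray(ratios, dtype=np.float64)
    counts = np.floor(exact).astype(np.int64)
    order = np.argsort(-(exact - counts), kind="stable")
    for k in order[: n - counts.sum()]:
        counts[k] += 1
    return counts


def stratified_split(labels, ratios=(0.70, 0.10, 0.20),
                     seed: int | np.random.Generator = 0) -> DataSplit:
    """Per-class shuffled partition preserving the class ratio in each
    subset to within one node."""
    labels = np.asarray(labels)
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        counts = _apportion(idx.size, ratios)
        if np.any(counts == 0):
            warnings.warn(f"class {cls} has too few nodes ({idx.size}) for the "
                          "split granularity; best-effort allocation", stacklevel=2)
        bounds = np.cumsum(counts)
        parts[0].append(idx[: bounds[0]])
        parts[1].append(idx[bounds[0]: bounds[1]])
        parts[2].append(idx[bounds[1]:])
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return DataSplit(train, val, test, tuple(ratios))


class AdamW:
    """AdamW (decoupled weight decay) over a dict of numpy parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


class PlateauScheduler:
    """Halve (by `factor`) the learning rate after `patience` consecutive
    epochs without improvement of the monitored quantity (maximize mode)."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 3):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.num_bad = 0

    def step(self, metric: float) -> None:
        if metric > self.best:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.optimizer.lr *= self.factor
                self.num_bad = 0


def degree_matched_random_graph(adjacency: np.ndarray,
                                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Seeded configuration-model rewiring with (approximately) the same
    degree sequence; multi-edges and self-loops are collapsed/dropped."""
    adjacency = np.asarray(adjacency)
    degrees = adjacency.sum(axis=1).astype(int).tolist()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = nx.configuration_model(degrees, seed=int(rng.integers(2 ** 31)))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    out = np.zeros_like(adjacency)
    for i, j in g.edges():
        out[i, j] = out[j, i] = 1
    return out


def apply_ablation(graph: CorrelationGraph, config: TrainConfig,
                   rng: np.random.Generator | None = None) -> tuple[CorrelationGraph, dict]:
    """Resolve ablation flags into the (possibly replaced) graph plus the
    keyword flags consumed by :func:`csgnn.model.forward`.

    `no_dynamic_threshold` acts upstream (raw expression instead of X') and
    is handled by the estimator; `no_correlation_graph` swaps in a
    degree-matched random graph here.
    """
    flags = {k: getattr(config, k) for k in
             ("no_second_order", "no_attention", "no_interaction_module")}
    if config.no_correlation_graph:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        graph = build_neighborhoods(
            degree_matched_random_graph(graph.adjacency, rng), tau=graph.tau)
    return graph, flags


def _loss_and_grads(params: ModelParams, features: np.ndarray, masks,
                    flags: dict, y: np.ndarray, batch_idx: np.ndarray,
                    pos_weight: float) -> tuple[float, dict[str, np.ndarray]]:
    """Weighted BCE on the batch nodes through a full-graph forward."""
    tensors = {k: Tensor(getattr(params, k), requires_grad=True) for k in PARAM_FIELDS}
    tparams = dataclasses.replace(params, **tensors)
    result = forward(tparams, features, masks, **flags)
    logits = result.logits
    sel = np.zeros(y.size)
    sel[batch_idx] = 1.0
    yb = y.astype(np.float64)
    # stable BCE from logits: y*softplus(-z)*w_pos + (1-y)*softplus(z)
    per_node = F.add(F.mul(F.softplus(F.mul(logits, -1.0)), yb * pos_weight),
                     F.mul(F.softplus(logits), 1.0 - yb))
    loss = F.div(F.reduce_sum(F.mul(per_node, sel)), float(batch_idx.size))
    loss.backward()
    grads = {k: tensors[k].grad if tensors[k].grad is not None
             else np.zeros_like(getattr(params, k)) for k in PARAM_FIELDS}
    return float(loss.data), grads


def train_model(features: np.ndarray, labels: np.ndarray, graph: CorrelationGraph,
                split: DataSplit, config: TrainConfig,
                params: ModelParams | None = None):
    """Optimize the model on the training nodes; select by validation AUROC.

    Returns ``(best_params, log)`` where `log` is a list of per-epoch dicts
    with keys epoch, loss, val_auroc, lr.  Only labels of `split.train_idx`
    enter the loss and only `split.val_idx` labels drive model selection.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    if split.train_idx.size == 0:
        raise ValueError("empty training set")

    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, ablation_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    graph, flags = apply_ablation(graph, config, ablation_rng)
    masks = graph.masks()

    if params is None:
        params = init_params(features.shape[1], d=config.d, d_h=config.d_h,
                             leaky_slope=config.leaky_slope, rng=init_rng)
    else:
        params = params.copy()

    y_train = labels[split.train_idx]
    n_pos = int(y_train.sum())
    n_neg = y_train.size - n_pos
    if config.loss == "weighted_bce" and n_pos > 0:
        pos_weight = n_neg / n_pos
    else:
        pos_weight = 1.0

    optimizer = AdamW(params.as_arrays(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    scheduler = PlateauScheduler(optimizer, config.scheduler_factor,
                                 config.scheduler_patience)

    best_val = -np.inf
    best_params = params.copy()
    log: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(split.train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, order.size, config.batch_size):
            batch = order[start: start + config.batch_size]
            loss, grads = _loss_and_grads(params, features, masks, flags,
                                          labels, batch, pos_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            optimizer.step(grads)
            epoch_loss += loss
            n_batches += 1

        probs = forward(params, features, masks, **flags).probabilities
        if split.val_idx.size and len(np.unique(labels[split.val_idx])) == 2:
            val_auroc = auc_score(probs[split.val_idx], labels[split.val_idx])
        else:
            val_auroc = np.nan
        if np.isfinite(val_auroc) and val_auroc > best_val:
            best_val = val_auroc
            best_params = params.copy()
        log.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
                    "val_auroc": val_auroc, "lr": optimizer.lr})
        logger.info("epoch %d loss %.4f val_auroc %s lr %.2e", epoch,
                    log[-1]["loss"], f"{val_auroc:.4f}", optimizer.lr)
        if np.isfinite(val_auroc):
            scheduler.step(val_auroc)

    if not np.isfinite(best_val):
        best_params = params.copy()
    return best_params, log
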