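"""CSGNN forward computation.

Two layers of order-specific graph attention aggregate a node's first- and
second-order co-expression neighborhoods into a 2d embedding; pairwise
compatibility descriptors (elementwise sum, elementwise product, ordered
concatenation) between a node and its union context C(i) = N1 ∪ N2 are
attention-weighted into an 8d interaction-aware representation; a two-layer
perceptron decodes it to an essentiality probability.

The forward pass is written against :mod:`csgnn._autodiff`'s dispatching
primitives, so the same code path serves numpy inference and gradient-based
training.  Isolated nodes follow the empty-sum convention (zero vectors),
so every node always receives a prediction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _autodiff as F
from ._autodiff import Tensor
from .graph import CorrelationGraph

__all__ = [
    "ModelParams",
    "ForwardResult",
    "init_params",
    "forward",
    "attention_coefficients",
    "layer_forward",
    "pair_descriptor",
    "context_aggregate",
    "decode",
    "classify",
    "PredictionResult",
]

PARAM_FIELDS = (
    "W1", "q1_order1", "q1_order2",
    "W2", "q2_order1", "q2_order2",
    "dec_W1", "dec_b1", "dec_W2", "dec_b2",
)


@dataclasses.dataclass
class ModelParams:
    """All learnable weights.  The decoder weights are distinct parameters
    from the projection matrices even though conventional notation reuses
    the symbols W1/W2 for both roles."""

    W1: np.ndarray        # (d, M)
    q1_order1: np.ndarray  # (2d,)
    q1_order2: np.ndarray  # (2d,)
    W2: np.ndarray        # (d, 2d)
    q2_order1: np.ndarray  # (2d,)
    q2_order2: np.ndarray  # (2d,)
    dec_W1: np.ndarray    # (d_h, 8d)
    dec_b1: np.ndarray    # (d_h,)
    dec_W2: np.ndarray    # (1, d_h)
    dec_b2: np.ndarray    # ()
    leaky_slope: float = 0.2

    @property
    def d(self) -> int:
        return self.W1.shape[0]

    @property
    def d_h(self) -> int:
        return self.dec_W1.shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams(*(getattr(self, f).copy() for f in PARAM_FIELDS),
                           leaky_slope=self.leaky_slope)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in PARAM_FIELDS}

    def save(self, path: str | Path, config: dict | None = None) -> None:
        """Checkpoint to a single .npz with a JSON sidecar for the config."""
        path = Path(path)
        np.savez(path, leaky_slope=np.float64(self.leaky_slope), **self.as_arrays())
        if config is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        with np.load(path) as data:
            return cls(*(data[f] for f in PARAM_FIELDS),
                       leaky_slope=float(data["leaky_slope"]))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(n_features: int, d: int = 64, d_h: int = 128,
                leaky_slope: float = 0.2,
                rng: np.random.Generator | int | None = None) -> ModelParams:
    """Seeded uniform Glorot initialization of every weight."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return ModelParams(
        W1=_glorot(rng, n_features, d, (d, n_features)),
        q1_order1=_glorot(rng, 2 * d, 1, (2 * d,)),
        q1_order2=_glorot(rng, 2 * d, 1, (2 * d,)),
        W2=_glorot(rng, 2 * d, d, (d, 2 * d)),
        q2_order1=_glorot(rng, 2 * d, 1, (2 * d,)),
        q2_order2=_glorot(rng, 2 * d, 1, (2 * d,)),
        dec_W1=_glorot(rng, 8 * d, d_h, (d_h, 8 * d)),
        dec_b1=np.zeros(d_h),
        dec_W2=_glorot(rng, d_h, 1, (1, d_h)),
        dec_b2=np.zeros(()),
        leaky_slope=leaky_slope,
    )


@dataclasses.dataclass
class ForwardResult:
    """Intermediates of one forward pass.  Fields hold numpy arrays in
    inference mode and autodiff tensors during training."""

    h1: object            # (N, 2d)
    h2_order1: object     # (N, d)
    h2_order2: object     # (N, d)
    h_final: object       # (N, 2d)
    attention1: tuple     # dense (N, N) coefficient matrices, orders 1 and 2
    attention2: tuple
    context_weights: object  # dense (N, N), rows sum to 1 on nonempty C(i)
    h_bar: object         # (N, 8d)
    logits: object        # (N,)
    probabilities: object  # (N,)


def _masked_softmax(e, mask: np.ndarray):
    """Row-wise softmax of `e` restricted to `mask`; empty rows are all-zero."""
    maskf = mask.astype(np.float64)
    e_data = e.data if isinstance(e, Tensor) else np.asarray(e)
    neg = np.where(mask, e_data, -np.inf)
    rowmax = neg.max(axis=1, keepdims=True, initial=-np.inf)
    rowmax = np.where(np.isfinite(rowmax), rowmax, 0.0)  # constant shift
    num = F.mul(F.exp(F.mul(F.add(e, -rowmax), maskf)), maskf)
    denom = F.reduce_sum(num, axis=1, keepdims=True)
    empty = 1.0 - mask.any(axis=1).astype(np.float64)
    return F.div(num, F.add(denom, empty[:, None]))


def _attention_order(HW, q, mask: np.ndarray, slope: float, uniform: bool):
    """Coefficients alpha_ij over one structural order (Eq.-style
    LeakyReLU(q^T [Wh_i || Wh_j]) scores, softmax-normalized per row)."""
    if uniform:
        counts = mask.sum(axis=1, keepdims=True)
        return mask.astype(np.float64) / np.maximum(counts, 1)
    d = (HW.data if isinstance(HW, Tensor) else HW).shape[1]
    n = (HW.data if isinstance(HW, Tensor) else HW).shape[0]
    u = F.matmul(HW, q[: d] if not isinstance(q, Tensor) else F.take(q, slice(0, d)))
    v = F.matmul(HW, q[d:] if not isinstance(q, Tensor) else F.take(q, slice(d, 2 * d)))
    e = F.leaky_relu(F.add(F.reshape(u, (n, 1)), F.reshape(v, (1, n))), slope)
    return _masked_softmax(e, mask)


def _attention_layer(H, W, q_pair, masks, slope: float, uniform: bool):
    HW = F.matmul(H, F.transpose(W) if isinstance(W, Tensor) else np.asarray(W).T)
    outs, alphas = [], []
    for q, mask in zip(q_pair, masks):
        alpha = _attention_order(HW, q, mask, slope, uniform)
        outs.append(F.relu(F.matmul(alpha, HW)))
        alphas.append(alpha)
    return outs, F.concat(outs, axis=1), tuple(alphas)


def forward(params, features, graph: CorrelationGraph | tuple, *,
            no_second_order: bool = False, no_attention: bool = False,
            no_interaction_module: bool = False) -> ForwardResult:
    """Complete forward pass from node features to probabilities.

    `params` may hold numpy arrays or autodiff tensors; `features` likewise.
    `graph` is a :class:`CorrelationGraph` or a precomputed (M1, M2, C)
    boolean mask triple.  The ablation flags reproduce the simplified
    pipeline variants (empty second order, uniform attention weights, and
    self-pair decoding respectively).
    """
    m1, m2, mc = graph.masks() if isinstance(graph, CorrelationGraph) else graph
    n = m1.shape[0]
    if no_second_order:
        m2 = np.zeros_like(m2)
        mc = m1
    slope = params.leaky_slope

    (h11, h12), h1, attn1 = _attention_layer(
        features, params.W1, (params.q1_order1, params.q1_order2),
        (m1, m2), slope, no_attention)
    (h21, h22), h_final, attn2 = _attention_layer(
        h1, params.W2, (params.q2_order1, params.q2_order2),
        (m1, m2), slope, no_attention)

    if no_interaction_module:
        # decode the self-pair descriptor [h+h || h*h || h || h]
        h_bar = F.concat([F.add(h_final, h_final), F.mul(h_final, h_final),
                          h_final, h_final], axis=1)
        weights = np.zeros((n, n))
    else:
        beta1, beta2 = attn2
        both = m1 & m2
        c1 = 0.5 * both + (m1 & ~m2)
        c2 = 0.5 * both + (m2 & ~m1)
        w_raw = F.add(F.mul(beta1, c1), F.mul(beta2, c2))
        rowsum = F.reduce_sum(w_raw, axis=1, keepdims=True)
        empty = 1.0 - mc.any(axis=1).astype(np.float64)
        weights = F.div(w_raw, F.add(rowsum, empty[:, None]))
        wH = F.matmul(weights, h_final)
        r = F.reduce_sum(weights, axis=1, keepdims=True)
        h_bar = F.concat([F.add(F.mul(r, h_final), wH), F.mul(h_final, wH),
                          F.mul(r, h_final), wH], axis=1)

    dec_W1T = F.transpose(params.dec_W1) if isinstance(params.dec_W1, Tensor) else params.dec_W1.T
    dec_W2T = F.transpose(params.dec_W2) if isinstance(params.dec_W2, Tensor) else params.dec_W2.T
    z = F.relu(F.add(F.matmul(h_bar, dec_W1T), params.dec_b1))
    logits = F.reshape(F.add(F.matmul(z, dec_W2T), params.dec_b2), (n,))
    probs = F.sigmoid(logits)
    return ForwardResult(h1, h21, h22, h_final, attn1, attn2,
                         weights, h_bar, logits, probs)


# ---------------------------------------------------------------------------
# thin per-operation wrappers over the dense internals
# ---------------------------------------------------------------------------

def attention_coefficients(features: np.ndarray, W: np.ndarray, q: np.ndarray,
                           neighborhoods: dict[int, list[int]],
                           leaky_slope: float = 0.2) -> dict[tuple[int, int], float]:
    """Softmax attention coefficients alpha_ij for one structural order,
    as a sparse map (i, j) -> coefficient.  Empty neighborhoods contribute
    no entries."""
    features = np.asarray(features, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if W.shape[1] != features.shape[1] or q.shape[0] != 2 * W.shape[0]:
        raise ValueError("incompatible projection/attention shapes")
    n = features.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    for i, js in neighborhoods.items():
        mask[i, js] = True
    alpha = _attention_order(features @ W.T, q, mask, leaky_slope, uniform=False)
    return {(i, j): float(alpha[i, j]) for i in range(n) for j in np.flatnonzero(mask[i])}


def layer_forward(features: np.ndarray, W: np.ndarray,
                  q_order1: np.ndarray, q_order2: np.ndarray,
                  graph: CorrelationGraph, leaky_slope: float = 0.2):
    """One attention layer: per-order aggregates, their concatenation and
    the dense coefficient matrices."""
    m1, m2, _ = graph.masks()
    outs, h_cat, alphas = _attention_layer(
        np.asarray(features, dtype=np.float64), np.asarray(W),
        (np.asarray(q_order1), np.asarray(q_order2)), (m1, m2),
        leaky_slope, uniform=False)
    return outs[0], outs[1], h_cat, alphas


def pair_descriptor(h_i, h_j) -> np.ndarray:
    """[h_i + h_j || h_i ⊙ h_j || h_i || h_j]; ordered, target-centric."""
    h_i = np.asarray(h_i, dtype=np.float64)
    h_j = np.asarray(h_j, dtype=np.float64)
    if h_i.shape != h_j.shape or h_i.ndim != 1:
        raise ValueError("pair_descriptor expects two equal-length vectors")
    return np.concatenate([h_i + h_j, h_i * h_j, h_i, h_j])


def context_aggregate(h_final: np.ndarray, graph: CorrelationGraph,
                      beta_order1: np.ndarray, beta_order2: np.ndarray):
    """Interaction-aware representations h̄_i = Σ_{j∈C(i)} w_ij h_pair(i, j).

    Raw weights come from the second-layer coefficients (mean of the two
    orders where N1 and N2 overlap) renormalized over C(i); empty contexts
    yield zero rows.  Returns (h_bar, dense weight matrix).
    """
    h_final = np.asarray(h_final, dtype=np.float64)
    m1, m2, mc = graph.masks()
    both = m1 & m2
    w_raw = beta_order1 * (0.5 * both + (m1 & ~m2)) + beta_order2 * (0.5 * both + (m2 & ~m1))
    rowsum = w_raw.sum(axis=1, keepdims=True)
    empty = ~mc.any(axis=1)
    weights = w_raw / np.where(rowsum > 0, rowsum, 1.0)
    wH = weights @ h_final
    r = weights.sum(axis=1, keepdims=True)
    h_bar = np.concatenate([r * h_final + wH, h_final * wH, r * h_final, wH], axis=1)
    h_bar[empty] = 0.0
    return h_bar, weights


def decode(h_bar: np.ndarray, params: ModelParams) -> np.ndarray:
    """Two-layer perceptron probability head: sigmoid(W2 relu(W1 h̄ + b1) + b2)."""
    h_bar = np.atleast_2d(np.asarray(h_bar, dtype=np.float64))
    z = np.maximum(h_bar @ params.dec_W1.T + params.dec_b1, 0.0)
    from scipy.special import expit

    out = expit(z @ params.dec_W2.T + params.dec_b2)
    return out.reshape(-1)


@dataclasses.dataclass
class PredictionResult:
    probabilities: np.ndarray  # (N,) in [0, 1]
    hard_labels: np.ndarray    # (N,) in {0, 1}, 1 iff prob >= delta
    ranking: np.ndarray        # node indices by descending probability
    delta: float


def classify(probabilities: np.ndarray, delta: float = 0.5):
    """Hard labels (prob >= delta) and a ranking by descending probability,
    ties broken by ascending node index."""
    p = np.asarray(probabilities, dtype=np.float64)
    hard = (p >= delta).astype(np.int64)
    ranking = np.lexsort((np.arange(p.size), -p))
    return hard, ranking
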