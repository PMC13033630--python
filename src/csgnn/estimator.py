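"""Sklearn-style estimator tying the full pipeline together.

`CSGNNClassifier.fit(X, y)` takes the raw gene-expression matrix (rows =
proteins, columns = time points) and binary essentiality labels, applies
dynamic-threshold activity filtering, builds the tau-binarized Pearson
co-expression graph, z-scores the features per time point, and trains the
two-layer attention network transductively with an internal stratified
70/10/20 split.  Prediction recomputes the forward pass from the supplied
matrix, so `predict_proba(X_train)` reproduces the fitted probabilities
exactly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .activity import filter_activity
from .evaluation import evaluate_predictions
from .graph import binarize, build_neighborhoods, pearson_similarity, restrict_to_ppi
from .model import PredictionResult, classify, forward
from .training import DataSplit, TrainConfig, apply_ablation, stratified_split, train_model

__all__ = ["CSGNNClassifier"]


class CSGNNClassifier(ClassifierMixin, BaseEstimator):
    """Correlation-guided subgraph attention network for node essentiality.

    Parameters
    ----------
    tau : float, default 0.6
        Strict Pearson-correlation threshold for graph construction.
    d : int, default 64
        Embedding width per structural order.
    d_h : int, default 128
        Decoder hidden width.
    learning_rate, batch_size, weight_decay, epochs,
    scheduler_factor, scheduler_patience :
        AdamW protocol with validation-AUROC plateau halving of the
        learning rate.
    delta : float, default 0.5
        Decision threshold on the predicted probability.
    loss : {'weighted_bce', 'bce'}
        Positive-class-weighted (N_neg/N_pos) or plain cross-entropy.
    threshold_form : {'divide', 'multiply'}
        Algebra of the dynamic-threshold margin.
    graph_mode : {'correlation_only', 'ppi_intersect'}
        Whether to intersect correlation edges with a PPI edge list
        passed to ``fit``.
    no_dynamic_threshold, no_correlation_graph, no_second_order,
    no_attention, no_interaction_module : bool
        Ablation switches for the simplified pipeline variants.
    random_state : int, default 0
        Governs the split, initialization, shuffling and the ablation
        random graph.
    """

    def __init__(self, tau: float = 0.6, d: int = 64, d_h: int = 128,
                 learning_rate: float = 1e-4, batch_size: int = 64,
                 weight_decay: float = 1e-4, epochs: int = 30,
                 scheduler_factor: float = 0.5, scheduler_patience: int = 3,
                 delta: float = 0.5, leaky_slope: float = 0.2,
                 loss: str = "weighted_bce", ddof: int = 0,
                 threshold_form: str = "divide",
                 graph_mode: str = "correlation_only", normalize: bool = True,
                 split_ratios: tuple = (0.70, 0.10, 0.20),
                 no_dynamic_threshold: bool = False,
                 no_correlation_graph: bool = False,
                 no_second_order: bool = False,
                 no_attention: bool = False,
                 no_interaction_module: bool = False,
                 random_state: int = 0):
        self.tau = tau
        self.d = d
        self.d_h = d_h
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.scheduler_factor = scheduler_factor
        self.scheduler_patience = scheduler_patience
        self.delta = delta
        self.leaky_slope = leaky_slope
        self.loss = loss
        self.ddof = ddof
        self.threshold_form = threshold_form
        self.graph_mode = graph_mode
        self.normalize = normalize
        self.split_ratios = split_ratios
        self.no_dynamic_threshold = no_dynamic_threshold
        self.no_correlation_graph = no_correlation_graph
        self.no_second_order = no_second_order
        self.no_attention = no_attention
        self.no_interaction_module = no_interaction_module
        self.random_state = random_state

    # -- pipeline pieces ----------------------------------------------------
    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            weight_decay=self.weight_decay, epochs=self.epochs,
            scheduler_factor=self.scheduler_factor,
            scheduler_patience=self.scheduler_patience,
            seed=self.random_state, delta=self.delta, tau=self.tau,
            d=self.d, d_h=self.d_h, leaky_slope=self.leaky_slope,
            loss=self.loss,
            no_dynamic_threshold=self.no_dynamic_threshold,
            no_correlation_graph=self.no_correlation_graph,
            no_second_order=self.no_second_order,
            no_attention=self.no_attention,
            no_interaction_module=self.no_interaction_module)

    def _activity(self, X: np.ndarray) -> np.ndarray:
        if self.no_dynamic_threshold:
            return np.asarray(X, dtype=np.float64)
        return filter_activity(X, ddof=self.ddof,
                               threshold_form=self.threshold_form).values

    def _build_graph(self, activity: np.ndarray, ppi_edges=None):
        graph = build_neighborhoods(binarize(pearson_similarity(activity), self.tau),
                                    tau=self.tau)
        if self.graph_mode != "correlation_only":
            graph = restrict_to_ppi(graph, ppi_edges if ppi_edges is not None else [],
                                    n_nodes=activity.shape[0], mode=self.graph_mode)
        return graph

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y, ppi_edges=None, split: DataSplit | None = None):
        X, y = check_X_y(X, y, ensure_min_features=2)
        self.classes_ = np.unique(y)
        if not np.isin(self.classes_, [0, 1]).all():
            raise ValueError("labels must be binary {0, 1}")
        y = y.astype(np.int64)
        self.n_features_in_ = X.shape[1]

        activity = self._activity(X)
        self.graph_ = self._build_graph(activity, ppi_edges)

        if self.normalize:
            self.norm_mean_ = activity.mean(axis=0)
            std = activity.std(axis=0)
            self.norm_std_ = np.where(std > 0, std, 1.0)
            features = (activity - self.norm_mean_) / self.norm_std_
        else:
            self.norm_mean_ = np.zeros(X.shape[1])
            self.norm_std_ = np.ones(X.shape[1])
            features = activity

        if split is None:
            split = stratified_split(y, self.split_ratios, seed=self.random_state)
        self.split_ = split

        config = self._train_config()
        self.params_, log = train_model(features, y, self.graph_, split, config)
        self.history_ = log
        finite = [e["val_auroc"] for e in log if np.isfinite(e["val_auroc"])]
        self.best_val_auroc_ = max(finite) if finite else float("nan")

        # fitted transductive graph variant actually used in the forward pass
        self._eval_graph_, self._flags_ = apply_ablation(
            self.graph_, config,
            np.random.default_rng(np.random.SeedSequence(self.random_state).spawn(3)[2]))
        self.probabilities_ = np.asarray(
            forward(self.params_, features, self._eval_graph_.masks(),
                    **self._flags_).probabilities)
        return self

    def _forward_probs(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of time points than at fit")
        activity = self._activity(X)
        graph, _ = apply_ablation(
            self._build_graph(activity), self._train_config(),
            np.random.default_rng(np.random.SeedSequence(self.random_state).spawn(3)[2]))
        features = (activity - self.norm_mean_) / self.norm_std_ if self.normalize else activity
        return np.asarray(forward(self.params_, features, graph.masks(),
                                  **self._flags_).probabilities)

    def predict_proba(self, X) -> np.ndarray:
        p = self._forward_probs(X)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self._forward_probs(X)

    def predict(self, X) -> np.ndarray:
        hard, _ = classify(self._forward_probs(X), self.delta)
        return hard

    def predict_result(self, X=None) -> PredictionResult:
        """Probabilities, hard labels and the descending-score ranking."""
        p = self.probabilities_ if X is None else self._forward_probs(X)
        hard, ranking = classify(p, self.delta)
        return PredictionResult(p, hard, ranking, self.delta)

    def evaluate(self, y, eval_idx=None, n_values=None):
        """Metric suite on the fitted graph: threshold metrics + AUROC on
        `eval_idx` (default: the held-out test split), Top-N on the full
        ranking."""
        check_is_fitted(self)
        if eval_idx is None:
            eval_idx = self.split_.test_idx
        kwargs = {} if n_values is None else {"n_values": n_values}
        result = self.predict_result()
        return evaluate_predictions(result.probabilities, y, eval_idx,
                                    ranking=result.ranking, delta=self.delta,
                                    **kwargs)
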