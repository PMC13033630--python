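"""Dynamic-threshold activity filtering of temporal expression profiles.

A protein's expression trajectory mixes condition-relevant activity with
background fluctuation.  Each row is therefore compared against its own
dynamic threshold

    Threshold_i = mu_i + 2 * sigma_i / (1 + Var_i)

where mu, sigma and Var are the (population) mean, standard deviation and
variance of the profile.  The margin grows with dispersion but is damped by
the ``1 + Var`` factor so that strongly varying trajectories are not
filtered over-aggressively.  Values at or above the threshold are kept,
values below are zeroed, yielding the activity matrix X' used both as node
features and as the basis of the co-expression graph.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ActivityMatrix",
    "ActivityFilter",
    "compute_dynamic_threshold",
    "filter_activity",
]


@dataclasses.dataclass
class ActivityMatrix:
    """Thresholded feature matrix X' with the per-row statistics behind it."""

    node_ids: list[str]
    values: np.ndarray      # (N, M)
    thresholds: np.ndarray  # (N,)
    mean: np.ndarray
    std: np.ndarray
    var: np.ndarray


def _row_stats(values: np.ndarray, ddof: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=ddof)
    return mu, np.sqrt(var), var


def compute_dynamic_threshold(profile, ddof: int = 0,
                              threshold_form: str = "divide") -> float:
    """Threshold for one expression profile.

    ``threshold_form='divide'`` is the standard reading,
    mu + 2*sigma/(1+Var); ``'multiply'`` gives mu + 2*sigma*(1+Var) as an
    escape hatch.  A constant profile has sigma = 0 and returns its mean.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or profile.size < 2:
        raise ValueError("profile must be a 1-D vector with at least 2 time points")
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile contains non-finite values")
    mu = profile.mean()
    var = profile.var(ddof=ddof)
    sigma = np.sqrt(var)
    if threshold_form == "divide":
        return float(mu + 2.0 * sigma / (1.0 + var))
    if threshold_form == "multiply":
        return float(mu + 2.0 * sigma * (1.0 + var))
    raise ValueError(f"unknown threshold_form {threshold_form!r}")


def filter_activity(values: np.ndarray, node_ids: list[str] | None = None,
                    ddof: int = 0, threshold_form: str = "divide") -> ActivityMatrix:
    """Apply the dynamic threshold row-wise: keep x >= Threshold_i, else 0."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("expected an (N, M) matrix with M >= 2")
    if not np.all(np.isfinite(values)):
        bad = np.where(~np.isfinite(values).all(axis=1))[0]
        raise ValueError(f"non-finite expression values in rows {bad.tolist()}")
    if node_ids is None:
        node_ids = [str(i) for i in range(values.shape[0])]

    mu, sigma, var = _row_stats(values, ddof)
    if threshold_form == "divide":
        thresholds = mu + 2.0 * sigma / (1.0 + var)
    elif threshold_form == "multiply":
        thresholds = mu + 2.0 * sigma * (1.0 + var)
    else:
        raise ValueError(f"unknown threshold_form {threshold_form!r}")

    filtered = np.where(values >= thresholds[:, None], values, 0.0)
    return ActivityMatrix(list(node_ids), filtered, thresholds, mu, sigma, var)


class ActivityFilter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :func:`filter_activity`.

    Stateless in the sklearn sense (thresholds are per-row functions of the
    input), so `transform` may be called on any matrix after `fit`.

    Parameters
    ----------
    ddof : int, default 0
        Delta degrees of freedom for the row moments (0 = population).
    threshold_form : {'divide', 'multiply'}, default 'divide'
        Algebra of the adaptive margin.
    """

    def __init__(self, ddof: int = 0, threshold_form: str = "divide"):
        self.ddof = ddof
        self.threshold_form = threshold_form

    def fit(self, X, y=None):
        check_array(X, ensure_min_features=2)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        result = filter_activity(X, ddof=self.ddof, threshold_form=self.threshold_form)
        self.thresholds_ = result.thresholds
        return result.values
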