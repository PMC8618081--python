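"""Imputation metrics, naive baselines and the artificial-masking protocol.

Because the true values behind naturally missing entries are unknowable,
imputation accuracy is measured by removing an extra, exactly counted
fraction of the *observed* test entries completely at random, letting each
method see only the doubly-masked series, and scoring mean absolute error
(MAE, in data units) and symmetric mean absolute percentage error (sMAPE,
in percent) on the artificially removed entries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, DegenerateInputError


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mae_metric(predictions, truths) -> float:
    """Mean absolute error ``(1/B) sum |y_hat - y|``."""
    y_hat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(truths, dtype=float).ravel()
    if y_hat.size == 0 or y_hat.size != y.size:
        raise DegenerateInputError("predictions and truths must be equal nonzero length")
    return float(np.mean(np.abs(y_hat - y)))


def smape_metric(predictions, truths) -> float:
    """Symmetric mean absolute percentage error, in percent.

    ``(1/B) sum |y_hat - y| / ((y_hat + y) / 2) * 100``; a term with
    ``y_hat == y == 0`` contributes 0.  For nonnegative inputs the result
    lies in ``[0, 200]``.
    """
    y_hat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(truths, dtype=float).ravel()
    if y_hat.size == 0 or y_hat.size != y.size:
        raise DegenerateInputError("predictions and truths must be equal nonzero length")
    denom = (y_hat + y) / 2.0
    num = np.abs(y_hat - y)
    terms = np.where(num == 0, 0.0, num / np.where(denom == 0, 1.0, denom))
    return float(np.mean(terms) * 100.0)


# ---------------------------------------------------------------------------
# naive baselines (scikit-learn transformers over NaN-marked matrices)
# ---------------------------------------------------------------------------

class MeanImputer(TransformerMixin, BaseEstimator):
    """Impute every missing entry with the global observed-training mean."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        obs = X[np.isfinite(X)]
        if obs.size == 0:
            raise DegenerateInputError("no observed entries to fit the mean on")
        self.mean_ = float(obs.mean())
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else None
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return np.where(np.isfinite(X), X, self.mean_)


class SpatialAverageImputer(TransformerMixin, BaseEstimator):
    """Impute a missing entry with the same-timestamp mean across stations.

    Each missing entry is replaced by the mean of the *observed* entries of
    its row; a fully missing row falls back to the global observed-training
    mean.  Observed entries pass through unchanged.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        obs = X[np.isfinite(X)]
        if obs.size == 0:
            raise DegenerateInputError("no observed entries to fit the fallback on")
        self.fallback_ = float(obs.mean())
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else None
        return self

    def transform(self, X):
        check_is_fitted(self, "fallback_")
        X = np.asarray(X, dtype=float)
        finite = np.isfinite(X)
        counts = finite.sum(axis=1)
        sums = np.where(finite, X, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row_mean = np.where(counts > 0, sums / np.maximum(counts, 1), self.fallback_)
        return np.where(finite, X, row_mean[:, None])


def mean_baseline(training_values):
    """Thin functional wrapper: a callable imputing with the training mean."""
    imp = MeanImputer().fit(np.asarray(training_values, dtype=float).reshape(-1, 1))
    return lambda X: imp.transform(np.asarray(X, dtype=float))


def spatial_average_baseline(row_values, row_mask, fallback):
    """Impute one row: missing entries get the mean of the row's observed ones."""
    x = np.asarray(row_values, dtype=float)
    m = np.asarray(row_mask, dtype=float)
    n_obs = m.sum()
    fill = (x * m).sum() / n_obs if n_obs > 0 else float(fallback)
    return np.where(m == 1, x, fill)


# ---------------------------------------------------------------------------
# the artificial-masking evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-method MAE/sMAPE on the artificially removed test entries."""

    results: dict = field(default_factory=dict)  # name -> {"mae","smape"} | {"error"}
    n_scored: int = 0
    rate: float = 0.0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            if "error" in res:
                rows.append({"method": name, "mae": np.nan, "smape": np.nan,
                             "error": res["error"]})
            else:
                rows.append({"method": name, "mae": res["mae"],
                             "smape": res["smape"], "error": ""})
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        frame = self.to_frame()
        header = (
            f"artificial-masking protocol: rate={self.rate}, seed={self.seed}, "
            f"n_scored={self.n_scored}\n"
        )
        return header + frame.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def evaluate_protocol(
    test_values: np.ndarray,
    methods: dict,
    extra_rate: float = 0.2,
    seed: int = 0,
) -> EvaluationReport:
    """Score imputation methods under seeded artificial removal.

    Parameters
    ----------
    test_values : ndarray, shape (n_rows, n_stations)
        Test series with NaN at naturally missing positions.
    methods : dict
        Maps a method name to a fitted transformer (``transform(X) -> X``)
        or a bare callable with the same signature.  Each method sees only
        the doubly-masked matrix.
    extra_rate : float
        Fraction of the *observed* entries to remove; exactly
        ``ceil(extra_rate * n_observed)`` entries are flipped.
    seed : int
        Seeds the uniform choice of removed positions.

    Returns
    -------
    EvaluationReport
        MAE and sMAPE per method, computed only on the removed entries.  A
        method that raises is recorded as an error entry; the others are
        still scored.
    """
    X = np.asarray(test_values, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("test_values must be a 2-D matrix")
    if not methods:
        raise ConfigurationError("at least one method is required")
    if not (0 < extra_rate < 1):
        raise ConfigurationError("extra_rate must lie in (0, 1)")
    obs_idx = np.flatnonzero(np.isfinite(X).ravel())
    if obs_idx.size == 0:
        raise DegenerateInputError("test series has no observed entries")
    k = math.ceil(extra_rate * obs_idx.size)
    rng = np.random.default_rng(seed)
    removed = rng.choice(obs_idx, size=k, replace=False)
    masked = X.copy()
    masked.ravel()[removed] = np.nan
    truth = X.ravel()[removed]

    report = EvaluationReport(rate=extra_rate, seed=seed, n_scored=int(k))
    for name, method in methods.items():
        try:
            transform = method.transform if hasattr(method, "transform") else method
            completed = np.asarray(transform(masked), dtype=float)
            if completed.shape != X.shape:
                raise ConfigurationError(
                    f"method {name!r} returned shape {completed.shape}, "
                    f"expected {X.shape}"
                )
            preds = completed.ravel()[removed]
            report.results[name] = {
                "mae": mae_metric(preds, truth),
                "smape": smape_metric(preds, truth),
            }
        except Exception as exc:  # noqa: BLE001 - per-method fault isolation
            report.results[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return report
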