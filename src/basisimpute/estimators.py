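"""Scikit-learn style estimator over the four-block decomposition model.

:class:`BasisDecompositionImputer` is a transformer over 2-D arrays shaped
``(n_time_steps, n_stations)`` with ``NaN`` marking missing entries:
``fit`` runs the self-supervised masked-reconstruction training on windows
cut from the input, ``transform`` fills the missing entries of a (possibly
different) series recorded by the same stations.  It composes with sklearn
pipelines and model selection; the naive baselines in
:mod:`basisimpute.evaluation` share the same transformer contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, DegenerateInputError
from .network import Decomposition, DecompositionNetwork
from .training import TrainConfig, train
from .windows import matrix_to_mask, reassemble_series, window_series


class BasisDecompositionImputer(TransformerMixin, BaseEstimator):
    """Interpretable imputation by sequential bias/slope/seasonality/residual
    elimination.

    Parameters
    ----------
    window_length : int, default 60
        Input horizon T; the model imputes one window at a time (one hour
        at minute cadence).
    hidden_dim : int, default 64
        Hidden width of the three coefficient encoders.
    season_dim, residual_dim : int, defaults 8 and 256
        Coefficient dimensions of the seasonality and residual blocks.
    negative_slope : float, default 0.2
        Leaky-rectifier negative slope.
    integer_grid : bool, default False
        Evaluate the slope/Fourier bases on the raw integer grid (degenerate
        for the Fourier terms; comparison only).
    learning_rate, beta1, beta2, batch_size, drop_rate, shift_prob,
    shift_range, scale_prob, scale_range, patience_epochs, max_epochs :
        Training-protocol knobs; see :class:`basisimpute.training.TrainConfig`.
    val_fraction : float, default 0.2
        Fraction of windows held out (seeded) for early stopping.
    dtype : str, default "float64"
        Parameter dtype; "float32" roughly halves training cost.
    random_state : int, default 42
        Master seed for weight initialisation, the train/validation split
        and every stochastic step of training.
    overwrite_observed : bool, default False
        If True, ``transform`` returns the model output everywhere instead
        of passing observed values through unchanged.
    verbose : int, default 0
        If positive, print one line per epoch.

    Attributes
    ----------
    network_ : DecompositionNetwork
        The trained model (best-validation weights).
    history_ : list of EpochRecord
        Per-epoch train loss and validation masked MAE.
    best_epoch_ : int
    best_val_mae_ : float
        Validation masked MAE of the returned weights.
    n_features_in_ : int
        Number of stations seen during fit.
    """

    def __init__(
        self,
        window_length: int = 60,
        hidden_dim: int = 64,
        season_dim: int = 8,
        residual_dim: int = 256,
        negative_slope: float = 0.2,
        integer_grid: bool = False,
        learning_rate: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        batch_size: int = 512,
        drop_rate: float = 0.2,
        shift_prob: float = 0.25,
        shift_range: tuple = (0.0, 10.0),
        scale_prob: float = 0.25,
        scale_range: tuple = (0.0, 3.0),
        patience_epochs: int = 5,
        max_epochs: int = 200,
        steps_per_epoch: int | None = None,
        val_fraction: float = 0.2,
        dtype: str = "float64",
        random_state: int = 42,
        overwrite_observed: bool = False,
        verbose: int = 0,
    ):
        self.window_length = window_length
        self.hidden_dim = hidden_dim
        self.season_dim = season_dim
        self.residual_dim = residual_dim
        self.negative_slope = negative_slope
        self.integer_grid = integer_grid
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.drop_rate = drop_rate
        self.shift_prob = shift_prob
        self.shift_range = shift_range
        self.scale_prob = scale_prob
        self.scale_range = scale_range
        self.patience_epochs = patience_epochs
        self.max_epochs = max_epochs
        self.steps_per_epoch = steps_per_epoch
        self.val_fraction = val_fraction
        self.dtype = dtype
        self.random_state = random_state
        self.overwrite_observed = overwrite_observed
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            batch_size=self.batch_size,
            patience_epochs=self.patience_epochs,
            drop_rate=self.drop_rate,
            shift_prob=self.shift_prob,
            shift_range=tuple(self.shift_range),
            scale_prob=self.scale_prob,
            scale_range=tuple(self.scale_range),
            seed=self.random_state,
            max_epochs=self.max_epochs,
            steps_per_epoch=self.steps_per_epoch,
        )

    @staticmethod
    def _check_matrix(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ConfigurationError("X must be (n_time_steps, n_stations)")
        if np.isinf(X).any():
            raise ConfigurationError("X may carry NaN for missing, not inf")
        return X

    def fit(self, X, y=None):
        """Train on a NaN-marked series of shape (n_time_steps, n_stations)."""
        X = self._check_matrix(X)
        self.n_features_in_ = X.shape[1]
        values, mask = matrix_to_mask(X)
        win_v, win_m, _ = window_series(values, mask, self.window_length)
        usable = win_m.sum(axis=(1, 2)) > 0
        win_v, win_m = win_v[usable], win_m[usable]
        k = win_v.shape[0]
        if k < 2:
            raise DegenerateInputError(
                "need at least two usable windows to form a train/validation split"
            )
        n_val = max(1, int(round(self.val_fraction * k)))
        order = np.random.default_rng(
            np.random.SeedSequence(entropy=self.random_state, spawn_key=(101,))
        ).permutation(k)
        val_idx, train_idx = order[:n_val], order[n_val:]
        if train_idx.size == 0:
            raise DegenerateInputError("validation split left no training windows")

        self.network_ = DecompositionNetwork(
            n_stations=self.n_features_in_,
            window_length=self.window_length,
            hidden_dim=self.hidden_dim,
            season_dim=self.season_dim,
            residual_dim=self.residual_dim,
            negative_slope=self.negative_slope,
            integer_grid=self.integer_grid,
            dtype=np.dtype(self.dtype),
            random_state=np.random.SeedSequence(
                entropy=self.random_state, spawn_key=(7,)
            ),
        )
        log = print if self.verbose else None
        self.network_, self.history_ = train(
            self.network_,
            win_v[train_idx], win_m[train_idx],
            win_v[val_idx], win_m[val_idx],
            self._train_config(),
            log=log,
        )
        self.best_epoch_ = self.network_.best_epoch_
        self.best_val_mae_ = self.network_.best_val_mae_
        return self

    # ------------------------------------------------------------------

    def _decompose_windows(self, X) -> tuple[Decomposition, list, np.ndarray, np.ndarray]:
        check_is_fitted(self, "network_")
        X = self._check_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ConfigurationError(
                f"X has {X.shape[1]} stations, the model was fit on "
                f"{self.n_features_in_}"
            )
        values, mask = matrix_to_mask(X)
        win_v, win_m, placement = window_series(values, mask, self.window_length)
        dec = self.network_.forward(win_v, win_m)
        return dec, placement, win_v, win_m

    def transform(self, X):
        """Fill the missing entries of a NaN-marked series.

        Observed values pass through bit-exactly unless
        ``overwrite_observed=True``, in which case the model output replaces
        the whole series.
        """
        X = self._check_matrix(X)
        dec, placement, win_v, win_m = self._decompose_windows(X)
        y_hat = reassemble_series(dec.y_hat, placement, X.shape[0])
        if self.overwrite_observed:
            return y_hat
        return np.where(np.isfinite(X), X, y_hat)

    def decompose(self, X) -> pd.DataFrame:
        """Long-format per-window component export.

        One row per ``(window_id, t, station, component)`` with component in
        ``{bias, slope, seasonality, residual, sum, input, mask}`` -- enough
        to redraw the cumulative component picture for any window.
        """
        from .io import decomposition_long_frame

        dec, placement, win_v, win_m = self._decompose_windows(X)
        N = dec.y_hat.shape[2]
        return decomposition_long_frame(dec, win_v, win_m, placement, np.arange(N))

    def _more_tags(self):
        return {"allow_nan": True}
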