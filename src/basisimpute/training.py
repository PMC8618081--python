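"""Self-supervised training of the decomposition network.

The model never sees complete ground truth: at every iteration an extra
fraction of the *observed* entries of each window is dropped from the input,
and the network is trained to reconstruct all originally observed entries
(the freshly dropped ones included -- that is what makes restoration
learnable).  Inputs and targets are jointly shift/scale augmented, the loss
is a masked mean absolute error, optimisation is Adam, and early stopping
watches the masked MAE of restored injected entries on a validation set
whose injection is drawn once with a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, TrainingDivergedError
from .network import DecompositionNetwork


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol.

    Defaults follow the reference protocol for minute-cadence air-quality
    data: Adam with ``lr=1e-5``, ``beta1=0.9``, ``beta2=0.999``, batch size
    512, 20% additional missingness injected per iteration, shift
    augmentation U(0, 10) with probability 0.25, scale augmentation U(0, 3)
    with probability 0.25, early stopping after 5 epochs without validation
    improvement, seed 42.  ``max_epochs`` caps the run.

    ``steps_per_epoch`` controls how many optimiser steps make up an epoch
    (the interval at which validation and patience are assessed).  ``None``
    means one pass over the training windows -- but note that with fewer
    windows than the batch size a pass is a *single* step, which makes
    patience-based stopping fire long before the small learning rate can
    converge; small-data studies therefore set an explicit step count so an
    epoch has comparable weight to one on a production-sized archive.
    """

    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 512
    patience_epochs: int = 5
    drop_rate: float = 0.2
    shift_prob: float = 0.25
    shift_range: tuple[float, float] = (0.0, 10.0)
    scale_prob: float = 0.25
    scale_range: tuple[float, float] = (0.0, 3.0)
    seed: int = 42
    max_epochs: int = 200
    steps_per_epoch: int | None = None

    def validate(self) -> None:
        if not (self.learning_rate > 0 and self.batch_size > 0):
            raise ConfigurationError("learning rate and batch size must be positive")
        if not (0 < self.drop_rate < 1):
            raise ConfigurationError("drop_rate must lie in (0, 1)")
        for p in (self.shift_prob, self.scale_prob):
            if not (0 <= p <= 1):
                raise ConfigurationError("augmentation probabilities must be in [0, 1]")
        if self.patience_epochs < 1 or self.max_epochs < 1:
            raise ConfigurationError("patience and max_epochs must be >= 1")
        if self.steps_per_epoch is not None and self.steps_per_epoch < 1:
            raise ConfigurationError("steps_per_epoch must be >= 1 when set")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shift_range"] = list(self.shift_range)
        d["scale_range"] = list(self.scale_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key in ("shift_range", "scale_range"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def inject_additional_missing(values, mask, rate, rng):
    """Drop an exact fraction of the observed entries of each window.

    For every window, flips exactly ``ceil(rate * n_observed)`` observed
    mask entries to 0, chosen uniformly without replacement.  Accepts a
    single ``(T, N)`` window or a batch ``(B, T, N)``.

    Returns ``(new_mask, injected)`` where ``injected`` marks the newly
    missing positions (a subset of the previously observed ones).  Values
    are untouched -- callers keep the originals as the reconstruction
    target.
    """
    if not (0 < rate < 1):
        raise ConfigurationError("injection rate must lie in (0, 1)")
    mask = np.asarray(mask, dtype=float)
    single = mask.ndim == 2
    batch_mask = mask[None] if single else mask
    new_mask = batch_mask.copy()
    injected = np.zeros_like(batch_mask)
    for i, m in enumerate(batch_mask):
        obs = np.flatnonzero(m.ravel() == 1)
        if obs.size == 0:
            raise DegenerateInputError(
                f"window {i} has no observed entries to inject missingness into"
            )
        k = math.ceil(rate * obs.size)
        chosen = rng.choice(obs, size=k, replace=False)
        # index explicitly: ravel() on a non-C-contiguous row would hand
        # back a copy and silently drop the writes
        rows, cols = np.unravel_index(chosen, m.shape)
        new_mask[i, rows, cols] = 0.0
        injected[i, rows, cols] = 1.0
    if single:
        return new_mask[0], injected[0]
    return new_mask, injected


def augment_shift_scale(input_values, target_values, rng, config: TrainConfig):
    """Jointly shift and/or scale an example's input and target values.

    With probability ``shift_prob`` adds ``s ~ U(*shift_range)`` to every
    value; independently, with probability ``scale_prob`` multiplies every
    value by ``f ~ U(*scale_range)``.  Both transforms apply identically to
    input and target so the reconstruction objective is preserved; masks are
    untouched.  Batched inputs ``(B, T, N)`` draw independently per example.
    """
    inp = np.asarray(input_values, dtype=float)
    tgt = np.asarray(target_values, dtype=float)
    single = inp.ndim == 2
    if single:
        inp, tgt = inp[None], tgt[None]
    B = inp.shape[0]
    do_shift = rng.random(B) < config.shift_prob
    shifts = rng.uniform(*config.shift_range, size=B) * do_shift
    do_scale = rng.random(B) < config.scale_prob
    scales = np.where(do_scale, rng.uniform(*config.scale_range, size=B), 1.0)
    inp = inp * scales[:, None, None] + shifts[:, None, None]
    tgt = tgt * scales[:, None, None] + shifts[:, None, None]
    if single:
        return inp[0], tgt[0]
    return inp, tgt


def masked_mae(y_hat, target, target_mask) -> float:
    """Mean absolute error over positions with ``target_mask == 1``."""
    y_hat = np.asarray(y_hat, dtype=float)
    target = np.asarray(target, dtype=float)
    m = np.asarray(target_mask, dtype=float)
    n = m.sum()
    if n == 0:
        raise DegenerateInputError("masked MAE undefined: no observed entries")
    return float(np.abs((y_hat - target) * m).sum() / n)


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in place)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_mae: float
    epochs_since_improvement: int


def _epoch_rng(seed: int, epoch: int, step: int) -> np.random.Generator:
    # deterministic per-(epoch, step) stream derived from the master seed;
    # epoch -1 is reserved for the one-time validation injection
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(epoch + 1, step))
    )


def train(
    network: DecompositionNetwork,
    train_values: np.ndarray,
    train_mask: np.ndarray,
    val_values: np.ndarray,
    val_mask: np.ndarray,
    config: TrainConfig | None = None,
    log=None,
) -> tuple[DecompositionNetwork, list[EpochRecord]]:
    """Run the masked-reconstruction training loop.

    Parameters
    ----------
    network : DecompositionNetwork
        Model to train in place; the best-validation weights are restored
        before returning.
    train_values, train_mask : ndarray, shape (n_windows, T, N)
        Training windows with their natural observation masks.
    val_values, val_mask : ndarray, shape (m_windows, T, N)
        Validation windows.  A one-time seeded injection (same drop rate)
        defines the early-stopping metric: masked MAE of the restored
        injected entries.
    config : TrainConfig, optional
    log : callable, optional
        Called with one formatted line per epoch.

    Returns
    -------
    (network, history)
        The network carrying the best-validation weights, and per-epoch
        records.

    Raises
    ------
    TrainingDivergedError
        If the loss becomes non-finite.
    """
    config = config or TrainConfig()
    config.validate()
    train_values = np.asarray(train_values, dtype=float)
    train_mask = np.asarray(train_mask, dtype=float)
    if train_values.ndim != 3 or train_values.shape[0] == 0:
        raise ConfigurationError("train_values must be a nonempty (n, T, N) array")
    if val_values is None or np.asarray(val_values).shape[0] == 0:
        raise ConfigurationError("a nonempty validation set is required")

    val_values = np.asarray(val_values, dtype=float)
    val_mask = np.asarray(val_mask, dtype=float)
    val_rng = _epoch_rng(config.seed, -1, 0)
    val_input_mask, val_injected = inject_additional_missing(
        val_values, val_mask, config.drop_rate, val_rng
    )

    opt = Adam(network.parameters(), config.learning_rate, config.beta1, config.beta2)
    best_val = np.inf
    best_params = network.copy_parameters()
    best_epoch = -1
    since = 0
    history: list[EpochRecord] = []
    n = train_values.shape[0]

    batch = min(config.batch_size, n)
    # an "epoch" is one pass over the training windows unless steps_per_epoch
    # overrides it: each training example is freshly augmented and injected,
    # so the effective sample is unbounded and the epoch is really the
    # interval at which validation (and hence patience) is assessed
    steps_per_epoch = (
        config.steps_per_epoch
        if config.steps_per_epoch is not None
        else math.ceil(n / batch)
    )

    for epoch in range(config.max_epochs):
        epoch_losses = []
        for step in range(steps_per_epoch):
            rng = _epoch_rng(config.seed, epoch, step + 1)
            idx = rng.choice(n, size=batch, replace=False)
            inp, tgt = augment_shift_scale(
                train_values[idx], train_values[idx], rng, config
            )
            input_mask, _ = inject_additional_missing(
                inp, train_mask[idx], config.drop_rate, rng
            )
            loss, grads = network.loss_and_gradients(
                inp, input_mask, tgt, train_mask[idx]
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step}"
                )
            opt.step(grads)
            epoch_losses.append(loss)

        dec = network.forward(val_values, val_input_mask)
        val_score = masked_mae(dec.y_hat, val_values, val_injected)
        if not np.isfinite(val_score):
            raise TrainingDivergedError(f"non-finite validation score at epoch {epoch}")
        if val_score < best_val:
            best_val = val_score
            best_params = network.copy_parameters()
            best_epoch = epoch
            since = 0
        else:
            since += 1
        rec = EpochRecord(epoch, float(np.mean(epoch_losses)), val_score, since)
        history.append(rec)
        if log is not None:
            log(
                f"epoch {epoch:5d}  train_loss {rec.train_loss:.6f}  "
                f"val_mae {rec.val_mae:.6f}  since_improvement {since}"
            )
        if since >= config.patience_epochs:
            break

    network.set_parameters(best_params)
    network.best_epoch_ = best_epoch
    network.best_val_mae_ = float(best_val)
    return network, history
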