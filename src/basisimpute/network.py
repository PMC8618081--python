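"""Four-block decomposition network for spatio-temporal imputation.

The network imputes a ``T x N`` window (T time steps, N stations) by
sequentially *eliminating* four interpretable components from its input:

1. **bias** -- the per-station mean of the observed entries (closed form, no
   learned weights);
2. **slope** -- a shared linear trend ``theta2 * v`` on the centred window
   grid, with the scalar ``theta2`` produced by a coefficient encoder;
3. **seasonality** -- a shared four-harmonic Fourier curve whose 8
   coefficients come from a second encoder;
4. **residual** -- a free-form ``T x N`` matrix produced by a third encoder
   followed by an affine head.

Each coefficient encoder is five fully connected layers (hidden width 64,
leaky-rectifier nonlinearity with negative slope 0.2 after the first four)
applied to the flattened output of the previous block.  The sum of the four
eliminated components is the imputation ``y_hat``; what remains after all
subtractions (``x_final``) is driven towards zero by training.

Missing entries are filled with the station bias before the first
subtraction, so the encoders see exactly 0 at missing positions and the mask
never needs to be fed to them.

The forward pass, the masked-MAE loss gradient and the Adam update are all
implemented directly on numpy arrays; the backward pass is verified against
central-difference gradients in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .basis import TimeBasis, fourier_design, make_time_basis, slope_basis
from .errors import ConfigurationError, DegenerateInputError

HIDDEN_DIM = 64
SEASON_DIM = 8
RESIDUAL_DIM = 256
NEGATIVE_SLOPE = 0.2
N_ENCODER_LAYERS = 5


# ---------------------------------------------------------------------------
# closed-form bias block
# ---------------------------------------------------------------------------

def compute_bias(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-station mean of observed entries, the model's first component.

    Accepts a single window ``(T, N)`` or a batch ``(B, T, N)``; returns an
    ``(N,)`` or ``(B, N)`` array.  A station with no observed entry in the
    window gets bias 0 (a neutral value: its post-bias representation is then
    exactly zero).  A window with no observed entry at all is an error.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=float)
    single = values.ndim == 2
    if single:
        values, mask = values[None], mask[None]
    counts = mask.sum(axis=1)  # (B, N)
    if (counts.sum(axis=1) == 0).any():
        bad = int(np.flatnonzero(counts.sum(axis=1) == 0)[0])
        raise DegenerateInputError(
            f"window {bad} has no observed entries; cannot estimate bias"
        )
    sums = (values * mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        bias = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), 0.0)
    return bias[0] if single else bias


# ---------------------------------------------------------------------------
# elementary layers
# ---------------------------------------------------------------------------

def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


def _leaky_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, 1.0, slope)


def _mlp_forward(layers, x, slope):
    """Five affine maps with the leaky rectifier after the first four."""
    acts = [x]
    pre = []
    a = x
    for k, (W, b) in enumerate(layers):
        z = a @ W + b
        pre.append(z)
        a = _leaky(z, slope) if k < len(layers) - 1 else z
        acts.append(a)
    return a, (acts, pre)


def _mlp_backward(layers, cache, d_out, slope):
    """Return (per-layer (dW, db) list, gradient w.r.t. the input)."""
    acts, pre = cache
    grads = [None] * len(layers)
    da = d_out
    for k in range(len(layers) - 1, -1, -1):
        W, _ = layers[k]
        dz = da if k == len(layers) - 1 else da * _leaky_grad(pre[k], slope)
        grads[k] = (acts[k].T @ dz, dz.sum(axis=0))
        da = dz @ W.T
    return grads, da


# ---------------------------------------------------------------------------
# decomposition container
# ---------------------------------------------------------------------------

@dataclass
class Decomposition:
    """All four eliminated components of a window (or batch of windows).

    ``y_hat`` is their broadcast sum -- the imputation; ``x_final`` is the
    bias-filled input minus ``y_hat``, i.e. what the model failed to
    eliminate.  Shapes are unbatched (``(N,)``, ``(T,)``, ``(T, N)``) when
    built from a single window, batched with a leading axis otherwise.
    """

    h_bias: np.ndarray
    h_slope: np.ndarray
    h_season: np.ndarray
    h_resid: np.ndarray
    y_hat: np.ndarray
    x_final: np.ndarray

    COMPONENTS = ("bias", "slope", "seasonality", "residual")

    def component_matrices(self) -> dict[str, np.ndarray]:
        """Each component broadcast to full ``(..., T, N)`` shape."""
        T = self.h_slope.shape[-1]
        N = self.h_bias.shape[-1]
        bias = np.broadcast_to(self.h_bias[..., None, :], self.h_resid.shape)
        slope = np.broadcast_to(self.h_slope[..., :, None], self.h_resid.shape)
        season = np.broadcast_to(self.h_season[..., :, None], self.h_resid.shape)
        assert bias.shape[-2:] == (T, N)
        return {
            "bias": bias,
            "slope": slope,
            "seasonality": season,
            "residual": self.h_resid,
        }


class DecompositionNetwork:
    """The learnable four-block imputation model.

    Parameters
    ----------
    n_stations : int
        Number of parallel series N the model is shaped for.
    window_length : int
        Even input horizon T (default 60: one hour at minute cadence).
    hidden_dim : int
        Width of the encoder hidden layers (default 64).
    season_dim, residual_dim : int
        Coefficient dimensions of the seasonality and residual blocks
        (defaults 8 and 256).
    negative_slope : float
        Leaky-rectifier negative slope (default 0.2).
    integer_grid : bool
        Evaluate the slope/Fourier bases on the raw integer grid instead of
        the normalised one.  On the integer grid the Fourier basis is
        degenerate (sines vanish); provided for comparison only.
    dtype : numpy dtype
        Parameter dtype.  float64 by default; float32 roughly halves the
        cost of a training step.
    random_state : int or numpy Generator, optional
        Seeds the weight initialisation.

    Notes
    -----
    Hidden weights (and the residual head) use He-style initialisation
    scaled for the leaky rectifier.  The *final* affine map of every
    encoder starts at zero, so every coefficient -- and hence every learned
    component -- is exactly zero at initialisation: a fresh model is the
    per-station masked-mean imputer, and the learned blocks grow away from
    zero during training.
    """

    def __init__(
        self,
        n_stations: int,
        window_length: int = 60,
        hidden_dim: int = HIDDEN_DIM,
        season_dim: int = SEASON_DIM,
        residual_dim: int = RESIDUAL_DIM,
        negative_slope: float = NEGATIVE_SLOPE,
        integer_grid: bool = False,
        dtype=np.float64,
        random_state=None,
    ):
        if n_stations < 1:
            raise ConfigurationError("n_stations must be positive")
        self.n_stations = int(n_stations)
        self.basis: TimeBasis = make_time_basis(window_length)
        self.window_length = self.basis.T
        self.hidden_dim = int(hidden_dim)
        self.season_dim = int(season_dim)
        self.residual_dim = int(residual_dim)
        self.negative_slope = float(negative_slope)
        self.integer_grid = bool(integer_grid)
        self.dtype = np.dtype(dtype)
        self._v = slope_basis(self.basis, integer_grid).astype(self.dtype)
        self._F = fourier_design(self.basis, integer_grid).astype(self.dtype)
        rng = np.random.default_rng(random_state)
        D = self.window_length * self.n_stations
        self.encoders = {
            "slope": self._init_mlp(rng, D, 1),
            "season": self._init_mlp(rng, D, self.season_dim),
            "residual": self._init_mlp(rng, D, self.residual_dim),
        }
        # residual head: theta4 -> flattened T x N matrix.  The head weight
        # is randomly initialised while the encoder's final layer is zero:
        # theta4 = 0 still makes h_resid exactly 0 at initialisation, but a
        # zero head would deadlock the block (with u = leaky(theta4) = 0
        # both dW_head = u^T G and the gradient reaching the encoder are
        # identically zero, freezing the residual block forever).
        head_std = np.sqrt(
            (2.0 / (1.0 + self.negative_slope**2)) / self.residual_dim
        )
        self.head = [
            rng.normal(0.0, head_std, size=(self.residual_dim, D)).astype(self.dtype),
            np.zeros(D, dtype=self.dtype),
        ]

    def _init_mlp(self, rng, in_dim, out_dim):
        dims = [in_dim] + [self.hidden_dim] * (N_ENCODER_LAYERS - 1) + [out_dim]
        gain = 2.0 / (1.0 + self.negative_slope**2)
        layers = []
        for k in range(N_ENCODER_LAYERS):
            if k == N_ENCODER_LAYERS - 1:
                W = np.zeros((dims[k], dims[k + 1]), dtype=self.dtype)
            else:
                std = np.sqrt(gain / dims[k])
                W = rng.normal(0.0, std, size=(dims[k], dims[k + 1])).astype(self.dtype)
            layers.append([W, np.zeros(dims[k + 1], dtype=self.dtype)])
        return layers

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        """Flat list of parameter arrays in a fixed, documented order."""
        params = []
        for name in ("slope", "season", "residual"):
            for W, b in self.encoders[name]:
                params.extend([W, b])
        params.extend(self.head)
        return params

    def set_parameters(self, arrays) -> None:
        for own, new in zip(self.parameters(), arrays):
            if own.shape != new.shape:
                raise ConfigurationError(
                    f"parameter shape mismatch: {own.shape} vs {new.shape}"
                )
            own[...] = new

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    # -- forward ------------------------------------------------------------

    def encode_coefficients(self, x_prev: np.ndarray, block: str) -> np.ndarray:
        """Run one coefficient encoder on (a batch of) flattened windows."""
        x = np.asarray(x_prev, dtype=self.dtype)
        single = x.ndim == 2
        flat = x.reshape(1 if single else x.shape[0], -1)
        D = self.window_length * self.n_stations
        if flat.shape[1] != D:
            raise ConfigurationError(
                f"encoder input dimension {flat.shape[1]} != T*N = {D}"
            )
        theta, _ = _mlp_forward(self.encoders[block], flat, self.negative_slope)
        return theta[0] if single else theta

    def slope_component(self, theta_slope) -> np.ndarray:
        """``theta2 * v`` on the model's grid; shape (T,) or (B, T)."""
        theta = np.asarray(theta_slope, dtype=self.dtype)
        if theta.ndim == 0:
            return float(theta) * self._v
        return theta.reshape(-1, 1) * self._v[None, :]

    def seasonality_component(self, theta_season) -> np.ndarray:
        """Four-harmonic Fourier curve; shape (T,) or (B, T)."""
        theta = np.asarray(theta_season, dtype=self.dtype)
        return theta @ self._F.T

    def residual_component(self, theta_resid) -> np.ndarray:
        """Leaky rectifier then affine head, reshaped to (T, N) / (B, T, N)."""
        theta = np.asarray(theta_resid, dtype=self.dtype)
        W, b = self.head
        if W.shape[0] != theta.shape[-1]:
            raise ConfigurationError(
                f"residual head expects dim {W.shape[0]}, got {theta.shape[-1]}"
            )
        single = theta.ndim == 1
        u = _leaky(theta.reshape(1 if single else theta.shape[0], -1),
                   self.negative_slope)
        r = (u @ W + b).reshape(-1, self.window_length, self.n_stations)
        return r[0] if single else r

    def forward(self, values: np.ndarray, mask: np.ndarray) -> Decomposition:
        """Decompose (a batch of) windows into the four components."""
        dec, _ = self._forward_cached(values, mask)
        return dec

    def _forward_cached(self, values, mask):
        values = np.asarray(values, dtype=self.dtype)
        mask = np.asarray(mask, dtype=self.dtype)
        single = values.ndim == 2
        if single:
            values, mask = values[None], mask[None]
        B, T, N = values.shape
        if (T, N) != (self.window_length, self.n_stations):
            raise ConfigurationError(
                f"window shape {(T, N)} does not match model "
                f"({self.window_length}, {self.n_stations})"
            )
        bias = compute_bias(values, mask).astype(self.dtype)  # (B, N)
        filled = np.where(mask == 1, values, bias[:, None, :])
        X1 = filled - bias[:, None, :]  # exactly 0 at missing positions

        th2, c2 = _mlp_forward(self.encoders["slope"], X1.reshape(B, -1),
                               self.negative_slope)
        h_slope = th2 * self._v[None, :]  # (B,1)*(T,) -> (B, T)
        X2 = X1 - h_slope[:, :, None]

        th3, c3 = _mlp_forward(self.encoders["season"], X2.reshape(B, -1),
                               self.negative_slope)
        h_season = th3 @ self._F.T
        X3 = X2 - h_season[:, :, None]

        th4, c4 = _mlp_forward(self.encoders["residual"], X3.reshape(B, -1),
                               self.negative_slope)
        u = _leaky(th4, self.negative_slope)
        W6, b6 = self.head
        h_resid = (u @ W6 + b6).reshape(B, T, N)
        X4 = X3 - h_resid

        y_hat = bias[:, None, :] + h_slope[:, :, None] + h_season[:, :, None] + h_resid
        dec = Decomposition(
            h_bias=bias[0] if single else bias,
            h_slope=h_slope[0] if single else h_slope,
            h_season=h_season[0] if single else h_season,
            h_resid=h_resid[0] if single else h_resid,
            y_hat=y_hat[0] if single else y_hat,
            x_final=X4[0] if single else X4,
        )
        cache = (c2, c3, c4, th4, u, y_hat, B)
        return dec, cache

    # -- loss and gradients -------------------------------------------------

    def loss_and_gradients(self, values, mask, target, target_mask):
        """Masked-MAE loss and its gradient for every parameter.

        The loss is the mean absolute difference between ``y_hat`` and
        ``target`` over positions with ``target_mask == 1`` (summed over the
        whole batch).  Returns ``(loss, grads)`` with ``grads`` aligned with
        :meth:`parameters`.
        """
        values = np.asarray(values, dtype=self.dtype)
        mask = np.asarray(mask, dtype=self.dtype)
        target = np.asarray(target, dtype=self.dtype)
        tmask = np.asarray(target_mask, dtype=self.dtype)
        if values.ndim == 2:
            values, mask = values[None], mask[None]
            target, tmask = target[None], tmask[None]
        dec, cache = self._forward_cached(values, mask)
        c2, c3, c4, th4, u, y_hat, B = cache
        n_obs = tmask.sum()
        if n_obs == 0:
            raise DegenerateInputError("no observed target entries for the loss")
        diff = y_hat - target
        loss = float(np.abs(diff * tmask).sum() / n_obs)

        G = tmask * np.sign(diff) / n_obs  # dL / d y_hat, (B, T, N)
        slope = self.negative_slope
        W6, _ = self.head

        # residual head
        G_flat = G.reshape(B, -1)
        dW6 = u.T @ G_flat
        db6 = G_flat.sum(axis=0)
        du = G_flat @ W6.T
        dth4 = du * _leaky_grad(th4, slope)
        g_resid, dX3_flat = _mlp_backward(self.encoders["residual"], c4, dth4, slope)
        dX3 = dX3_flat.reshape(G.shape)

        # seasonality: appears in y_hat (+) and in X3 (-) feeding the
        # residual encoder
        dh_season = G.sum(axis=2) - dX3.sum(axis=2)  # (B, T)
        dth3 = dh_season @ self._F
        g_season, dX2_enc = _mlp_backward(self.encoders["season"], c3, dth3, slope)
        dX2 = dX3 + dX2_enc.reshape(G.shape)

        # slope: appears in y_hat (+) and in X2 (-) feeding the season encoder
        dh_slope = G.sum(axis=2) - dX2.sum(axis=2)  # (B, T)
        dth2 = (dh_slope * self._v[None, :]).sum(axis=1, keepdims=True)
        g_slope, _ = _mlp_backward(self.encoders["slope"], c2, dth2, slope)

        grads = []
        for block_grads in (g_slope, g_season, g_resid):
            for dW, db in block_grads:
                grads.extend([dW, db])
        grads.extend([dW6, db6])
        return loss, grads

    # -- persistence ----------------------------------------------------

    def _metadata(self) -> dict:
        return {
            "n_stations": self.n_stations,
            "window_length": self.window_length,
            "hidden_dim": self.hidden_dim,
            "season_dim": self.season_dim,
            "residual_dim": self.residual_dim,
            "negative_slope": self.negative_slope,
            "integer_grid": self.integer_grid,
            "dtype": self.dtype.name,
        }

    def save(self, path) -> None:
        """Write all weights plus shape metadata to a single ``.npz`` archive."""
        arrays = {}
        for name in ("slope", "season", "residual"):
            for k, (W, b) in enumerate(self.encoders[name], start=1):
                arrays[f"{name}_W{k}"] = W
                arrays[f"{name}_b{k}"] = b
        arrays["head_W"], arrays["head_b"] = self.head
        arrays["metadata"] = np.frombuffer(
            json.dumps(self._metadata()).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "DecompositionNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["metadata"]).decode())
            net = cls(
                n_stations=meta["n_stations"],
                window_length=meta["window_length"],
                hidden_dim=meta["hidden_dim"],
                season_dim=meta["season_dim"],
                residual_dim=meta["residual_dim"],
                negative_slope=meta["negative_slope"],
                integer_grid=meta["integer_grid"],
                dtype=meta["dtype"],
            )
            for name in ("slope", "season", "residual"):
                for k in range(1, N_ENCODER_LAYERS + 1):
                    W = data[f"{name}_W{k}"]
                    b = data[f"{name}_b{k}"]
                    if net.encoders[name][k - 1][0].shape != W.shape:
                        raise ConfigurationError(
                            f"checkpoint layer {name}/{k} has shape "
                            f"{W.shape}, expected "
                            f"{net.encoders[name][k - 1][0].shape}"
                        )
                    net.encoders[name][k - 1][0][...] = W
                    net.encoders[name][k - 1][1][...] = b
            net.head[0][...] = data["head_W"]
            net.head[1][...] = data["head_b"]
        return net
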