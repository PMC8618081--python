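"""Fixed time-grid bases shared by the slope and seasonality blocks.

The model evaluates its linear and Fourier bases on a centred window grid
``v_raw = [-T/2, ..., T/2 - 1]``.  Because sines and cosines of ``2*pi*i*t``
are degenerate on an integer grid (the sines vanish, the cosines are 1), the
bases are evaluated by default on the normalised grid ``v_norm = v_raw / T``,
which gives the four harmonics periods of ``T, T/2, T/3, T/4`` time steps.
The literal integer grid remains available behind ``integer_grid=True`` for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

#: number of sine/cosine harmonic pairs in the seasonality block
N_HARMONICS = 4


@dataclass(frozen=True)
class TimeBasis:
    """Centred time-horizon grid for a window of length ``T``.

    Attributes
    ----------
    T : int
        Window length (even, >= 2).
    v_raw : ndarray of int, shape (T,)
        ``[-T/2, -T/2 + 1, ..., T/2 - 1]``; zero sits at index ``T//2``.
    v_norm : ndarray of float, shape (T,)
        ``v_raw / T``; entries lie in ``[-0.5, 0.5)``.
    """

    T: int
    v_raw: np.ndarray
    v_norm: np.ndarray


def make_time_basis(T: int) -> TimeBasis:
    """Build the centred window grid for an even horizon ``T``.

    Raises
    ------
    ConfigurationError
        If ``T`` is not a positive even integer >= 2.
    """
    if not isinstance(T, (int, np.integer)) or T < 2 or T % 2 != 0:
        raise ConfigurationError(
            f"window length must be an even integer >= 2, got {T!r}"
        )
    v_raw = np.arange(-T // 2, T // 2, dtype=np.int64)
    v_norm = v_raw / float(T)
    return TimeBasis(T=int(T), v_raw=v_raw, v_norm=v_norm)


def slope_basis(basis: TimeBasis, integer_grid: bool = False) -> np.ndarray:
    """Return the T-vector the slope coefficient multiplies."""
    return basis.v_raw.astype(float) if integer_grid else basis.v_norm


def fourier_design(basis: TimeBasis, integer_grid: bool = False) -> np.ndarray:
    """Design matrix of the seasonality block, shape ``(T, 2 * N_HARMONICS)``.

    Column ``2i - 2`` is ``sin(2*pi*i*v)`` and column ``2i - 1`` is
    ``cos(2*pi*i*v)`` for harmonic ``i = 1..N_HARMONICS``, so an 8-vector of
    coefficients pairs up as ``(a_1, b_1, ..., a_4, b_4)``.
    """
    v = slope_basis(basis, integer_grid=integer_grid)
    cols = []
    for i in range(1, N_HARMONICS + 1):
        cols.append(np.sin(2.0 * np.pi * i * v))
        cols.append(np.cos(2.0 * np.pi * i * v))
    return np.stack(cols, axis=1)
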