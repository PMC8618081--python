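"""The model's unit of work: fixed-length windows of a multi-station series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError


@dataclass
class Window:
    """A ``T x N`` slice of a multi-station series with its observation mask.

    ``values`` may carry arbitrary placeholders (e.g. 0 or NaN) wherever
    ``mask`` is 0; every entry at ``mask == 1`` must be finite.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.ndim != 2:
            raise ConfigurationError("window values must be a T x N matrix")
        if self.values.shape != self.mask.shape:
            raise ConfigurationError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ConfigurationError("mask entries must be exactly 0 or 1")
        self.mask = self.mask.astype(float)
        if not np.isfinite(self.values[self.mask == 1]).all():
            raise ConfigurationError("observed entries must be finite")

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def n_stations(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


def matrix_to_mask(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a matrix with NaN markers into (zero-filled values, mask)."""
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X).astype(float)
    return np.where(mask == 1, X, 0.0), mask


def window_series(
    values: np.ndarray, mask: np.ndarray, T: int
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Cut a full-length series into consecutive non-overlapping windows.

    Returns stacked arrays ``(k, T, N)`` plus a placement index: for each
    window, ``(start_row, novel_from)`` where rows ``start_row + novel_from``
    onward are the rows this window is responsible for on reassembly.  A
    trailing remainder shorter than ``T`` is covered by one extra window made
    of the final ``T`` rows, responsible only for its novel tail.

    Raises
    ------
    DegenerateInputError
        If the series is shorter than ``T``.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=float)
    n = values.shape[0]
    if n < T:
        raise DegenerateInputError(f"series of length {n} is shorter than T={T}")
    starts = list(range(0, n - T + 1, T))
    placement = [(s, 0) for s in starts]
    covered = starts[-1] + T
    if covered < n:
        tail_start = n - T
        placement.append((tail_start, covered - tail_start))
    win_values = np.stack([values[s : s + T] for s, _ in placement])
    win_mask = np.stack([mask[s : s + T] for s, _ in placement])
    return win_values, win_mask, placement


def reassemble_series(
    windows: np.ndarray, placement: list[tuple[int, int]], length: int
) -> np.ndarray:
    """Invert :func:`window_series` for windows of shape ``(k, T, N)``."""
    T = windows.shape[1]
    out = np.empty((length, windows.shape[2]), dtype=float)
    for w, (start, novel_from) in zip(windows, placement):
        out[start + novel_from : start + T] = w[novel_from:]
    return out
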