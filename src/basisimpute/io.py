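"""Wide-CSV reading/writing and whole-series imputation plumbing.

The on-disk dialect is a comma-separated table whose first column holds
ISO-8601 timestamps at a uniform cadence and whose remaining columns are
stations; blank cells (or configurable sentinels such as ``-999``) mark
missing values.  Tables with absent rows are densified to the declared
cadence with fully missing rows inserted, so downstream windowing can
assume uniform spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError
from .network import DecompositionNetwork
from .windows import matrix_to_mask, reassemble_series, window_series

DEFAULT_SENTINELS = ("NA", "NaN", "nan", "-999")


@dataclass
class ParseReport:
    rows_read: int
    rows_densified: int
    cells_missing: int


@dataclass
class SeriesTable:
    """A wide multi-station series with a uniform timestamp index."""

    frame: pd.DataFrame  # DatetimeIndex x station columns, NaN = missing

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def station_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values).astype(float)


def read_series_csv(
    path,
    cadence: str = "1min",
    sentinels=DEFAULT_SENTINELS,
) -> tuple[SeriesTable, ParseReport]:
    """Read a wide CSV into a :class:`SeriesTable`.

    Blank cells and any value in ``sentinels`` become missing; rows absent
    at the declared cadence are inserted as fully missing.

    Raises
    ------
    ConfigurationError
        On unparseable timestamps or values (with row/column context) and on
        an empty file.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ConfigurationError(f"{path}: empty file") from None
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ConfigurationError(
            f"{path}: need a timestamp column plus at least one station"
        )
    ts_col = raw.columns[0]
    try:
        index = pd.DatetimeIndex(pd.to_datetime(raw[ts_col], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"{path}: unparseable timestamp: {exc}") from None
    if not index.is_monotonic_increasing or index.has_duplicates:
        raise ConfigurationError(f"{path}: timestamps must be strictly increasing")

    data = raw.drop(columns=[ts_col]).replace(list(sentinels) + [""], np.nan)
    try:
        frame = data.astype(float)
    except ValueError:
        for col in data.columns:
            bad = pd.to_numeric(data[col], errors="coerce").isna() & data[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ConfigurationError(
                    f"{path}: unparseable value {data[col].iloc[row]!r} "
                    f"at row {row + 2}, column {col!r}"
                ) from None
        raise
    frame.index = index
    rows_read = len(frame)

    full_index = pd.date_range(index[0], index[-1], freq=cadence)
    if not index.equals(full_index):
        if not index.isin(full_index).all():
            raise ConfigurationError(
                f"{path}: timestamps do not align to the {cadence} cadence"
            )
        frame = frame.reindex(full_index)
    report = ParseReport(
        rows_read=rows_read,
        rows_densified=len(frame) - rows_read,
        cells_missing=int(frame.isna().to_numpy().sum()),
    )
    return SeriesTable(frame=frame), report


def write_series_csv(table: SeriesTable, path) -> None:
    """Write a :class:`SeriesTable` back to the wide dialect (blank = missing)."""
    out = table.frame.copy()
    out.index.name = "timestamp"
    out.to_csv(path, na_rep="")


def table_from_values(values, station_ids=None, start="2020-01-01",
                      cadence: str = "1min") -> SeriesTable:
    """Wrap a ``(n, N)`` NaN-marked array as a :class:`SeriesTable`."""
    values = np.asarray(values, dtype=float)
    n, N = values.shape
    cols = station_ids if station_ids is not None else [f"S{j:02d}" for j in range(N)]
    index = pd.date_range(start, periods=n, freq=cadence)
    return SeriesTable(frame=pd.DataFrame(values, index=index, columns=list(cols)))


def decomposition_long_frame(dec, win_v, win_m, placement, station_ids) -> pd.DataFrame:
    """Long-format component export: one row per (window, t, station, component).

    Components are ``bias, slope, seasonality, residual, sum, input, mask``;
    ``input`` carries NaN at unobserved positions.  ``t`` is the absolute row
    of the source table, so cumulative component plots can be redrawn
    directly from this frame.
    """
    comp = dec.component_matrices()
    k, T, N = dec.y_hat.shape
    t_idx = np.repeat(np.arange(T), N)
    s_idx = np.tile(np.asarray(station_ids), T)
    layers = {**comp, "sum": dec.y_hat,
              "input": np.where(win_m == 1, win_v, np.nan), "mask": win_m}
    frames = []
    for w in range(k):
        start, _ = placement[w]
        for name, arr in layers.items():
            frames.append(pd.DataFrame({
                "window_id": w,
                "t": t_idx + start,
                "station": s_idx,
                "component": name,
                "value": arr[w].ravel(),
            }))
    return pd.concat(frames, ignore_index=True)


def impute_series(
    table: SeriesTable,
    network: DecompositionNetwork,
    overwrite_observed: bool = False,
) -> tuple[SeriesTable, pd.DataFrame]:
    """Impute a whole series with a trained network, window by window.

    Returns the completed table (observed values pass through unchanged
    unless ``overwrite_observed``) and the long-format decomposition export
    with columns ``(window_id, t, station, component, value)`` where
    component is one of ``bias, slope, seasonality, residual, sum, input,
    mask``.
    """
    if len(table.station_ids) != network.n_stations:
        raise ConfigurationError(
            f"table has {len(table.station_ids)} stations, checkpoint expects "
            f"{network.n_stations}"
        )
    values, mask = matrix_to_mask(table.values)
    win_v, win_m, placement = window_series(values, mask, network.window_length)
    dec = network.forward(win_v, win_m)
    y_hat = reassemble_series(dec.y_hat, placement, values.shape[0])
    raw = table.values
    completed = y_hat if overwrite_observed else np.where(np.isfinite(raw), raw, y_hat)
    out = SeriesTable(frame=pd.DataFrame(
        completed, index=table.timestamps, columns=table.station_ids
    ))
    export = decomposition_long_frame(dec, win_v, win_m, placement, table.station_ids)
    return out, export
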