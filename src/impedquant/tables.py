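"""Peak-table conventions.

A *peak table* is a :class:`pandas.DataFrame` with one row per detected (or
simulated) bead event and columns

``amp_f1 .. amp_fN``
    per-channel peak amplitudes in volts (N = panel length, default 8),
``concentration_pg_ml``
    the analyte concentration label of the source experiment (NaN when the
    provenance is unknown, e.g. freshly detected unlabeled data),
``chip_id`` / ``experiment_id``
    provenance identifiers,
``time_s``
    optional event time within the source trace (NaN if not applicable).

All amplitude values are non-negative magnitudes of the impedance
deviation from baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "AMP_PREFIX",
    "META_COLUMNS",
    "amplitude_columns",
    "amplitude_matrix",
    "empty_peak_table",
    "make_peak_table",
    "validate_peak_table",
]

AMP_PREFIX = "amp_f"
META_COLUMNS = ("concentration_pg_ml", "chip_id", "experiment_id", "time_s")


def amplitude_columns(table: pd.DataFrame) -> list:
    """Names of the per-channel amplitude columns, in channel order."""
    cols = [c for c in table.columns if c.startswith(AMP_PREFIX)]
    cols.sort(key=lambda c: int(c[len(AMP_PREFIX):]))
    return cols


def amplitude_matrix(table: pd.DataFrame) -> np.ndarray:
    """(n_rows, n_channels) float array of peak amplitudes."""
    return table[amplitude_columns(table)].to_numpy(dtype=float)


def empty_peak_table(n_channels: int) -> pd.DataFrame:
    """An empty table with the full schema for ``n_channels`` channels."""
    cols = {f"{AMP_PREFIX}{i + 1}": pd.Series(dtype=float)
            for i in range(n_channels)}
    cols["concentration_pg_ml"] = pd.Series(dtype=float)
    cols["chip_id"] = pd.Series(dtype=object)
    cols["experiment_id"] = pd.Series(dtype=object)
    cols["time_s"] = pd.Series(dtype=float)
    return pd.DataFrame(cols)


def make_peak_table(amplitudes: np.ndarray, concentration, chip_id,
                    experiment_id, time_s=None) -> pd.DataFrame:
    """Assemble a peak table from an (n, n_channels) amplitude array."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.ndim != 2:
        raise InputError("amplitudes must be a 2-D (n_events, n_channels) array")
    n, n_ch = amplitudes.shape
    if n == 0:
        return empty_peak_table(n_ch)
    data = {f"{AMP_PREFIX}{i + 1}": amplitudes[:, i] for i in range(n_ch)}
    data["concentration_pg_ml"] = np.full(n, np.nan) if concentration is None \
        else np.full(n, float(concentration))
    data["chip_id"] = [chip_id] * n
    data["experiment_id"] = [experiment_id] * n
    data["time_s"] = np.full(n, np.nan) if time_s is None \
        else np.asarray(time_s, dtype=float)
    return pd.DataFrame(data)


def validate_peak_table(table: pd.DataFrame, n_channels: int | None = None) -> None:
    """Raise :class:`InputError` if ``table`` violates the schema invariants."""
    cols = amplitude_columns(table)
    if not cols:
        raise InputError("peak table has no amplitude columns (amp_f*)")
    if n_channels is not None and len(cols) != n_channels:
        raise InputError(
            f"peak table has {len(cols)} amplitude columns, expected {n_channels}")
    for name in META_COLUMNS:
        if name not in table.columns:
            raise InputError(f"peak table missing required column '{name}'")
    amps = table[cols].to_numpy(dtype=float)
    if amps.size:
        if not np.all(np.isfinite(amps)):
            raise InputError("peak amplitudes must be finite")
        if np.any(amps < 0):
            raise InputError("peak amplitudes must be non-negative magnitudes")
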