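"""Reading and writing the package's on-disk formats.

Peak tables are plain CSV (UTF-8, header row, ``.`` decimal point) with
columns ``amp_f1..amp_fN``, ``concentration_pg_ml``, ``chip_id``,
``experiment_id``, ``time_s``; floats are written with full ``repr``
precision so write/read round-trips are bit-identical for finite values.
Traces are a multi-column CSV plus a JSON sidecar carrying the sampling
rate, frequency panel, provenance and the injected ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FrequencyPanel
from .errors import ParseError
from .synthgen import ImpedanceTrace, TraceEvent
from .tables import AMP_PREFIX, META_COLUMNS, amplitude_columns, validate_peak_table

__all__ = [
    "write_peak_table",
    "read_peak_table",
    "write_trace",
    "read_trace",
    "write_mocks",
]


def write_peak_table(table: pd.DataFrame, path) -> None:
    """Write a peak table as CSV (full float precision)."""
    validate_peak_table(table)
    cols = amplitude_columns(table) + [c for c in table.columns
                                       if not c.startswith(AMP_PREFIX)]
    # %.17g round-trips IEEE doubles exactly
    table[cols].to_csv(path, index=False, float_format="%.17g")


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak-table CSV, validating the schema.

    Raises :class:`ParseError` naming the offending column or line.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    amp_cols = [c for c in table.columns if c.startswith(AMP_PREFIX)]
    if not amp_cols:
        raise ParseError(f"{path}: no amplitude columns ({AMP_PREFIX}*) "
                         "in header")
    for name in META_COLUMNS:
        if name not in table.columns:
            raise ParseError(f"{path}: missing required column '{name}'")
    for c in amp_cols:
        vals = pd.to_numeric(table[c], errors="coerce")
        bad = vals.isna() & table[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric amplitude in column "
                             f"'{c}' at line {line}")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise ParseError(f"{path}: missing amplitude in column '{c}' "
                             f"at line {line}")
        table[c] = vals.astype(float)
    return table


def write_trace(trace: ImpedanceTrace, csv_path, meta_path=None) -> None:
    """Write a trace as multi-column CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    cols = {"time_s": trace.times_s}
    for i in range(trace.n_channels):
        cols[f"ch{i + 1}_v"] = trace.samples[:, i]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "frequencies_hz": list(trace.channel_frequencies.frequencies_hz),
        "concentration": trace.concentration,
        "chip_id": trace.chip_id,
        "experiment_id": trace.experiment_id,
        "truth": None if trace.truth is None else [
            {"time_s": ev.time_s,
             "amplitudes": np.asarray(ev.amplitudes).tolist(),
             "concentration": ev.concentration}
            for ev in trace.truth],
    }
    meta_path.write_text(json.dumps(meta), encoding="utf-8")


def read_trace(csv_path, meta_path=None) -> ImpedanceTrace:
    """Read a trace written by :func:`write_trace`."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    try:
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        df = pd.read_csv(csv_path)
    except Exception as exc:
        raise ParseError(f"{csv_path}: {exc}") from exc
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    truth = None
    if meta.get("truth") is not None:
        truth = [TraceEvent(ev["time_s"], np.asarray(ev["amplitudes"]),
                            ev["concentration"]) for ev in meta["truth"]]
    return ImpedanceTrace(
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        samples=df[ch_cols].to_numpy(dtype=float),
        channel_frequencies=FrequencyPanel(tuple(meta["frequencies_hz"])),
        truth=truth, concentration=meta.get("concentration"),
        chip_id=meta.get("chip_id"), experiment_id=meta.get("experiment_id"))


def write_mocks(mocks, path) -> None:
    """Write mock experiments as one CSV with mock_id/sample_label columns."""
    parts = []
    for mock in mocks:
        df = mock.peaks.copy()
        df["mock_id"] = mock.mock_id
        df["sample_label"] = mock.sample_label
        parts.append(df)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
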