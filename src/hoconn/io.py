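"""Delimited-text I/O for time series, estimates and maps.

TSV is the canonical exchange format (parcel time series are routinely
exported as delimited text); CSV is accepted on input by extension.  A
matrix file holds one region per row by default (``regions_in_rows``),
with an optional first header row/column of region labels.  Results
tables use a fixed column schema with 10-significant-digit floats and a
deterministic row order so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .estimators import CumulantEstimate
from .timeseries import RegionTimeSeries

__all__ = [
    "ParseError",
    "read_timeseries",
    "write_timeseries",
    "write_results",
    "read_results",
    "write_metadata",
    "load_config",
]

RESULT_COLUMNS = ["indices", "order", "measure", "value", "se", "ci_low", "ci_high", "p"]


class ParseError(ValueError):
    """A delimited matrix file could not be parsed; names the line."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_timeseries(path, regions_in_rows: bool = True) -> RegionTimeSeries:
    """Read a delimited numeric matrix as a region-by-time series.

    The first row is treated as region labels when any of its cells is
    non-numeric (after orientation, the first column when regions are in
    columns).  Ragged rows, non-numeric cells and empty files raise
    :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    sep = _sep_for(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    table = [ln.split(sep) for ln in lines]
    width = len(table[0])
    for ln_no, row in enumerate(table, start=1):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {ln_no} has {len(row)} fields, expected {width}"
            )
    header: list[str] | None = None
    # a leading label column: every row starts with a non-numeric token but
    # the remaining cells of the first row are numeric
    label_col = all(not _is_number(row[0]) for row in table) and all(
        _is_number(tok) for tok in table[0][1:]
    )
    if not label_col and not all(_is_number(tok) for tok in table[0]):
        header, table = table[0], table[1:]
        if not table:
            raise ParseError(f"{path}: no data rows after header (line 1)")
        label_col = any(not _is_number(row[0]) for row in table)
    data = np.empty((len(table), width - (1 if label_col else 0)))
    row_labels: list[str] = []
    for r, row in enumerate(table):
        ln_no = r + 1 + (1 if header is not None else 0)
        if label_col:
            row_labels.append(row[0])
            row = row[1:]
        for c, tok in enumerate(row):
            try:
                data[r, c] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at line {ln_no}"
                ) from None
    if not regions_in_rows:
        data = data.T
        ids = header[1:] if (header is not None and label_col) else header
        ids = ids if ids is not None else [f"R{i+1}" for i in range(data.shape[0])]
    else:
        ids = row_labels if label_col else (
            header if (header is not None and len(header) == data.shape[0]) else None
        )
        if ids is None:
            ids = [f"R{i+1}" for i in range(data.shape[0])]
    if len(ids) != data.shape[0]:
        raise ParseError(f"{path}: {len(ids)} labels for {data.shape[0]} regions")
    return RegionTimeSeries(data, ids)


def write_timeseries(ts: RegionTimeSeries, path) -> None:
    """Write regions-in-rows TSV with a leading region-label column."""
    path = Path(path)
    with path.open("w") as fh:
        for lab, row in zip(ts.region_ids, ts.data):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    return f"{v:.10g}"


def write_results(estimates: Iterable[CumulantEstimate] | pd.DataFrame, path) -> None:
    """Write an estimate table as TSV with the fixed column schema.

    Rows are sorted lexicographically by index tuple (then measure) so the
    output is deterministic; floats carry 10 significant digits.
    """
    path = Path(path)
    if isinstance(estimates, pd.DataFrame):
        df = estimates.copy()
    else:
        rows = []
        for est in estimates:
            ci_low, ci_high = est.ci if est.ci is not None else (None, None)
            rows.append(
                {
                    "indices": ",".join(est.indices),
                    "order": est.order,
                    "measure": est.measure,
                    "value": est.value,
                    "se": est.se,
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "p": est.p_value,
                }
            )
        df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RESULT_COLUMNS].sort_values(["indices", "measure"], kind="mergesort")
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            cells = [
                str(row["indices"]),
                str(int(row["order"])),
                str(row["measure"]),
                _fmt(row["value"]),
                _fmt(row["se"]),
                _fmt(row["ci_low"]),
                _fmt(row["ci_high"]),
                _fmt(row["p"]),
            ]
            fh.write("\t".join(cells) + "\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(meta: dict, path) -> None:
    """JSON sidecar with parameters, seed and ground truth."""
    Path(path).write_text(json.dumps(meta, indent=2, default=float) + "\n")


def load_config(path) -> dict:
    """YAML (or JSON) config mapping used for CLI --config overrides."""
    cfg = yaml.safe_load(Path(path).read_text())
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
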