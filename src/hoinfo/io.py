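"""Readers and writers for the delimited-text interchange formats.

- Correlation matrix: delimited text, first row = node labels, square
  numeric body. Mild asymmetry is repaired by averaging with the transpose.
- Time series: delimited text, header row of node labels, T rows of values.
- System partition: two columns, node_id and label.
- Run manifest: one file path per line (optionally subject/run columns),
  listing the per-run time-series files to aggregate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate_report import SystemPartition
from .fc_pipeline import TimeSeriesMatrix
from .gaussian_info import CorrelationMatrix

__all__ = [
    "read_correlation",
    "write_correlation",
    "read_timeseries",
    "write_timeseries",
    "read_partition",
    "read_manifest",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_correlation(path: str | Path, symmetrize: bool = True) -> CorrelationMatrix:
    """Load a correlation matrix, repairing asymmetry by transpose-averaging."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    vals = df.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise ValueError(
            f"{path}: matrix body is {vals.shape[0]}x{vals.shape[1]}, expected square"
        )
    if symmetrize:
        vals = (vals + vals.T) / 2.0
    return CorrelationMatrix(vals, list(df.columns))


def write_correlation(corr: CorrelationMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(corr.values, columns=list(corr.node_ids)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_timeseries(
    path: str | Path,
    sampling_interval: float | None = None,
    run_id: str | None = None,
    subject_id: str | None = None,
) -> TimeSeriesMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in time series")
    return TimeSeriesMatrix(
        values=df.to_numpy(dtype=float),
        node_ids=list(df.columns),
        sampling_interval=sampling_interval,
        run_id=run_id or path.stem,
        subject_id=subject_id,
    )


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(ts.values, columns=list(ts.node_ids)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_partition(path: str | Path) -> SystemPartition:
    """Load a node_id,label table into a SystemPartition."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns node_id,label")
    return SystemPartition(
        node_ids=[str(v) for v in df.iloc[:, 0]],
        labels=[str(v) for v in df.iloc[:, 1]],
    )


def read_manifest(
    path: str | Path, sampling_interval: float | None = None
) -> list[TimeSeriesMatrix]:
    """Load every run listed in a manifest (one path per line, optionally
    tab-separated subject and run columns; paths relative to the manifest)."""
    path = Path(path)
    runs: list[TimeSeriesMatrix] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ts_path = Path(parts[0])
        if not ts_path.is_absolute():
            ts_path = path.parent / ts_path
        subject = parts[1] if len(parts) > 1 else None
        run = parts[2] if len(parts) > 2 else None
        runs.append(
            read_timeseries(
                ts_path,
                sampling_interval=sampling_interval,
                run_id=run,
                subject_id=subject,
            )
        )
    if not runs:
        raise ValueError(f"{path}: manifest lists no runs")
    return runs
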