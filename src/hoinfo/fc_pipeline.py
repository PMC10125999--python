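"""Build an aggregate functional-connectivity matrix from node time series.

The canonical path: per-run z-scoring, optional global signal regression,
optional detrend / zero-phase band-pass / frame trimming, concatenation of
runs, and a single Pearson correlation over the concatenated series,
symmetrized by averaging with its transpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .gaussian_info import CorrelationMatrix

__all__ = [
    "TimeSeriesMatrix",
    "zscore",
    "global_signal_regression",
    "detrend_filter_trim",
    "fc_from_runs",
    "inject_global_redundancy",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T x N node time-series table.

    ``sampling_interval`` (seconds per frame) is required only for
    frequency-domain operations. ``run_id`` / ``subject_id`` are free-form
    provenance tags.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]
    sampling_interval: float | None = None
    run_id: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"time series must be 2-D (T x N), got shape {vals.shape}")
        if vals.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.isfinite(vals).all():
            raise ValueError("time series contains non-finite values")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        ids = self.node_ids
        if ids is None:
            ids = tuple(f"n{i}" for i in range(vals.shape[1]))
        else:
            ids = tuple(str(s) for s in ids)
        if len(ids) != vals.shape[1]:
            raise ValueError(f"{len(ids)} labels for {vals.shape[1]} columns")
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def zscore(ts: TimeSeriesMatrix, ddof: int = 0) -> TimeSeriesMatrix:
    """Column-wise standardization to mean 0, sd 1 (population convention).

    Raises on zero-variance columns, naming the offending node.
    """
    vals = ts.values
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        names = ", ".join(ts.node_ids[i] for i in bad[:5])
        raise ValueError(f"zero-variance column(s): {names}")
    return replace(ts, values=(vals - mean) / sd)


def global_signal_regression(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Regress the across-node mean time course out of every node.

    The global signal is the unweighted mean over columns; each column is
    replaced by its least-squares residual (with intercept), leaving it
    orthogonal to the global signal. A zero-variance global signal makes the
    projection degenerate: the input passes through with a warning.
    """
    if ts.n_nodes < 2:
        raise ValueError("global signal regression requires at least 2 nodes")
    vals = ts.values
    gs = vals.mean(axis=1)
    if gs.std() == 0.0:
        warnings.warn(
            "global signal has zero variance; skipping regression",
            RuntimeWarning,
            stacklevel=2,
        )
        return ts
    design = np.column_stack([np.ones(ts.n_timepoints), gs])
    beta, *_ = np.linalg.lstsq(design, vals, rcond=None)
    resid = vals - design @ beta
    return replace(ts, values=resid)


def detrend_filter_trim(
    ts: TimeSeriesMatrix,
    band: tuple[float, float] | None = None,
    trim: int = 0,
    detrend: bool = True,
    filter_order: int = 2,
) -> TimeSeriesMatrix:
    """Linear detrend, zero-phase band-pass, symmetric frame trimming.

    All three steps are optional; the order is detrend, filter, trim.
    ``band`` is (low, high) in Hz and requires ``sampling_interval``; the
    filter is a Butterworth of order ``filter_order`` applied forward and
    backward (zero phase).
    """
    vals = ts.values
    if detrend:
        vals = sps.detrend(vals, axis=0, type="linear")
    if band is not None:
        if ts.sampling_interval is None:
            raise ValueError("band-pass filtering requires sampling_interval")
        low, high = band
        nyquist = 0.5 / ts.sampling_interval
        if not (0.0 < low < high < nyquist):
            raise ValueError(
                f"band ({low}, {high}) Hz infeasible for Nyquist {nyquist:.4g} Hz"
            )
        sos = sps.butter(filter_order, [low, high], btype="bandpass", fs=1.0 / ts.sampling_interval, output="sos")
        vals = sps.sosfiltfilt(sos, vals, axis=0)
    if trim:
        if 2 * trim >= vals.shape[0]:
            raise ValueError(f"trimming 2x{trim} frames exceeds series length {vals.shape[0]}")
        vals = vals[trim:-trim]
    return replace(ts, values=np.ascontiguousarray(vals))


def fc_from_runs(
    runs: Sequence[TimeSeriesMatrix],
    zscore_per_run: bool = True,
    mode: str = "append",
) -> CorrelationMatrix:
    """Pearson FC from one or more runs.

    Default ``mode="append"``: each run is z-scored and the series are
    concatenated in time before a single correlation is computed.
    ``mode="average"`` correlates each run separately and averages the
    matrices. Either way the result is symmetrized by averaging with its
    transpose and the diagonal forced to exactly 1.
    """
    if not runs:
        raise ValueError("at least one run is required")
    ref_ids = runs[0].node_ids
    for r in runs[1:]:
        if r.node_ids != ref_ids:
            extra = set(r.node_ids) ^ set(ref_ids)
            raise ValueError(f"runs disagree on node labels: {sorted(extra)[:10]}")
    if mode not in ("append", "average"):
        raise ValueError(f"mode must be 'append' or 'average', got {mode!r}")

    if mode == "append":
        blocks = [zscore(r).values if zscore_per_run else r.values for r in runs]
        data = np.vstack(blocks)
        corr = np.corrcoef(data, rowvar=False)
    else:
        mats = [np.corrcoef(r.values, rowvar=False) for r in runs]
        corr = np.mean(mats, axis=0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, ref_ids)


def inject_global_redundancy(
    ts: TimeSeriesMatrix,
    amplitude: float,
    cutoff: float = 0.01,
    seed: int = 0,
    filter_order: int = 2,
) -> TimeSeriesMatrix:
    """Add one shared low-frequency Gaussian signal to every node.

    Emulates a globally redundant contaminant (e.g. slow scanner or
    physiological drift): white Gaussian noise is low-pass filtered at
    ``cutoff`` Hz, re-standardized, scaled by ``amplitude``, and added to
    each column. ``amplitude=0`` returns the input unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0.0:
        return ts
    if ts.sampling_interval is None:
        raise ValueError("injection requires sampling_interval to define the cutoff")
    nyquist = 0.5 / ts.sampling_interval
    if not (0.0 < cutoff < nyquist):
        raise ValueError(f"cutoff {cutoff} Hz infeasible for Nyquist {nyquist:.4g} Hz")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(ts.n_timepoints)
    sos = sps.butter(filter_order, cutoff, btype="lowpass", fs=1.0 / ts.sampling_interval, output="sos")
    shared = sps.sosfiltfilt(sos, noise)
    sd = shared.std()
    if sd == 0.0:
        raise RuntimeError("filtered contaminant degenerated to a constant")
    shared = shared / sd
    return replace(ts, values=ts.values + amplitude * shared[:, None])
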