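"""From ROI time series to Fisher-z connectivity vectors.

The stage order is nuisance regression (with an intercept and a linear
trend added to the supplied confounds), zero-phase band-pass filtering of
the residuals (0.008-0.1 Hz), motion scrubbing (censoring frames with
framewise displacement above 0.5 mm), and finally pairwise Pearson
correlation with the r-to-z transform.  Censoring after filtering avoids
introducing discontinuities into the filter input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .edges import edge_pairs
from .errors import ConfigError, DataValidationError, QualityError

__all__ = [
    "TimeSeries",
    "regress_confounds",
    "bandpass",
    "scrub_frames",
    "timeseries_to_fc",
    "preprocess_to_fc",
]

R_CLIP = 1.0 - 1e-7  # keep atanh finite for perfectly (anti)correlated pairs


@dataclass
class TimeSeries:
    """frames x R ROI signal matrix with repetition time and motion trace."""

    data: np.ndarray
    tr_seconds: float
    fd_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise DataValidationError("time series must be frames x ROI with >= 2 frames")
        if self.tr_seconds <= 0:
            raise DataValidationError("tr_seconds must be positive")
        if self.fd_trace is not None:
            self.fd_trace = np.asarray(self.fd_trace, dtype=np.float64)
            if self.fd_trace.shape != (self.data.shape[0],):
                raise DataValidationError("fd_trace length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def regress_confounds(ts: TimeSeries, confounds: pd.DataFrame) -> TimeSeries:
    """Per-ROI least-squares residuals after [intercept, trend, confounds].

    Raises a regression error naming the collinear columns when the design
    is rank deficient.
    """
    C = np.asarray(confounds, dtype=float)
    if C.ndim != 2 or C.shape[1] < 1:
        raise DataValidationError("confound table needs at least one column")
    if C.shape[0] != ts.n_frames:
        raise DataValidationError("confound table length must equal the frame count")
    if not np.isfinite(C).all():
        raise DataValidationError("confounds must be finite")
    n = ts.n_frames
    trend = np.linspace(-1.0, 1.0, n)
    X = np.column_stack([np.ones(n), trend, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = list(confounds.columns) if hasattr(confounds, "columns") else [
            f"c{k}" for k in range(C.shape[1])
        ]
        collinear = []
        base = np.column_stack([np.ones(n), trend])
        for k in range(C.shape[1]):
            cand = np.column_stack([base, C[:, : k + 1]])
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                collinear.append(names[k])
        raise DataValidationError(f"rank-deficient confound design; collinear: {collinear}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return replace(ts, data=ts.data - X @ beta)


def bandpass(ts: TimeSeries, low: float = 0.008, high: float = 0.1) -> TimeSeries:
    """Zero-phase band-pass of each ROI series.

    A second-order Butterworth band-pass applied forward and backward
    (``filtfilt``), so the passband is traversed twice (doubling the
    stop-band attenuation) with no phase lag.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 < low < high:
        raise ConfigError("need 0 < low < high")
    if high >= nyquist:
        raise ConfigError(
            f"band edge {high} Hz is not below the Nyquist frequency {nyquist:.4g} Hz"
        )
    b, a = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.tr_seconds)
    filtered = signal.filtfilt(b, a, ts.data, axis=0)
    return replace(ts, data=filtered)


def scrub_frames(ts: TimeSeries, threshold: float = 0.5, min_frames: int = 50) -> TimeSeries:
    """Censor frames whose framewise displacement strictly exceeds ``threshold`` mm."""
    if ts.fd_trace is None:
        raise DataValidationError("scrubbing requires an fd_trace")
    keep = ts.fd_trace <= threshold
    n_keep = int(keep.sum())
    if n_keep < min_frames:
        raise QualityError(
            f"only {n_keep} frames survive FD <= {threshold} mm (minimum {min_frames})"
        )
    return TimeSeries(ts.data[keep], ts.tr_seconds, ts.fd_trace[keep])


def timeseries_to_fc(ts: TimeSeries) -> np.ndarray:
    """Fisher-z vector of all pairwise Pearson correlations, in flat edge order.

    Correlations are clipped to |r| <= 1 - 1e-7 before atanh so that
    perfectly correlated pairs stay finite.
    """
    if ts.n_frames < 3:
        raise QualityError("need at least 3 frames to correlate")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DataValidationError(f"zero-variance ROIs: {dead.tolist()}")
    r = np.corrcoef(ts.data, rowvar=False)
    rows, cols = edge_pairs(ts.n_rois)
    z = np.arctanh(np.clip(r[rows, cols], -R_CLIP, R_CLIP))
    return z


def preprocess_to_fc(
    ts: TimeSeries,
    confounds: pd.DataFrame | None = None,
    low: float = 0.008,
    high: float = 0.1,
    fd_threshold: float = 0.5,
    min_frames: int = 50,
) -> np.ndarray:
    """Full stage chain: regression -> band-pass -> scrubbing -> correlation."""
    if confounds is not None:
        ts = regress_confounds(ts, confounds)
    ts = bandpass(ts, low, high)
    if ts.fd_trace is not None:
        ts = scrub_frames(ts, fd_threshold, min_frames)
    else:
        warnings.warn("no fd_trace supplied; skipping motion scrubbing", stacklevel=2)
    return timeseries_to_fc(ts)
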