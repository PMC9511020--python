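"""Static functional connectivity: Pearson matrices, vectorization, scaling.

Turns per-subject ROI time series into the two feature representations the
models consume: the full p x p correlation matrix (deep-learning input) and
its strictly-lower-triangle vectorization of length p(p-1)/2
(machine-learning input).  Feature standardization always fits on the
training set only and applies those parameters to held-out data.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.preprocessing import StandardScaler

from .types import ConnectivityMatrix, FeatureVector, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "compute_sfc",
    "vectorize_lower_triangle",
    "matrix_from_lower_triangle",
    "lower_triangle_index_map",
    "standardize_features",
    "minmax_scale_timeseries",
]


def compute_sfc(ts: RoiTimeSeries, minmax_first: bool = False) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between ROI time courses.

    Parameters
    ----------
    ts
        Subject time series, shape T x p with T >= 3.
    minmax_first
        Optionally min-max scale each ROI column to [0, 1] before
        correlating.  Pearson r is invariant under positive affine maps,
        so this cannot change the result; the flag exists purely to
        mirror pipelines that log the scaled series.

    Raises
    ------
    ValueError
        If T < 3, any value is non-finite, or any ROI column has zero
        variance (a zero-variance parcel signals an extraction fault).
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 timepoints for Pearson correlation, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in time series")
    if minmax_first:
        x = minmax_scale_timeseries(ts).values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.roi_labels[i] for i in dead[:5])
        raise ValueError(f"zero-variance ROI column(s): {names}")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    cm = ConnectivityMatrix(values=corr, roi_labels=list(ts.roi_labels), subject_id=ts.subject_id)
    cm.validate(atol=1e-10)
    return cm


def minmax_scale_timeseries(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Scale each ROI column to [0, 1]."""
    x = ts.values
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return RoiTimeSeries(ts.subject_id, (x - lo) / span, list(ts.roi_labels))


def lower_triangle_index_map(p: int) -> list[tuple[int, int]]:
    """Row-major enumeration of strictly-lower-triangle positions."""
    return [(i, j) for i in range(1, p) for j in range(i)]


def vectorize_lower_triangle(cm: ConnectivityMatrix, atol: float = 1e-9) -> FeatureVector:
    """Linearize the strictly lower triangle (no diagonal) of a symmetric matrix."""
    v = cm.values
    asym = np.abs(v - v.T).max() if v.size else 0.0
    if asym > atol:
        raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g} > {atol:g})")
    p = cm.n_regions
    idx = lower_triangle_index_map(p)
    rows, cols = np.tril_indices(p, k=-1)
    return FeatureVector(values=v[rows, cols], index_map=idx)


def matrix_from_lower_triangle(fv: FeatureVector, roi_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Rebuild a symmetric unit-diagonal matrix from its lower-triangle vector."""
    m = len(fv.values)
    p = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if p * (p - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not p*(p-1)/2 for integer p")
    out = np.eye(p)
    rows, cols = np.tril_indices(p, k=-1)
    out[rows, cols] = fv.values
    out[cols, rows] = fv.values
    if roi_labels is None:
        roi_labels = [f"ROI{i}" for i in range(p)]
    return ConnectivityMatrix(values=out, roi_labels=roi_labels)


def standardize_features(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardScaler]:
    """Per-feature z-scoring fitted on the training block only.

    ``train`` is (n_train, d) — rows are subjects, columns are features
    (lower-triangle edges, or flattened matrices for the deep models).
    Zero-variance features pass through unscaled and are logged.
    Returns (scaled train, scaled apply_to or None, fitted scaler).
    """
    train = np.asarray(train, dtype=np.float64)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("training set must be a nonempty 2-D array")
    scaler = StandardScaler()
    scaled_train = scaler.fit_transform(train)
    zero_var = np.flatnonzero(scaler.var_ == 0)
    if zero_var.size:
        logger.warning(
            "standardize_features: %d zero-variance feature(s) passed through unscaled "
            "(first indices: %s)", zero_var.size, zero_var[:10].tolist(),
        )
    scaled_apply = scaler.transform(np.asarray(apply_to, dtype=np.float64)) if apply_to is not None else None
    return scaled_train, scaled_apply, scaler
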