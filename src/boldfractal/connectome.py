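"""Parcel time-series extraction and weighted functional connectivity.

Edges are Pearson, partial (shrinkage-regularized), or wavelet-scale
correlations between mean parcel time series.  Negative correlations are
set to zero (edge absent) and the diagonal is zeroed; no further
thresholding is applied, so matrices are "fully connected" in the sense of
retaining every non-negative edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .fractal import DEFAULT_WAVELET, modwt
from .parcellate import Parcellation

METHODS = ("pearson", "partial", "wavelet")


@dataclass
class ParcelTimeseries:
    """Mean time series per kept parcel: ``data`` is (n_parcels, n_timepoints)."""

    data: np.ndarray
    parcel_ids: np.ndarray
    tr_s: float


@dataclass
class ConnectomeMatrix:
    """Symmetric non-negative weighted adjacency with zero diagonal."""

    weights: np.ndarray
    parcel_ids: np.ndarray
    method: str
    scale: int | None = None


def extract_timeseries(
    bold_data: np.ndarray, parc: Parcellation, tr_s: float = 1.0
) -> ParcelTimeseries:
    """Mean over member voxels at each timepoint, per kept parcel.

    A kept parcel with zero voxels on the image grid yields a NaN row
    (flagged, not raised).
    """
    data = np.asarray(bold_data, dtype=float)
    if data.shape[:3] != parc.labels.shape:
        raise ValueError("grids do not match")
    ids = parc.kept_ids()
    out = np.full((ids.size, data.shape[3]), np.nan)
    for row, pid in enumerate(ids):
        sel = parc.labels == pid
        if sel.any():
            out[row] = data[sel].mean(axis=0)
    return ParcelTimeseries(data=out, parcel_ids=ids, tr_s=tr_s)


def _clean_correlation(r: np.ndarray) -> np.ndarray:
    """Zero negatives and the diagonal; silence NaNs from constant rows."""
    r = np.where(np.isfinite(r), r, 0.0)
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return (r + r.T) / 2.0


def _pearson(data: np.ndarray) -> np.ndarray:
    sd = data.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant parcel series: correlations set to 0", stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(data)


def _partial(data: np.ndarray) -> np.ndarray:
    """Partial correlation from the inverse of a Ledoit-Wolf shrinkage
    covariance (stable when parcels approach or exceed timepoints)."""
    lw = LedoitWolf(assume_centered=False).fit(data.T)
    prec = lw.precision_
    d = np.sqrt(np.diag(prec))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = -prec / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def _wavelet(data: np.ndarray, scale: int, wavelet: str) -> np.ndarray:
    """Pearson correlation of boundary-free MODWT detail coefficients at the
    requested scale."""
    decomp = modwt(data, wavelet=wavelet, n_levels=scale)
    nb = int(decomp.n_boundary[scale - 1])
    coeffs = decomp.detail_coeffs[scale - 1][:, nb:]
    if coeffs.shape[1] < 8:
        raise ValueError(
            f"too few boundary-free coefficients at scale {scale} "
            f"({coeffs.shape[1]}); use a lower scale or longer series"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(coeffs)


def connectivity(
    ts: ParcelTimeseries,
    method: str = "pearson",
    scale: int | None = None,
    wavelet: str = DEFAULT_WAVELET,
) -> ConnectomeMatrix:
    """Weighted functional network from parcel time series.

    ``method`` is one of ``pearson``, ``partial`` or ``wavelet`` (the latter
    correlates MODWT detail coefficients at ``scale``, default 2 — the band
    carrying slow resting-state fluctuations at TR ~ 2.4 s).  Negative
    correlations become 0; the diagonal is 0.
    """
    data = np.asarray(ts.data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 parcels")
    if data.shape[1] < 8:
        raise ValueError("need >= 8 timepoints")
    if np.isnan(data).any():
        raise ValueError("time-series matrix contains NaN rows (empty parcels?)")

    if method == "pearson":
        r = _pearson(data)
    elif method == "partial":
        r = _partial(data)
    elif method == "wavelet":
        if scale is None:
            scale = 2
        r = _wavelet(data, scale, wavelet)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return ConnectomeMatrix(
        weights=_clean_correlation(r),
        parcel_ids=ts.parcel_ids,
        method=method,
        scale=scale if method == "wavelet" else None,
    )
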